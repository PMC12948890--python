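"""Synthetic three-timepoint MESE knee phantom generator.

Builds schematic knee cartilage slices — curved femoral bands, flat tibial
bands and patellofemoral patches labeled with the WORMS-derived base
scheme, plus synovial-fluid pixels (T2 above the 100 ms exclusion cutoff)
adjacent to the superficial cartilage — renders the corresponding MESE
echo images through the EPG forward model with Rician or Gaussian noise,
and assembles full bilateral three-timepoint study designs with optional
knee dropout.  The geometry is deliberately schematic: the pipeline under
test is geometry-agnostic, so anatomical realism buys nothing testable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .epg import simulate_emc_batch
from .matching import ImageSeries
from .regions import DEFAULT_SCHEME, RegionScheme, SampleKey
from .sequence import SequenceParams, echo_train

__all__ = [
    "PhantomSpec",
    "Phantom",
    "SyntheticStudy",
    "FLUID_LABEL",
    "make_phantom",
    "render_mese",
    "make_study",
]

FLUID_LABEL = 99
TIMEPOINTS = ("rest", "21k", "control")

# baseline (rest) T2 per base section, ms; condyle sections take their
# plate's value, patellofemoral sections their own
_DEFAULT_BASELINE_T2 = {
    "LFa": 45.0, "LFc": 45.0, "LFp": 45.0,
    "LTa": 36.4, "LTc": 36.4, "LTp": 36.4,
    "MFa": 45.9, "MFc": 45.9, "MFp": 45.9,
    "MTa": 40.8, "MTc": 40.8, "MTp": 40.8,
    "LPpf": 41.4, "LFpf": 47.0, "Pt": 43.4, "Ft": 44.6,
}


@dataclass
class PhantomSpec:
    """Ground-truth description of one synthetic knee.

    ``effects`` maps a base-section name (or ``"global"``) to a pair of
    percent changes ``(run_pct, control_pct)`` applied at the 21k and
    control timepoints relative to rest; the default is a global -2% at
    21k with full recovery at control.  ``on_grid`` rounds all cartilage
    truth T2 values to the 1 ms dictionary grid so that noise-free
    matching is exact.
    """

    shape: tuple = (96, 96, 3)
    baseline_t2: dict = field(default_factory=lambda: dict(_DEFAULT_BASELINE_T2))
    fluid_t2_range: tuple = (120.0, 250.0)
    effects: dict = field(default_factory=lambda: {"global": (-2.0, 0.0)})
    b1_model: str = "constant"          # "constant" | "smooth"
    b1_value: float = 1.0
    b1_range: tuple = (0.90, 1.10)      # for the smooth model
    noise_model: str = "rician"         # "none" | "gaussian" | "rician"
    snr: float = 50.0                   # first-echo amplitude / sigma
    t1_ms: float = 1000.0
    on_grid: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_model not in ("none", "gaussian", "rician"):
            raise ValueError(f"unknown noise model {self.noise_model!r}")
        if self.b1_model not in ("constant", "smooth"):
            raise ValueError(f"unknown b1 model {self.b1_model!r}")
        if self.fluid_t2_range[0] <= 100.0:
            raise ValueError("fluid T2 range must lie above the 100 ms cutoff")
        if self.snr <= 0:
            raise ValueError("snr must be positive")

    def effect_pct(self, section: str, timepoint: str) -> float:
        if timepoint == "rest":
            return 0.0
        pair = self.effects.get(section, self.effects.get("global", (0.0, 0.0)))
        return pair[0] if timepoint == "21k" else pair[1]


@dataclass
class Phantom:
    """Label map plus ground-truth T2/B1 fields for one knee, one timepoint."""

    labels: np.ndarray      # (X, Y, Z) int; 0 background, FLUID_LABEL fluid
    truth_t2: np.ndarray    # (X, Y, Z) ms, 0 outside tissue
    truth_b1: np.ndarray    # (X, Y, Z) fraction
    scheme: RegionScheme


@dataclass
class SyntheticStudy:
    """Full synthetic study: manifest plus per-(participant, knee, timepoint) data."""

    spec: PhantomSpec
    seq: SequenceParams
    manifest: pd.DataFrame                 # one row per (participant, knee, slice)
    images: dict                           # (pid, knee, tp) -> ImageSeries
    labels: dict                           # (pid, knee) -> label volume
    truth_t2: dict                         # (pid, knee, tp) -> truth map
    truth_b1: dict                         # (pid, knee) -> B1 map

    def sample_keys(self) -> list:
        keys = []
        for row in self.manifest.itertuples(index=False):
            for tp in TIMEPOINTS:
                keys.append(SampleKey(
                    participant=row.participant, knee=row.knee,
                    dominant=row.dominance == "dom", slice_index=row.slice,
                    timepoint=tp, sex=row.sex,
                ))
        return keys


def _slice_labels(shape_xy: tuple, scheme: RegionScheme) -> np.ndarray:
    """Schematic single-slice label image (curved bands + patches)."""
    nx, ny = shape_xy
    lab = np.zeros((nx, ny), dtype=np.int16)
    n2c = scheme.name_to_code
    xx, yy = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")

    def femoral(cx: float, cy: float, names: list, r_in: float, r_out: float) -> None:
        r = np.hypot(xx - cx, yy - cy)
        ang = np.degrees(np.arctan2(cy - yy, xx - cx))  # 0..180 above center
        band = (r >= r_in) & (r <= r_out) & (ang > 0) & (ang < 180)
        # anterior | central | posterior by arc angle
        for name, (lo, hi) in zip(names, ((120, 180), (60, 120), (0, 60))):
            sect = band & (ang > lo) & (ang <= hi)
            _paint(lab, sect, n2c[name])

    def tibial(x0: int, x1: int, y0: int, y1: int, names: list) -> None:
        thirds = np.linspace(x0, x1, 4).astype(int)
        for name, (a, b) in zip(names, zip(thirds[:-1], thirds[1:])):
            sect = np.zeros_like(lab, dtype=bool)
            sect[a:b, y0:y1] = True
            _paint(lab, sect, n2c[name])

    def patch(x0: int, y0: int, w: int, h: int, name: str) -> None:
        sect = np.zeros_like(lab, dtype=bool)
        sect[x0:x0 + w, y0:y0 + h] = True
        _paint(lab, sect, n2c[name])

    s = nx / 96.0  # geometry drawn for a 96-wide slice, scaled with the image
    cy = int(0.50 * ny)
    r_in, r_out, fl_w = 16.5 * s, 22.5 * s, 2.5 * s
    # lateral on the right half, medial on the left half
    cx_m, cx_l = int(0.25 * nx), int(0.75 * nx)
    femoral(cx_m, cy, ["MFa", "MFc", "MFp"], r_in, r_out)
    femoral(cx_l, cy, ["LFa", "LFc", "LFp"], r_in, r_out)
    # synovial fluid: thin arcs above the femoral cartilage
    for cx in (cx_m, cx_l):
        r = np.hypot(xx - cx, yy - cy)
        ang = np.degrees(np.arctan2(cy - yy, xx - cx))
        fl = (r > r_out) & (r <= r_out + fl_w) & (ang > 30) & (ang < 150)
        _paint(lab, fl, FLUID_LABEL)
    # tibial plateaus: flat bands below the condyles
    y0, y1 = int(cy + 26 * s), int(cy + 32 * s)
    tibial(int(0.03 * nx), int(0.47 * nx), y0, y1, ["MTa", "MTc", "MTp"])
    tibial(int(0.53 * nx), int(0.97 * nx), y0, y1, ["LTa", "LTc", "LTp"])
    # patellofemoral patches along the top edge
    pw, ph = max(3, int(10 * s)), max(3, int(8 * s))
    gap = max(1, int(2 * s))
    x = gap
    for name in ("LPpf", "LFpf", "Pt", "Ft"):
        patch(x, gap, pw, ph, name)
        x += pw + gap
    return lab


def _paint(lab: np.ndarray, mask: np.ndarray, code: int) -> None:
    if np.any(lab[mask] != 0):
        raise ValueError("phantom construction error: labels would overlap")
    lab[mask] = code


def _b1_field(spec: PhantomSpec) -> np.ndarray:
    nx, ny, nz = spec.shape
    if spec.b1_model == "constant":
        return np.full(spec.shape, float(spec.b1_value))
    # smooth radial polynomial spanning b1_range, constant across slices
    xx, yy = np.meshgrid(
        np.linspace(-1, 1, nx), np.linspace(-1, 1, ny), indexing="ij"
    )
    bowl = 1.0 - 0.5 * (xx ** 2 + yy ** 2)         # 0.0 .. 1.0
    lo, hi = spec.b1_range
    if not (0.60 <= lo < hi <= 1.40):
        raise ValueError("smooth B1 range must lie within [0.60, 1.40]")
    field = lo + (hi - lo) * bowl
    return np.repeat(field[:, :, None], nz, axis=2)


def make_phantom(
    spec: PhantomSpec,
    timepoint: str = "rest",
    scheme: RegionScheme = DEFAULT_SCHEME,
    rng: np.random.Generator | None = None,
) -> Phantom:
    """Construct label map and ground-truth T2/B1 fields for one knee.

    Cartilage sections take their baseline T2 scaled by the configured
    timepoint effect; fluid pixels draw uniform T2 from
    ``spec.fluid_t2_range``.  Deterministic for a fixed spec seed.
    """
    if timepoint not in TIMEPOINTS:
        raise ValueError(f"unknown timepoint {timepoint!r}")
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    nx, ny, nz = spec.shape
    sl = _slice_labels((nx, ny), scheme)
    labels = np.repeat(sl[:, :, None], nz, axis=2)

    truth = np.zeros(spec.shape)
    for code, name in scheme.base_labels.items():
        base = spec.baseline_t2[name]
        t2 = base * (1.0 + spec.effect_pct(name, timepoint) / 100.0)
        if t2 <= 0:
            raise ValueError(f"effect drives {name} T2 non-positive at {timepoint}")
        truth[labels == code] = t2
    fl = labels == FLUID_LABEL
    lo, hi = spec.fluid_t2_range
    truth[fl] = rng.uniform(lo, hi, size=int(fl.sum()))
    if spec.on_grid:
        truth[truth > 0] = np.round(truth[truth > 0])
    return Phantom(labels=labels, truth_t2=truth,
                   truth_b1=_b1_field(spec), scheme=scheme)


def render_mese(
    truth_t2: np.ndarray,
    truth_b1: np.ndarray,
    seq: SequenceParams,
    noise_model: str = "none",
    snr: float = 50.0,
    rng: np.random.Generator | None = None,
    t1_ms: float = 1000.0,
    fluid_mask: np.ndarray | None = None,
) -> ImageSeries:
    """EPG-render a truth T2/B1 volume into a magnitude MESE image series.

    The noise level sigma is set from ``snr`` as (mean first-echo cartilage
    amplitude) / snr, where cartilage excludes ``fluid_mask`` pixels.
    Rician noise adds two independent Gaussian channels to the complex
    signal before taking the magnitude; the Gaussian option perturbs the
    magnitude directly (for analytic checks).
    """
    truth_t2 = np.asarray(truth_t2, float)
    truth_b1 = np.asarray(truth_b1, float)
    tissue = truth_t2 > 0
    vol = np.zeros(truth_t2.shape + (seq.n_echoes,))
    if tissue.any():
        curves = simulate_emc_batch(
            truth_t2[tissue], t1_ms, truth_b1[tissue], seq
        )
        vol[tissue] = curves
    if noise_model == "none":
        return ImageSeries(voxels=vol, echo_times=echo_train(seq))
    if rng is None:
        rng = np.random.default_rng(0)
    ref = tissue if fluid_mask is None else (tissue & ~fluid_mask)
    first = vol[..., 0][ref]
    if first.size == 0:
        raise ValueError("cannot calibrate noise on an empty phantom")
    sigma = float(first.mean()) / snr
    if noise_model == "gaussian":
        vol = np.abs(vol + rng.normal(0.0, sigma, vol.shape))
    elif noise_model == "rician":
        re = vol + rng.normal(0.0, sigma, vol.shape)
        im = rng.normal(0.0, sigma, vol.shape)
        vol = np.hypot(re, im)
    else:
        raise ValueError(f"unknown noise model {noise_model!r}")
    return ImageSeries(voxels=vol, echo_times=echo_train(seq))


def make_study(
    spec: PhantomSpec,
    n_participants: int = 11,
    dropout_knees: int = 3,
    seq: SequenceParams | None = None,
    scheme: RegionScheme = DEFAULT_SCHEME,
    n_female: int | None = None,
    render: bool = True,
) -> SyntheticStudy:
    """Assemble a bilateral three-timepoint synthetic study.

    Emulates the study design: ``n_participants`` right-knee-dominant
    runners scanned bilaterally at rest, post-run and one-week control,
    three slices per knee, with ``dropout_knees`` knees excluded (as for
    motion artefacts).  The default 11 participants with 3 dropped knees
    leave 19 knees and 57 manifest samples.  Noise streams are derived per
    (participant, knee, timepoint) from the spec seed, so dropout does not
    shift the noise of the remaining knees.  ``render=False`` skips image
    synthesis (manifest and truth maps only).
    """
    if n_participants < 1:
        raise ValueError("need at least one participant")
    seq = seq if seq is not None else SequenceParams()
    if n_female is None:
        n_female = int(round(4.0 / 11.0 * n_participants))  # study sex ratio
    pids = [f"P{i + 1:02d}" for i in range(n_participants)]
    sexes = {p: ("female" if i < n_female else "male") for i, p in enumerate(pids)}

    all_knees = [(p, k) for p in pids for k in ("left", "right")]
    if dropout_knees > 0:
        drop_rng = np.random.default_rng(
            np.random.SeedSequence(spec.seed, spawn_key=(9999,))
        )
        drop_idx = drop_rng.choice(len(all_knees), size=dropout_knees, replace=False)
        dropped = {all_knees[i] for i in drop_idx}
    else:
        dropped = set()
    kept = [kn for kn in all_knees if kn not in dropped]

    images, labels, truth_t2, truth_b1 = {}, {}, {}, {}
    rows = []
    for (pid, knee) in kept:
        pi = pids.index(pid)
        ki = 0 if knee == "left" else 1
        geom_rng = np.random.default_rng(
            np.random.SeedSequence(spec.seed, spawn_key=(pi, ki))
        )
        for ti, tp in enumerate(TIMEPOINTS):
            ph = make_phantom(spec, timepoint=tp, scheme=scheme, rng=geom_rng)
            if ti == 0:
                labels[(pid, knee)] = ph.labels
                truth_b1[(pid, knee)] = ph.truth_b1
            truth_t2[(pid, knee, tp)] = ph.truth_t2
            if render:
                noise_rng = np.random.default_rng(
                    np.random.SeedSequence(spec.seed, spawn_key=(pi, ki, ti))
                )
                images[(pid, knee, tp)] = render_mese(
                    ph.truth_t2, ph.truth_b1, seq,
                    noise_model=spec.noise_model, snr=spec.snr, rng=noise_rng,
                    t1_ms=spec.t1_ms, fluid_mask=ph.labels == FLUID_LABEL,
                )
        for s in (1, 2, 3):
            rows.append({
                "participant": pid, "knee": knee,
                "dominance": "dom" if knee == "right" else "nondom",
                "slice": s, "sex": sexes[pid],
            })
    manifest = pd.DataFrame(rows)
    return SyntheticStudy(
        spec=spec, seq=seq, manifest=manifest, images=images,
        labels=labels, truth_t2=truth_t2, truth_b1=truth_b1,
    )
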