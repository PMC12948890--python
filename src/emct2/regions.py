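"""WORMS-derived cartilage region scheme, fluid filter and ROI statistics.

The sagittal knee cartilage is divided into 16 base sections: the four
condyle plates (LF, LT, MF, MT) each split into anterior/central/posterior,
plus the patellofemoral sections LPpf, LFpf (lateral patellofemoral) and
Pt, Ft (trochlea).  Reported regions additionally include the pooled plate
aggregates, the condyle unions LatC = LF∪LT and MedC = MF∪MT, the
patellofemoral unions LPF = LPpf∪LFpf and TrPF = Pt∪Ft, and the grand
total T2Tot — 25 regions in the full scheme.  Aggregates pool pixels, not
section means.  Synovial fluid is excluded by removing pixels whose matched
T2 exceeds 100 ms.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .matching import QuantMaps

logger = logging.getLogger(__name__)

__all__ = [
    "RegionScheme",
    "SampleKey",
    "DEFAULT_SCHEME",
    "FLUID_THRESHOLD_MS",
    "fluid_filter",
    "region_stats",
    "enumerate_regions",
]

FLUID_THRESHOLD_MS = 100.0

_BASE_SECTIONS = [
    "LFa", "LFc", "LFp",
    "LTa", "LTc", "LTp",
    "MFa", "MFc", "MFp",
    "MTa", "MTc", "MTp",
    "LPpf", "LFpf", "Pt", "Ft",
]

_DEFAULT_AGGREGATES = {
    "LF": ["LFa", "LFc", "LFp"],
    "LT": ["LTa", "LTc", "LTp"],
    "MF": ["MFa", "MFc", "MFp"],
    "MT": ["MTa", "MTc", "MTp"],
    "LatC": ["LFa", "LFc", "LFp", "LTa", "LTc", "LTp"],
    "MedC": ["MFa", "MFc", "MFp", "MTa", "MTc", "MTp"],
    "LPF": ["LPpf", "LFpf"],
    "TrPF": ["Pt", "Ft"],
    "T2Tot": list(_BASE_SECTIONS),
}

# canonical reporting order: condyle sections, plate aggregates, condyles,
# patellofemoral (sections interleaved with their unions), grand total
_CANONICAL_ORDER = [
    "LFa", "LFc", "LFp", "LTa", "LTc", "LTp",
    "MFa", "MFc", "MFp", "MTa", "MTc", "MTp",
    "LF", "LT", "MF", "MT",
    "LatC", "MedC",
    "LPpf", "LFpf", "LPF",
    "Pt", "Ft", "TrPF",
    "T2Tot",
]


@dataclass(frozen=True)
class RegionScheme:
    """Integer label codes for base sections plus named pixel-union aggregates.

    ``base_labels`` maps label code -> section name; ``aggregates`` maps
    aggregate name -> list of member section names.  An aggregate is
    reportable only when all of its members are present.
    """

    base_labels: dict = field(default_factory=dict)
    aggregates: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        names = list(self.base_labels.values())
        if len(set(names)) != len(names):
            raise ValueError("base section names must be unique")
        if len(set(self.base_labels)) != len(self.base_labels):
            raise ValueError("base label codes must be unique")
        for agg, members in self.aggregates.items():
            if agg in names:
                raise ValueError(f"aggregate {agg!r} collides with a base section")
            if len(set(members)) != len(members):
                raise ValueError(f"aggregate {agg!r} lists duplicate members")

    @property
    def name_to_code(self) -> dict:
        return {v: k for k, v in self.base_labels.items()}

    def codes_for(self, region: str) -> list:
        """Label codes pooled by ``region`` (a base section or aggregate)."""
        n2c = self.name_to_code
        if region in n2c:
            return [n2c[region]]
        if region in self.aggregates:
            return [n2c[m] for m in self.aggregates[region]]
        raise KeyError(f"unknown region {region!r}")

    @classmethod
    def default(cls) -> "RegionScheme":
        return cls(
            base_labels={i + 1: name for i, name in enumerate(_BASE_SECTIONS)},
            aggregates={k: list(v) for k, v in _DEFAULT_AGGREGATES.items()},
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "RegionScheme":
        raw = json.loads(Path(path).read_text())
        return cls(
            base_labels={int(k): v for k, v in raw["base_labels"].items()},
            aggregates=raw.get("aggregates", {}),
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "base_labels": {str(k): v for k, v in self.base_labels.items()},
            "aggregates": self.aggregates,
        }, indent=2))


DEFAULT_SCHEME = RegionScheme.default()


@dataclass(frozen=True)
class SampleKey:
    """Bookkeeping for one cartilage sample (one slice of one knee scan)."""

    participant: str
    knee: str                 # "left" | "right"
    dominant: bool
    slice_index: int          # 1..3, outermost to innermost
    timepoint: str            # "rest" | "21k" | "control"
    sex: str                  # "male" | "female"

    def __post_init__(self) -> None:
        if self.knee not in ("left", "right"):
            raise ValueError(f"knee must be left/right, got {self.knee!r}")
        if self.timepoint not in ("rest", "21k", "control"):
            raise ValueError(f"unknown timepoint {self.timepoint!r}")
        if self.sex not in ("male", "female"):
            raise ValueError(f"sex must be male/female, got {self.sex!r}")
        if self.slice_index not in (1, 2, 3):
            raise ValueError(f"slice_index must be 1..3, got {self.slice_index}")


def enumerate_regions(scheme: RegionScheme = DEFAULT_SCHEME) -> list:
    """Deterministic canonical ordering of reportable regions.

    Base sections present in the scheme are listed in anatomical order;
    an aggregate appears only if every member section is present.  The
    default scheme yields 25 regions; a condyle-only scheme (patellofemoral
    labels absent) yields 18.
    """
    present = set(scheme.base_labels.values())
    out = []
    for name in _CANONICAL_ORDER:
        if name in present:
            out.append(name)
        elif name in scheme.aggregates and set(scheme.aggregates[name]) <= present:
            out.append(name)
    # custom regions not in the canonical list go last, sorted
    extras = sorted(
        (set(scheme.aggregates) | present) - set(_CANONICAL_ORDER) - set(out)
    )
    for name in extras:
        if name in present or set(scheme.aggregates.get(name, [])) <= present:
            out.append(name)
    return out


def fluid_filter(maps: QuantMaps, roi_mask: np.ndarray,
                 threshold_ms: float = FLUID_THRESHOLD_MS) -> np.ndarray:
    """Remove synovial-fluid pixels from an ROI mask.

    Retains exactly the voxels that are inside ``roi_mask``, validly
    matched, and have ``t2 <= threshold_ms``; strictly greater values
    (synovial fluid) are removed.  Idempotent.
    """
    if threshold_ms <= 0:
        raise ValueError("fluid threshold must be positive")
    roi_mask = np.asarray(roi_mask, dtype=bool)
    with np.errstate(invalid="ignore"):
        keep = roi_mask & maps.validity_mask & (maps.t2_map <= threshold_ms)
    return keep


def region_stats(
    maps: QuantMaps,
    label_map: np.ndarray,
    key: SampleKey,
    scheme: RegionScheme = DEFAULT_SCHEME,
    fluid_threshold_ms: float = FLUID_THRESHOLD_MS,
    strict_labels: bool = True,
) -> pd.DataFrame:
    """Fluid-filtered per-region mean/SD T2 for one sample.

    Aggregates pool pixels (never averages of section means); SD uses the
    sample form (n-1 denominator, NaN for single-pixel regions).  Regions
    emptied by the fluid filter are dropped with a logged warning.

    Returns a DataFrame with columns participant, knee, dominance, slice,
    timepoint, sex, region, mean_t2_ms, sd_t2_ms, n_pixels.
    """
    label_map = np.asarray(label_map)
    if label_map.shape != maps.t2_map.shape:
        raise ValueError("label map shape does not match maps")
    if strict_labels:
        known = set(scheme.base_labels) | {0}
        codes = np.unique(label_map)
        unknown = sorted(set(codes.tolist()) - known)
        if unknown:
            raise ValueError(f"unknown label codes in label map: {unknown}")

    rows = []
    for region in enumerate_regions(scheme):
        codes = scheme.codes_for(region)
        roi = np.isin(label_map, codes)
        keep = fluid_filter(maps, roi, fluid_threshold_ms)
        n = int(keep.sum())
        if n == 0:
            logger.warning("region %s empty after fluid filter for %s/%s slice %d (%s)",
                           region, key.participant, key.knee,
                           key.slice_index, key.timepoint)
            continue
        vals = maps.t2_map[keep]
        rows.append({
            "participant": key.participant,
            "knee": key.knee,
            "dominance": "dom" if key.dominant else "nondom",
            "slice": key.slice_index,
            "timepoint": key.timepoint,
            "sex": key.sex,
            "region": region,
            "mean_t2_ms": float(np.mean(vals)),
            "sd_t2_ms": float(np.std(vals, ddof=1)) if n > 1 else float("nan"),
            "n_pixels": n,
        })
    return pd.DataFrame(rows)
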