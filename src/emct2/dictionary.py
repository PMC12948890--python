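"""Build the (T2, B1+) dictionary of normalized echo-modulation curves.

Every (T2, B1+) grid pair gets one EPG-simulated curve ("atom"), stored
L2-normalized so that maximum-dot-product matching equals maximum cosine
similarity regardless of per-pixel signal scale.  Default grid: T2 from
1 to 300 ms in 1 ms steps, B1+ from 60% to 140% in 1% increments, T1 fixed
at 1000 ms — 24,300 atoms for a 10-echo train.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .epg import simulate_emc_batch
from .sequence import SequenceParams

logger = logging.getLogger(__name__)

__all__ = [
    "DictionaryGrid",
    "EMCDictionary",
    "build_grid",
    "build_dictionary",
    "save_dictionary",
    "load_dictionary",
]


@dataclass(frozen=True)
class DictionaryGrid:
    """Strictly increasing T2 (ms) and B1+ (fraction) grids, T1 fixed."""

    t2_values: np.ndarray
    b1_values: np.ndarray
    t1_ms: float = 1000.0

    def __post_init__(self) -> None:
        t2 = np.asarray(self.t2_values, dtype=float)
        b1 = np.asarray(self.b1_values, dtype=float)
        if t2.ndim != 1 or b1.ndim != 1 or t2.size == 0 or b1.size == 0:
            raise ValueError("grids must be non-empty 1-D arrays")
        if t2.size > 1 and not np.all(np.diff(t2) > 0):
            raise ValueError("t2_values must be strictly increasing")
        if b1.size > 1 and not np.all(np.diff(b1) > 0):
            raise ValueError("b1_values must be strictly increasing")
        if t2[0] <= 0 or self.t1_ms <= 0:
            raise ValueError("relaxation times must be positive")
        object.__setattr__(self, "t2_values", t2)
        object.__setattr__(self, "b1_values", b1)

    @property
    def n_atoms(self) -> int:
        return self.t2_values.size * self.b1_values.size


@dataclass(frozen=True)
class EMCDictionary:
    """Flat matrix of unit-norm atoms plus per-atom (T2, B1+) index vectors.

    Atoms are ordered so that ``argmax`` over scores implements the matching
    tie-break rule: primary key ascending T2, secondary key B1 closeness to
    1.00 (then ascending B1).
    """

    atoms: np.ndarray       # (n_atoms, n_used_echoes), rows unit L2 norm
    t2_index: np.ndarray    # (n_atoms,) ms
    b1_index: np.ndarray    # (n_atoms,) fraction
    grid: DictionaryGrid
    seq: SequenceParams
    skip_first_echo: bool = False
    norm_kind: str = "l2"

    @property
    def n_atoms(self) -> int:
        return self.atoms.shape[0]

    @property
    def n_used_echoes(self) -> int:
        return self.atoms.shape[1]

    def content_hash(self) -> str:
        return _content_hash(self.grid, self.seq, self.skip_first_echo)


def _grid_axis(lo: float, hi: float, step: float, name: str) -> np.ndarray:
    if step <= 0:
        raise ValueError(f"{name} step must be positive, got {step}")
    if lo > hi:
        raise ValueError(f"{name} range inverted: {lo} > {hi}")
    span = hi - lo
    n_steps = span / step
    if abs(n_steps - round(n_steps)) > 1e-9 * max(1.0, abs(n_steps)):
        raise ValueError(
            f"{name} range ({lo}..{hi}) is not divisible by step {step}"
        )
    n = int(round(n_steps)) + 1
    return lo + step * np.arange(n)


def build_grid(
    t2_min: float = 1.0,
    t2_max: float = 300.0,
    t2_step: float = 1.0,
    b1_min: float = 0.60,
    b1_max: float = 1.40,
    b1_step: float = 0.01,
    t1: float = 1000.0,
) -> DictionaryGrid:
    """Inclusive-endpoint dictionary grid; refuses non-divisible ranges.

    Defaults give 300 T2 values and 81 B1+ values (24,300 pairs).
    """
    return DictionaryGrid(
        t2_values=_grid_axis(t2_min, t2_max, t2_step, "t2"),
        b1_values=_grid_axis(b1_min, b1_max, b1_step, "b1"),
        t1_ms=t1,
    )


def _content_hash(grid: DictionaryGrid, seq: SequenceParams, skip_first: bool) -> str:
    payload = {
        "t2_values": np.round(grid.t2_values, 9).tolist(),
        "b1_values": np.round(grid.b1_values, 9).tolist(),
        "t1_ms": grid.t1_ms,
        "seq": seq.to_config(),
        "skip_first_echo": bool(skip_first),
    }
    return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()


def build_dictionary(
    grid: DictionaryGrid,
    seq: SequenceParams,
    cache_dir: str | Path | None = None,
    skip_first_echo: bool = False,
) -> EMCDictionary:
    """Simulate and L2-normalize one atom per (T2, B1+) grid pair.

    Deterministic; when ``cache_dir`` is given, the atom matrix is cached on
    disk keyed by a content hash of the grid and sequence parameters (an I/O
    failure degrades to a warning, the in-memory result is still returned).
    ``skip_first_echo`` drops echo 1 from the atoms (and matching must then
    drop it from the pixel series too).
    """
    key = _content_hash(grid, seq, skip_first_echo)
    cache_path = None
    if cache_dir is not None:
        cache_path = Path(cache_dir) / f"emc_dict_{key[:16]}.npz"
        if cache_path.exists():
            try:
                with np.load(cache_path) as npz:
                    return EMCDictionary(
                        atoms=npz["atoms"],
                        t2_index=npz["t2_index"],
                        b1_index=npz["b1_index"],
                        grid=grid,
                        seq=seq,
                        skip_first_echo=skip_first_echo,
                    )
            except Exception as exc:  # corrupt cache: rebuild
                logger.warning("ignoring unreadable dictionary cache %s: %s",
                               cache_path, exc)

    # atom ordering encodes the tie-break: T2 ascending, then |B1-1|, then B1
    b1 = grid.b1_values
    b1_order = np.lexsort((b1, np.abs(b1 - 1.0)))
    b1_sorted = b1[b1_order]
    t2_index = np.repeat(grid.t2_values, b1.size)
    b1_index = np.tile(b1_sorted, grid.t2_values.size)

    curves = simulate_emc_batch(
        t2_index, grid.t1_ms, b1_index, seq
    )
    if skip_first_echo:
        curves = curves[:, 1:]
    norms = np.linalg.norm(curves, axis=1, keepdims=True)
    if np.any(norms == 0):
        raise RuntimeError("encountered a zero-norm atom; grid out of physical range")
    atoms = curves / norms

    dictionary = EMCDictionary(
        atoms=atoms, t2_index=t2_index, b1_index=b1_index,
        grid=grid, seq=seq, skip_first_echo=skip_first_echo,
    )
    if cache_path is not None:
        try:
            cache_path.parent.mkdir(parents=True, exist_ok=True)
            np.savez_compressed(
                cache_path, atoms=atoms, t2_index=t2_index, b1_index=b1_index
            )
            cache_path.with_suffix(".json").write_text(json.dumps({
                "content_hash": key,
                "t1_ms": grid.t1_ms,
                "t2_range_ms": [float(grid.t2_values[0]), float(grid.t2_values[-1])],
                "b1_range": [float(b1[0]), float(b1[-1])],
                "n_atoms": int(atoms.shape[0]),
                "seq": seq.to_config(),
                "skip_first_echo": bool(skip_first_echo),
            }, indent=2))
        except OSError as exc:
            warnings.warn(f"could not write dictionary cache: {exc}")
    return dictionary


def save_dictionary(dictionary: EMCDictionary, path: str | Path) -> None:
    """Persist a dictionary as a single .npz with embedded JSON metadata."""
    meta = json.dumps({
        "t1_ms": dictionary.grid.t1_ms,
        "seq": dictionary.seq.to_config(),
        "skip_first_echo": dictionary.skip_first_echo,
        "content_hash": dictionary.content_hash(),
    })
    np.savez_compressed(
        Path(path),
        atoms=dictionary.atoms,
        t2_index=dictionary.t2_index,
        b1_index=dictionary.b1_index,
        t2_values=dictionary.grid.t2_values,
        b1_values=dictionary.grid.b1_values,
        meta=np.array(meta),
    )


def load_dictionary(path: str | Path) -> EMCDictionary:
    """Load a dictionary previously written by :func:`save_dictionary`."""
    with np.load(Path(path)) as npz:
        meta = json.loads(str(npz["meta"]))
        grid = DictionaryGrid(
            t2_values=npz["t2_values"],
            b1_values=npz["b1_values"],
            t1_ms=meta["t1_ms"],
        )
        return EMCDictionary(
            atoms=npz["atoms"],
            t2_index=npz["t2_index"],
            b1_index=npz["b1_index"],
            grid=grid,
            seq=SequenceParams.from_config(meta["seq"]),
            skip_first_echo=meta["skip_first_echo"],
        )
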