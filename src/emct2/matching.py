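"""Per-pixel T2/B1+ estimation by exhaustive dictionary matching.

Each pixel's echo series is L2-normalized and compared against every
dictionary atom by inner product; the (T2, B1+) pair of the best-scoring
atom is assigned to the pixel.  A log-linear mono-exponential fit is also
provided as the conventional baseline, which is biased in the presence of
stimulated echoes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numba
import numpy as np

from .dictionary import EMCDictionary

logger = logging.getLogger(__name__)

__all__ = [
    "ImageSeries",
    "QuantMaps",
    "match_pixel",
    "match_pixels",
    "fit_map",
    "fit_monoexponential",
]


@dataclass
class ImageSeries:
    """4-D magnitude image (X, Y, Z, echo) with its echo-time table."""

    voxels: np.ndarray
    echo_times: np.ndarray
    voxel_size_mm: tuple = (0.29, 0.29, 2.5)
    affine: np.ndarray = field(default=None)

    def __post_init__(self) -> None:
        v = np.asarray(self.voxels, dtype=float)
        te = np.asarray(self.echo_times, dtype=float)
        if v.ndim != 4:
            raise ValueError(f"voxels must be 4-D (X, Y, Z, echo), got ndim={v.ndim}")
        if v.shape[-1] != te.size:
            raise ValueError("last axis of voxels must match echo_times length")
        if np.any(v < 0):
            raise ValueError("magnitude images must be non-negative")
        self.voxels = v
        self.echo_times = te
        if self.affine is None:
            self.affine = np.eye(4)

    @property
    def spatial_shape(self) -> tuple:
        return self.voxels.shape[:3]


@dataclass
class QuantMaps:
    """Pixel-wise T2 (ms), B1+ (fraction) and match-score maps.

    Invalid voxels (outside the mask, or zero-norm series) carry NaN in all
    float maps and False in ``validity_mask``.
    """

    t2_map: np.ndarray
    b1_map: np.ndarray
    score_map: np.ndarray
    validity_mask: np.ndarray


@numba.njit(fastmath=True)
def _argmax_inner_product(atoms: np.ndarray, pixels: np.ndarray):
    """Running-max exhaustive search; returns (best index, best score).

    Equivalent to ``argmax(atoms @ pixels.T, axis=0)`` but never
    materializes the full score matrix (the atom table stays cache
    resident).  Double precision throughout: adjacent long-T2 atoms are
    nearly collinear, so single-precision scores can misrank them.
    First-maximum wins, so the atom ordering encodes the tie-break rule.
    """
    n_atoms, n_echo = atoms.shape
    n_pix = pixels.shape[0]
    best = np.empty(n_pix, np.int64)
    best_score = np.empty(n_pix, np.float64)
    for n in range(n_pix):
        bs = -2.0
        bi = 0
        for a in range(n_atoms):
            s = 0.0
            for e in range(n_echo):
                s += atoms[a, e] * pixels[n, e]
            if s > bs:
                bs = s
                bi = a
        best[n] = bi
        best_score[n] = bs
    return best, best_score


def match_pixels(series: np.ndarray,
                 dictionary: EMCDictionary) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Match many pixel series at once.

    Parameters
    ----------
    series : (n_pixels, n_echoes) array
        Magnitude echo series (full echo count; the first echo is dropped
        here if the dictionary was built with ``skip_first_echo``).
    dictionary : EMCDictionary

    Returns
    -------
    (t2, b1, score) : arrays of length n_pixels
        NaN where the series has zero norm.  Ties are broken toward the
        smallest T2, then the B1 closest to 1.00 (encoded in the atom
        ordering, so a plain first-argmax suffices).
    """
    series = np.atleast_2d(np.asarray(series, dtype=float))
    if dictionary.skip_first_echo:
        series = series[:, 1:]
    if series.shape[1] != dictionary.n_used_echoes:
        raise ValueError(
            f"echo count mismatch: series has {series.shape[1]}, "
            f"dictionary expects {dictionary.n_used_echoes}"
        )
    n = series.shape[0]
    t2 = np.full(n, np.nan)
    b1 = np.full(n, np.nan)
    score = np.full(n, np.nan)
    norms = np.linalg.norm(series, axis=1)
    idx_ok = np.flatnonzero(norms > 0)
    if idx_ok.size == 0:
        return t2, b1, score
    block = np.ascontiguousarray(series[idx_ok] / norms[idx_ok, None])
    best, best_score = _argmax_inner_product(
        np.ascontiguousarray(dictionary.atoms), block)
    t2[idx_ok] = dictionary.t2_index[best]
    b1[idx_ok] = dictionary.b1_index[best]
    score[idx_ok] = np.clip(best_score, -1.0, 1.0)  # guard float32 round-off
    return t2, b1, score


def match_pixel(p: np.ndarray, dictionary: EMCDictionary):
    """Match a single pixel series; returns ``(t2_ms, b1, score)``.

    A zero-norm series is marked invalid (all-NaN result), not an error.
    """
    t2, b1, score = match_pixels(np.asarray(p, float)[None, :], dictionary)
    return float(t2[0]), float(b1[0]), float(score[0])


def fit_map(series: ImageSeries, mask: np.ndarray,
            dictionary: EMCDictionary) -> QuantMaps:
    """Dictionary-match every masked voxel of a 4-D series.

    Deterministic; voxels outside ``mask`` stay NaN/invalid.  Progress is
    logged per slice.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != series.spatial_shape:
        raise ValueError(
            f"mask shape {mask.shape} does not match image {series.spatial_shape}"
        )
    if series.voxels.shape[-1] != dictionary.seq.n_echoes:
        raise ValueError(
            f"series has {series.voxels.shape[-1]} echoes but the dictionary "
            f"was built for {dictionary.seq.n_echoes}"
        )
    shape = series.spatial_shape
    t2_map = np.full(shape, np.nan)
    b1_map = np.full(shape, np.nan)
    score_map = np.full(shape, np.nan)
    for z in range(shape[2]):
        sl = mask[:, :, z]
        if not sl.any():
            continue
        vox = series.voxels[:, :, z, :][sl]
        t2, b1, score = match_pixels(vox, dictionary)
        t2_map[:, :, z][sl] = t2
        b1_map[:, :, z][sl] = b1
        score_map[:, :, z][sl] = score
        logger.info("matched slice %d: %d voxels", z, int(sl.sum()))
    validity = np.isfinite(t2_map)
    return QuantMaps(t2_map=t2_map, b1_map=b1_map,
                     score_map=score_map, validity_mask=validity)


def fit_monoexponential(p: np.ndarray, echo_times: np.ndarray) -> float:
    """Conventional log-linear mono-exponential T2 estimate.

    Ordinary least squares of ``log(S)`` on TE over the strictly positive
    samples; ``t2 = -1 / slope``.  Returns NaN when fewer than two positive
    samples remain or the fitted slope is non-negative (no decay).
    """
    p = np.asarray(p, dtype=float)
    te = np.asarray(echo_times, dtype=float)
    pos = p > 0
    if pos.sum() < 2:
        return float("nan")
    slope = np.polyfit(te[pos], np.log(p[pos]), 1)[0]
    if slope >= 0:
        return float("nan")
    return float(-1.0 / slope)
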