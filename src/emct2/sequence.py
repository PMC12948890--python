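"""Multi-echo spin-echo (MESE) acquisition description.

A MESE acquisition is summarized by its repetition time, echo spacing,
echo count and the nominal excitation/refocusing flip angles.  Echo times
are ``TE_n = n * echo_spacing`` for ``n = 1..n_echoes``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["SequenceParams", "echo_train"]


@dataclass(frozen=True)
class SequenceParams:
    """MESE sequence parameters.

    Parameters
    ----------
    tr_ms : float
        Repetition time in milliseconds.
    esp_ms : float
        Echo spacing in milliseconds; the first echo occurs at ``esp_ms``.
    n_echoes : int
        Number of echoes in the train (>= 2).
    exc_deg : float
        Nominal excitation flip angle in degrees (applied about x).
    refoc_deg : float
        Nominal refocusing flip angle in degrees (applied about y,
        CPMG phase convention); must lie in (0, 180].
    pulse_shape : {"hard", "shaped"}
        ``hard`` applies the nominal angle uniformly across the slice;
        ``shaped`` splits the slice into ``slice_subdivisions`` sub-slices
        whose flip angles are weighted by ``profile`` and sums their
        complex signals.
    profile : tuple of float, optional
        Relative flip-angle weighting across the slice for ``shaped``
        pulses (resampled to ``slice_subdivisions`` points).  Required
        when ``pulse_shape == "shaped"``.
    slice_subdivisions : int
        Number of sub-slices used for shaped pulses (default 15).
    """

    tr_ms: float = 2057.0
    esp_ms: float = 5.9
    n_echoes: int = 10
    exc_deg: float = 90.0
    refoc_deg: float = 125.0
    pulse_shape: str = "hard"
    profile: tuple = field(default=None)
    slice_subdivisions: int = 15

    def __post_init__(self) -> None:
        if self.esp_ms <= 0:
            raise ValueError(f"echo spacing must be positive, got {self.esp_ms}")
        if int(self.n_echoes) != self.n_echoes or self.n_echoes < 2:
            raise ValueError(f"n_echoes must be an integer >= 2, got {self.n_echoes}")
        if self.tr_ms <= 0:
            raise ValueError(f"repetition time must be positive, got {self.tr_ms}")
        if not (0.0 < self.refoc_deg <= 180.0):
            raise ValueError(
                f"refocusing angle must lie in (0, 180] degrees, got {self.refoc_deg}"
            )
        if self.pulse_shape not in ("hard", "shaped"):
            raise ValueError(f"unknown pulse_shape {self.pulse_shape!r}")
        if self.slice_subdivisions < 1:
            raise ValueError("slice_subdivisions must be >= 1")
        if self.pulse_shape == "shaped":
            if self.profile is None or len(self.profile) == 0:
                raise ValueError("shaped pulses require a flip-angle profile")
            object.__setattr__(self, "profile", tuple(float(w) for w in self.profile))

    @classmethod
    def from_config(cls, cfg: dict) -> "SequenceParams":
        """Build from a JSON/YAML config block (keys ``tr_ms``, ``esp_ms``,
        ``n_echoes``, ``exc_deg``, ``refoc_deg``, ``pulse_shape``,
        ``profile``, ``slice_subdivisions``; missing keys take defaults)."""
        known = {
            "tr_ms", "esp_ms", "n_echoes", "exc_deg", "refoc_deg",
            "pulse_shape", "profile", "slice_subdivisions",
        }
        kwargs = {k: v for k, v in cfg.items() if k in known}
        if "profile" in kwargs and kwargs["profile"] is not None:
            kwargs["profile"] = tuple(kwargs["profile"])
        return cls(**kwargs)

    def to_config(self) -> dict:
        return {
            "tr_ms": self.tr_ms,
            "esp_ms": self.esp_ms,
            "n_echoes": self.n_echoes,
            "exc_deg": self.exc_deg,
            "refoc_deg": self.refoc_deg,
            "pulse_shape": self.pulse_shape,
            "profile": list(self.profile) if self.profile else None,
            "slice_subdivisions": self.slice_subdivisions,
        }


def echo_train(seq: SequenceParams) -> np.ndarray:
    """Echo times of the MESE train in milliseconds.

    Returns ``[ESP, 2*ESP, ..., n_echoes*ESP]`` (strictly increasing).
    """
    return seq.esp_ms * np.arange(1, seq.n_echoes + 1, dtype=float)
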