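"""Core sampled-signal containers shared by every pipeline stage.

Two lightweight immutable containers carry the data through the pipeline:
:class:`SampledSignal` for a uniformly sampled real series with a physical
unit, and :class:`IQBaseband` for the paired in-phase/quadrature radar
channels sharing one sample clock.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["SampledSignal", "IQBaseband"]


def _as_finite_1d(values, name: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional, got shape {arr.shape}")
    if arr.size and not np.all(np.isfinite(arr)):
        bad = int(np.flatnonzero(~np.isfinite(arr))[0])
        raise ValueError(f"{name} contains a non-finite value at sample {bad}")
    arr.flags.writeable = False
    return arr


@dataclass(frozen=True)
class SampledSignal:
    """A uniformly sampled real-valued series.

    Parameters
    ----------
    values : array-like of float
        Sample values; must be finite.
    fs : float
        Sampling rate in Hz, strictly positive.
    unit : str
        Physical unit label of the samples (e.g. ``"m"``).
    t0 : float
        Time of the first sample in seconds.
    """

    values: np.ndarray
    fs: float
    unit: str = ""
    t0: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", _as_finite_1d(self.values, "values"))
        if not self.fs > 0:
            raise ValueError(f"fs must be positive, got {self.fs}")

    def __len__(self) -> int:
        return self.values.size

    @property
    def n(self) -> int:
        return self.values.size

    @property
    def duration(self) -> float:
        """Span covered by the samples in seconds (n / fs)."""
        return self.n / self.fs

    @property
    def times(self) -> np.ndarray:
        """Sample times ``t0 + k / fs``."""
        return self.t0 + np.arange(self.n) / self.fs

    def with_values(self, values, unit: str | None = None) -> "SampledSignal":
        """Return a copy sharing the clock but carrying new samples."""
        return replace(
            self, values=np.asarray(values, dtype=float), unit=self.unit if unit is None else unit
        )

    def rms(self) -> float:
        return float(np.sqrt(np.mean(np.square(self.values)))) if self.n else 0.0


@dataclass(frozen=True)
class IQBaseband:
    """Paired in-phase / quadrature baseband channels on a shared clock."""

    i_values: np.ndarray
    q_values: np.ndarray
    fs: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "i_values", _as_finite_1d(self.i_values, "i_values"))
        object.__setattr__(self, "q_values", _as_finite_1d(self.q_values, "q_values"))
        if self.i_values.size != self.q_values.size:
            raise ValueError(
                "i and q channels must have equal length, got "
                f"{self.i_values.size} and {self.q_values.size}"
            )
        if not self.fs > 0:
            raise ValueError(f"fs must be positive, got {self.fs}")

    def __len__(self) -> int:
        return self.i_values.size

    @property
    def n(self) -> int:
        return self.i_values.size

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n) / self.fs
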