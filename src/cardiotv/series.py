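"""Containers for beat-to-beat and uniformly sampled physiological signals.

Two containers cover every signal the pipeline touches:

* :class:`BeatSeries` — irregularly sampled (time, value) pairs, one point per
  heart beat: R-R intervals (ms), systolic/diastolic pressure (mmHg),
  peripheral arterial tonometry pulse amplitude (arbitrary units).
* :class:`UniformSeries` — a uniformly sampled signal, by convention at 2 Hz
  with its time axis anchored so that ``t = 0`` is the stimulus onset.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["BeatSeries", "UniformSeries"]


@dataclass
class BeatSeries:
    """One beat-to-beat channel as (time, value) pairs.

    Parameters
    ----------
    times : array-like
        Beat times in seconds, strictly increasing.
    values : array-like
        One value per beat, finite, in ``units``.
    name : str
        Channel name, e.g. ``"RRI"`` or ``"SBP"``.
    units : str
        Physical units of ``values`` (``"ms"``, ``"mmHg"``, ``"a.u."``, ...).
    """

    times: np.ndarray
    values: np.ndarray
    name: str = ""
    units: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.ndim != 1 or self.values.ndim != 1:
            raise ValueError("times and values must be one-dimensional")
        if self.times.size != self.values.size:
            raise ValueError(
                f"times ({self.times.size}) and values ({self.values.size}) "
                "must have equal length"
            )
        if self.times.size < 2:
            raise ValueError("a beat series needs at least two beats")
        if not np.all(np.isfinite(self.times)) or not np.all(np.isfinite(self.values)):
            raise ValueError(f"non-finite entries in beat series {self.name!r}")
        if np.any(np.diff(self.times) <= 0):
            bad = int(np.argmax(np.diff(self.times) <= 0))
            raise ValueError(
                f"beat times of {self.name!r} must be strictly increasing "
                f"(violation at index {bad + 1}, t={self.times[bad + 1]:g})"
            )

    def __len__(self) -> int:
        return int(self.times.size)

    def window(self, t_lo: float, t_hi: float) -> "BeatSeries":
        """Beats with ``t_lo <= t < t_hi``."""
        mask = (self.times >= t_lo) & (self.times < t_hi)
        if mask.sum() < 2:
            raise ValueError(
                f"window [{t_lo:g}, {t_hi:g}) of {self.name!r} holds fewer than 2 beats"
            )
        return BeatSeries(self.times[mask], self.values[mask], self.name, self.units)

    @property
    def span(self) -> tuple[float, float]:
        return float(self.times[0]), float(self.times[-1])


@dataclass
class UniformSeries:
    """A uniformly sampled signal.

    ``start_time`` is in seconds relative to the stimulus onset, so sample
    ``k`` sits at ``start_time + k / fs``.
    """

    start_time: float
    fs: float
    values: np.ndarray
    name: str = ""
    units: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if self.values.ndim != 1:
            raise ValueError("values must be one-dimensional")
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"non-finite samples in uniform series {self.name!r}")

    def __len__(self) -> int:
        return int(self.values.size)

    @property
    def dt(self) -> float:
        return 1.0 / self.fs

    @property
    def times(self) -> np.ndarray:
        return self.start_time + np.arange(self.values.size) / self.fs

    @property
    def end_time(self) -> float:
        return self.start_time + (self.values.size - 1) / self.fs

    def copy_with(self, values: np.ndarray, **meta) -> "UniformSeries":
        new_meta = dict(self.meta)
        new_meta.update(meta)
        return UniformSeries(self.start_time, self.fs, np.asarray(values, float),
                             self.name, self.units, new_meta)

    def slice_time(self, t_lo: float, t_hi: float) -> "UniformSeries":
        """Samples with ``t_lo <= t < t_hi``."""
        t = self.times
        mask = (t >= t_lo) & (t < t_hi)
        if not mask.any():
            raise ValueError(f"no samples of {self.name!r} in [{t_lo:g}, {t_hi:g})")
        first = int(np.argmax(mask))
        return UniformSeries(float(t[first]), self.fs, self.values[mask],
                             self.name, self.units, dict(self.meta))
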