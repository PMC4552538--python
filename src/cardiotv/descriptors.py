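"""Kernel tracks -> transfer-function gains; signals -> time-varying spectra.

Three frequency bands are used throughout, following heart-rate-variability
convention: LF 0.04-0.15 Hz, HF 0.15-0.4 Hz, and the overall range
0.04-0.4 Hz.  Band edges are half-open ``[lo, hi)`` so LF and HF tile the
overall band without double-counting a bin.

* :func:`transfer_gains` turns a time-varying kernel into LF/HF/overall gain
  time courses: at each time step the kernel (50 lags, 0.5 s) is zero-padded
  to 256 points, Fourier transformed, and ``|H|`` averaged over the band bins.
* :func:`tv_psd` tracks a time-varying autoregressive model of a fluctuation
  signal with the same RLS + AAFT-stabilization machinery as the kernel fits
  and integrates the AR spectrum over the LF and HF bands (LFP, HFP; their
  ratio is the classic sympathovagal-balance index for R-R intervals).
* :func:`bin_summaries` produces the half-minute summary table: a baseline
  window (default 1-4 min before stimulus onset) and four half-minute bins
  from the onset, with change-from-baseline columns.
* :func:`relative_gain` rescales a gain track by its baseline summary — the
  only meaningful form for the PAT-amplitude branches, whose absolute scale
  is arbitrary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .branches import BRANCHES, DT, FS
from .estimator import KernelTrack, aaft_surrogate, rls_track
from .series import UniformSeries

__all__ = [
    "BANDS",
    "DEFAULT_BINS",
    "DescriptorTrack",
    "SpectralIndexTrack",
    "band_gains",
    "transfer_gains",
    "tv_psd",
    "bin_summaries",
    "relative_gain",
]

log = logging.getLogger(__name__)

BANDS: dict[str, tuple[float, float]] = {
    "lf": (0.04, 0.15),
    "hf": (0.15, 0.4),
    "overall": (0.04, 0.4),
}

#: label -> (t_lo, t_hi) in seconds relative to stimulus onset
DEFAULT_BINS: dict[str, tuple[float, float]] = {
    "baseline": (-240.0, -60.0),
    "0-0.5min": (0.0, 30.0),
    "0.5-1min": (30.0, 60.0),
    "1-1.5min": (60.0, 90.0),
    "1.5-2min": (90.0, 120.0),
}

NFFT = 256


@dataclass
class DescriptorTrack:
    """LF/HF/overall transfer-gain time courses for one branch."""

    branch: str
    time: np.ndarray
    lf: np.ndarray
    hf: np.ndarray
    overall: np.ndarray
    units: str = ""
    relative: bool = False

    def band(self, name: str) -> np.ndarray:
        return {"lf": self.lf, "hf": self.hf, "overall": self.overall}[name]


@dataclass
class SpectralIndexTrack:
    """Time-varying band powers of one fluctuation signal."""

    name: str
    time: np.ndarray
    freqs: np.ndarray
    psd: np.ndarray          # (T, F), one-sided, signal-units^2 / Hz
    lfp: np.ndarray
    hfp: np.ndarray

    @property
    def lhr(self) -> np.ndarray:
        out = np.full_like(self.lfp, np.nan)
        ok = self.hfp > 0
        out[ok] = self.lfp[ok] / self.hfp[ok]
        return out


def _band_bins(freqs: np.ndarray, band: tuple[float, float], fs: float) -> np.ndarray:
    lo, hi = band
    if not (0.0 < lo < hi <= fs / 2):
        raise ValueError(f"band [{lo:g}, {hi:g}) Hz outside (0, {fs / 2:g}] Hz")
    mask = (freqs >= lo) & (freqs < hi)
    if not mask.any():
        raise ValueError(
            f"band [{lo:g}, {hi:g}) Hz contains no DFT bin; increase the FFT "
            f"padding (resolution {freqs[1] - freqs[0]:g} Hz)")
    return mask


def band_gains(kernels: np.ndarray, fs: float = FS, nfft: int = NFFT,
               bands: dict | None = None) -> dict:
    """Mean ``|H|`` per band for one kernel or a (T, M) kernel track."""
    kernels = np.asarray(kernels, dtype=float)
    H = np.abs(np.fft.rfft(kernels, nfft, axis=-1))
    freqs = np.fft.rfftfreq(nfft, 1.0 / fs)
    out = {}
    for name, band in (bands or BANDS).items():
        mask = _band_bins(freqs, band, fs)
        out[name] = H[..., mask].mean(axis=-1)
    return out


def transfer_gains(track: KernelTrack, fs: float = FS, nfft: int = NFFT,
                   bands: dict | None = None) -> dict:
    """Per-branch LF/HF/overall gain time courses of a fitted kernel track."""
    out = {}
    for branch, kern in track.kernels.items():
        g = band_gains(kern, fs, nfft, bands)
        out[branch] = DescriptorTrack(
            branch, track.time, g["lf"], g["hf"], g["overall"],
            units=BRANCHES[branch].gain_units if branch in BRANCHES else "")
    return out


# ---------------------------------------------------------------------------
# time-varying AR spectra


def tv_psd(series: UniformSeries, ar_order: int = 8, lam: float = 0.97,
           n_surrogates: int = 50, rng: np.random.Generator | int = 0,
           nfft: int = NFFT) -> SpectralIndexTrack:
    """Time-varying power spectral density via an RLS-tracked AR model.

    The signal is modelled as ``y(t) = sum_k a_k(t) y(t-k) + e(t)``; the
    coefficients are tracked by forgetting-factor RLS and stabilized by the
    AAFT surrogate procedure (elementwise median of the coefficient tracks
    over ``n_surrogates`` refits; 0 disables stabilization).  The one-sided
    spectrum at each step is the AR spectrum with an exponentially weighted
    innovation-variance estimate; steps whose AR polynomial is unstable are
    masked.  LFP and HFP integrate the spectrum over the LF and HF bands.
    """
    if ar_order < 2:
        raise ValueError("AR order must be >= 2")
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    y = series.values - np.mean(series.values)  # no intercept in the AR model
    n = y.size
    if n <= 4 * ar_order:
        raise ValueError("record too short for the requested AR order")
    X = np.zeros((n, ar_order))
    for k in range(1, ar_order + 1):
        X[k:, k - 1] = y[:-k]
    valid = np.zeros(n, dtype=bool)
    valid[ar_order:] = True

    theta0, resid, pred = rls_track(y, X, valid, lam)
    tracks = [theta0]
    rows = np.flatnonzero(valid)
    for _ in range(n_surrogates):
        y_k = y.copy()
        y_k[rows] = pred + aaft_surrogate(resid, rng)
        theta_k, _, _ = rls_track(y_k, X, valid, lam)
        tracks.append(theta_k)
    theta = (np.median(np.stack(tracks[1:]), axis=0) if n_surrogates > 0
             else theta0)

    # exponentially weighted innovation variance, matching the RLS memory;
    # the first RLS convergence steps are excluded (their one-step errors
    # reflect the zero initialization, not the innovations)
    skip = min(max(4 * ar_order, 32), rows.size // 4)
    sig2 = np.empty(rows.size)
    acc = float(np.mean(resid[skip: skip + max(4 * ar_order, 32)] ** 2))
    sig2[:skip] = acc
    for j in range(skip, rows.size):
        e = resid[j]
        acc = (lam * acc + (1.0 - lam) * e * e if lam < 1.0
               else acc + (e * e - acc) / (j - skip + 1))
        sig2[j] = acc

    freqs = np.fft.rfftfreq(nfft, 1.0 / series.fs)
    # |A(f)|^2 for all steps at once: A = 1 - sum_k a_k exp(-i 2 pi f k dt)
    A = 1.0 - np.tensordot(theta, np.exp(
        -2j * np.pi * np.arange(1, ar_order + 1)[:, None] * freqs[None, :] / series.fs),
        axes=(1, 0))
    dt = 1.0 / series.fs
    psd = 2.0 * sig2[:, None] * dt / np.abs(A) ** 2

    # mask steps with an unstable AR polynomial
    unstable = np.zeros(rows.size, dtype=bool)
    for j in range(rows.size):
        roots = np.roots(np.concatenate([[1.0], -theta[j]]))
        if roots.size and np.max(np.abs(roots)) >= 1.0:
            unstable[j] = True
    if unstable.any():
        log.info("tv_psd: masking %d unstable steps of %s", int(unstable.sum()),
                 series.name)
        psd[unstable] = np.nan

    lf_mask = _band_bins(freqs, BANDS["lf"], series.fs)
    hf_mask = _band_bins(freqs, BANDS["hf"], series.fs)
    lfp = np.trapezoid(psd[:, lf_mask], freqs[lf_mask], axis=1)
    hfp = np.trapezoid(psd[:, hf_mask], freqs[hf_mask], axis=1)
    return SpectralIndexTrack(series.name, series.times[valid], freqs, psd, lfp, hfp)


# ---------------------------------------------------------------------------
# binned summaries


def bin_summaries(series_map: dict, stats: dict | None = None,
                  bins: dict | None = None) -> pd.DataFrame:
    """Half-minute summary table with change-from-baseline columns.

    ``series_map`` maps variable name to ``(time, values)`` with time in
    seconds relative to stimulus onset.  ``stats`` maps variable name to
    ``"median"`` (physiological measurements, the default) or ``"mean"``
    (spectral indices and gains).  Bins not covered by a track yield NaN.
    """
    bins = bins or DEFAULT_BINS
    if "baseline" not in bins:
        raise ValueError("bins must include a 'baseline' window")
    stats = stats or {}
    rows = []
    for var, (time, values) in series_map.items():
        time = np.asarray(time, float)
        values = np.asarray(values, float)
        stat = stats.get(var, "median")
        agg = np.nanmedian if stat == "median" else np.nanmean
        summaries = {}
        for label, (lo, hi) in bins.items():
            mask = (time >= lo) & (time < hi) & np.isfinite(values)
            summaries[label] = float(agg(values[mask])) if mask.any() else np.nan
        base = summaries["baseline"]
        for label, (lo, hi) in bins.items():
            rows.append({"variable": var, "bin": label, "t_lo_s": lo, "t_hi_s": hi,
                         "stat": stat, "value": summaries[label],
                         "delta_from_baseline": summaries[label] - base})
    return pd.DataFrame(rows)


def relative_gain(track: DescriptorTrack, baseline_window: tuple[float, float]
                  = DEFAULT_BINS["baseline"], mode: str = "ratio") -> DescriptorTrack:
    """Gain track normalized against its baseline-window mean.

    ``mode="ratio"`` divides by the baseline mean (requires a positive
    baseline); ``mode="diff"`` subtracts it.  The output is flagged relative:
    appropriate whenever the underlying signal has arbitrary units (PATampN).
    """
    lo, hi = baseline_window
    mask = (track.time >= lo) & (track.time < hi)
    if not mask.any():
        raise ValueError(f"gain track does not cover the baseline [{lo:g}, {hi:g}) s")
    out = {}
    for band in ("lf", "hf", "overall"):
        vals = track.band(band)
        base = float(np.nanmean(vals[mask]))
        if mode == "ratio":
            if base <= 0:
                raise ValueError(f"non-positive baseline {band} gain ({base:g})")
            out[band] = vals / base
        elif mode == "diff":
            out[band] = vals - base
        else:
            raise ValueError(f"unknown mode {mode!r}")
    return replace(track, lf=out["lf"], hf=out["hf"], overall=out["overall"],
                   units="baseline-relative" if mode == "ratio" else track.units,
                   relative=True)
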