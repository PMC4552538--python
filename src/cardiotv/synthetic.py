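"""Synthetic beat-to-beat cardiorespiratory recordings with known ground truth.

No subject recordings ship with this package, so every downstream stage is
exercised on generated records that mimic the study protocol: ~10 min of
quiet rest, a 60 s cold-face stimulus, and ~10 min of recovery.  The
generator draws

* an LF-dominant (Mayer-wave-like, ~0.1 Hz) blood-pressure fluctuation,
* a respiratory-band tidal-volume fluctuation (narrowband around the
  breathing frequency, default 0.25 Hz),

feeds them through known per-branch convolution kernels (optionally switching
at stimulus onset, mimicking autonomic gain changes), adds output noise and
slow polynomial drifts, and finally converts the uniform signals into
beat-to-beat series so the whole preprocessing path is exercised end-to-end.

A note on units: the peripheral-resistance branches (BPC, RPC) produce
*normalized* PAT-amplitude fluctuations.  The PATamp channel is emitted in
arbitrary units through an affine map (baseline mean/SD configurable); the
preprocessing normalization divides by the realized baseline SD, so absolute
BPC/RPC kernel scales are only recoverable up to that factor — exactly why
those gains are analysed as changes relative to baseline.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy.signal import lfilter

from .branches import BRANCHES, DT, FS, MEMORY, check_delay, delay_to_samples
from .series import BeatSeries, UniformSeries
from . import meixner

__all__ = [
    "InputSpec",
    "BranchTruth",
    "GroundTruth",
    "SyntheticSubject",
    "generate_inputs",
    "synthesize_outputs",
    "to_beat_series",
    "make_subject",
    "default_truth",
    "write_subject",
    "read_subject",
]


@dataclass
class InputSpec:
    """Spectral description of the exogenous inputs.

    Pressure fluctuations are an AR(2) resonator (poles at radius
    ``pressure_pole_radius``, resonance ``pressure_peak_hz``) driven by white
    noise, scaled to ``pressure_sd`` mmHg — a Mayer-wave-like LF process.
    Tidal-volume fluctuations use the same construction centred at the
    breathing frequency, giving breath-to-breath variability rather than a
    pure tone.
    """

    pressure_sd: float = 4.0          # mmHg
    pressure_peak_hz: float = 0.10
    pressure_pole_radius: float = 0.95
    breath_hz: float = 0.25           # breaths/s, must sit in the HF band
    breath_sd: float = 0.25           # L
    breath_pole_radius: float = 0.85  # breath-to-breath variability bandwidth
    dbp_ratio: float = 0.7            # diastolic fluctuation per unit systolic

    def validate(self, fs: float = FS) -> None:
        if not (0.0 < self.breath_hz < fs / 2):
            raise ValueError(
                f"breathing frequency {self.breath_hz:g} Hz outside (0, {fs / 2:g}) Hz"
            )
        if not (0.15 <= self.breath_hz <= 0.4):
            raise ValueError(
                "breathing frequency must lie in the 0.15-0.4 Hz respiratory band "
                f"(got {self.breath_hz:g} Hz)"
            )
        if self.pressure_sd < 0 or self.breath_sd < 0:
            raise ValueError("input amplitudes must be >= 0")


@dataclass
class BranchTruth:
    """Piecewise-constant kernel schedule and latency for one branch.

    ``kernels`` holds one or more length-M kernels; ``switch_times`` (seconds
    relative to stimulus onset) give the instants at which the active kernel
    advances to the next entry.
    """

    kernels: list
    delay_s: float
    switch_times: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.kernels = [np.asarray(k, dtype=float) for k in self.kernels]
        for k in self.kernels:
            if k.shape != (MEMORY,):
                raise ValueError(f"each kernel must have {MEMORY} lags, got {k.shape}")
        if len(self.switch_times) != len(self.kernels) - 1:
            raise ValueError("need exactly one switch time between consecutive kernels")
        if list(self.switch_times) != sorted(self.switch_times):
            raise ValueError("switch times must be sorted")

    def kernel_at(self, t_rel_onset: float) -> np.ndarray:
        idx = int(np.searchsorted(np.asarray(self.switch_times, float), t_rel_onset,
                                  side="right"))
        return self.kernels[idx]


@dataclass
class GroundTruth:
    """Everything needed to synthesize one subject and to verify estimates."""

    branches: dict
    input_spec: InputSpec = field(default_factory=InputSpec)
    noise_sd: dict = field(default_factory=dict)   # per output: dRRI (ms), dPATampN
    mean_levels: dict = field(default_factory=lambda: {
        "RRI": 900.0, "SBP": 120.0, "DBP": 75.0,
        "PATamp_mean": 100.0, "PATamp_sd": 20.0, "VT": 0.5,
    })
    trend_coeffs: dict = field(default_factory=lambda: {
        # slow drift c0 + c1*x + c2*x^2, x = t/duration in [0, 1]
        "RRI": [0.0, 25.0, -15.0],      # ms
        "SBP": [0.0, 4.0, -2.0],        # mmHg
        "DBP": [0.0, 2.0, -1.0],        # mmHg
        "PATampN": [0.0, 0.4, -0.25],   # z-units
        "VT": [0.0, 0.05, -0.03],       # L
    })
    seed: int = 0

    def __post_init__(self) -> None:
        for name, bt in self.branches.items():
            if name not in BRANCHES:
                raise ValueError(f"unknown branch {name!r}")
            check_delay(name, bt.delay_s)
        for ch, sd in self.noise_sd.items():
            if sd < 0:
                raise ValueError(f"noise SD for {ch} must be >= 0")
        self.input_spec.validate()
        rri = self.mean_levels["RRI"]
        if not (300.0 <= rri <= 2000.0):
            raise ValueError(f"mean RRI {rri:g} ms outside the physiologic 300-2000 ms")


@dataclass
class SyntheticSubject:
    """One generated recording: beat channels, raw tidal volume, onset, truth."""

    channels: dict                 # name -> BeatSeries (RRI, SBP, DBP, PATamp)
    tidal_volume: UniformSeries    # raw respiratory signal (absolute time axis)
    cfs_onset: float               # seconds from record start
    truth: GroundTruth | None = None


def _ar2_resonator(peak_hz: float, radius: float, n: int, fs: float,
                   rng: np.random.Generator) -> np.ndarray:
    """Unit-variance narrowband Gaussian noise with an AR(2) resonance."""
    theta = 2.0 * np.pi * peak_hz / fs
    a1, a2 = 2.0 * radius * np.cos(theta), -radius * radius
    warm = int(round(20.0 / (1.0 - radius)))  # let the filter state settle
    w = rng.standard_normal(n + warm)
    y = lfilter([1.0], [1.0, -a1, -a2], w)[warm:]
    sd = float(np.std(y))
    return y / sd if sd > 0 else y


def generate_inputs(input_spec: InputSpec, duration_s: float, fs_hz: float = FS,
                    rng_seed: int | np.random.Generator = 0):
    """Draw the exogenous input fluctuations.

    Returns ``(dSBP, dVT)`` as zero-mean :class:`UniformSeries` on an absolute
    time axis starting at 0: an LF-dominant pressure fluctuation (mmHg) and a
    respiratory-band tidal-volume fluctuation (L).
    """
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    input_spec.validate(fs_hz)
    rng = (rng_seed if isinstance(rng_seed, np.random.Generator)
           else np.random.default_rng(rng_seed))
    n = int(round(duration_s * fs_hz))
    if input_spec.pressure_sd > 0:
        dsbp = input_spec.pressure_sd * _ar2_resonator(
            input_spec.pressure_peak_hz, input_spec.pressure_pole_radius, n, fs_hz, rng)
    else:
        dsbp = np.zeros(n)
    if input_spec.breath_sd > 0:
        dvt = input_spec.breath_sd * _ar2_resonator(
            input_spec.breath_hz, input_spec.breath_pole_radius, n, fs_hz, rng)
    else:
        dvt = np.zeros(n)
    return (UniformSeries(0.0, fs_hz, dsbp, "dSBP", "mmHg"),
            UniformSeries(0.0, fs_hz, dvt, "dVT", "L"))


def _convolve_tv(branch: str, bt: BranchTruth, u: np.ndarray, t_rel: np.ndarray) -> np.ndarray:
    """y[t] = sum_i h(t, i) u[t - i - d] with a piecewise-constant kernel."""
    d = delay_to_samples(bt.delay_s)
    n = u.size
    if n < MEMORY + abs(d):
        raise ValueError(
            f"{branch}: input length {n} shorter than memory + |delay| "
            f"({MEMORY} + {abs(d)})"
        )
    out = np.zeros(n)
    segments = [-np.inf, *bt.switch_times, np.inf]
    for k, kern in enumerate(bt.kernels):
        mask = (t_rel >= segments[k]) & (t_rel < segments[k + 1])
        if not mask.any():
            continue
        conv = np.convolve(u, kern)          # conv[t] = sum_i kern[i] u[t - i]
        shifted = np.zeros(n)
        idx = np.arange(n) - d
        ok = (idx >= 0) & (idx < conv.size)
        shifted[ok] = conv[idx[ok]]
        out[mask] = shifted[mask]
    return out


def synthesize_outputs(truth: GroundTruth, dsbp: UniformSeries, dvt: UniformSeries,
                       onset_s: float, rng: np.random.Generator | None = None):
    """Forward-simulate the two MISO models.

    Returns ``(outputs, warmup)`` where ``outputs`` maps ``dRRI`` (ms) and
    ``dPATampN`` (z-units) to fluctuation arrays on the input grid, and
    ``warmup`` is a boolean mask flagging the first ``memory + max delay``
    samples whose convolution sums read before the record start.
    """
    if dsbp.fs != dvt.fs or len(dsbp) != len(dvt):
        raise ValueError("input series must share one grid")
    fs = dsbp.fs
    t_rel = dsbp.times - onset_s
    dmap = dsbp.values / 3.0 + 2.0 * (truth.input_spec.dbp_ratio * dsbp.values) / 3.0

    inputs = {"ABR": dsbp.values, "RCC": dvt.values, "BPC": dmap, "RPC": dvt.values}
    sums = {"dRRI": ("ABR", "RCC"), "dPATampN": ("BPC", "RPC")}
    outputs: dict[str, np.ndarray] = {}
    max_delay = 0
    for out_name, branch_names in sums.items():
        acc = np.zeros(len(dsbp))
        used = False
        for bname in branch_names:
            if bname in truth.branches:
                bt = truth.branches[bname]
                acc += _convolve_tv(bname, bt, inputs[bname], t_rel)
                max_delay = max(max_delay, delay_to_samples(bt.delay_s))
                used = True
        if used or out_name in truth.noise_sd:
            sd = truth.noise_sd.get(out_name, 0.0)
            if sd > 0:
                if rng is None:
                    rng = np.random.default_rng(truth.seed)
                acc = acc + sd * rng.standard_normal(acc.size)
            outputs[out_name] = acc
    warmup = np.zeros(len(dsbp), dtype=bool)
    warmup[: MEMORY + max_delay] = True
    return outputs, warmup


def to_beat_series(rri: UniformSeries, other: dict, start_time: float | None = None):
    """Convert uniform signals into beat-to-beat series.

    Beat times follow the integrate-to-threshold convention: the interval
    started at beat ``t_k`` equals the local R-R interval signal value,
    ``t_{k+1} = t_k + RRI(t_k) / 1000``.  The R-R value is recorded *at the
    interval's starting beat*, so resampling the beat series recovers the
    uniform signal to within interpolation error.  Other channels are sampled
    at the beat times.
    """
    rri_t, rri_v = rri.times, rri.values
    if np.any(rri_v <= 0):
        bad = int(np.argmax(rri_v <= 0))
        raise ValueError(f"nonpositive R-R interval at t={rri_t[bad]:g} s")
    mean_rri = float(np.mean(rri_v))
    if not (300.0 <= mean_rri <= 2000.0):
        raise ValueError(f"mean RRI {mean_rri:g} ms outside the physiologic range")

    t = rri.start_time if start_time is None else start_time
    end = rri.end_time
    times, values = [], []
    while t <= end:
        v = float(np.interp(t, rri_t, rri_v))
        times.append(t)
        values.append(v)
        t += v / 1000.0
    times = np.asarray(times)
    values = np.asarray(values)
    channels = {"RRI": BeatSeries(times, values, "RRI", "ms")}
    for name, series in other.items():
        channels[name] = BeatSeries(
            times, np.interp(times, series.times, series.values), name, series.units)
    return channels


def default_truth(seed: int = 0, *, pole: float = 0.9,
                  stimulus_gain: dict | None = None) -> GroundTruth:
    """A physiologically plausible ground truth with dictionary-built kernels.

    Every kernel is a fixed linear combination of Meixner functions so the
    estimator's search grid contains the generating structure.  Typical scales:
    baroreflex ~5 ms/mmHg, respiratory sinus arrhythmia ~40 ms/L.

    ``stimulus_gain`` maps branch names to ``(factor, end_s)``: during the
    stimulus window ``[0, end_s)`` the branch kernel is scaled by ``factor``
    and restored afterwards — a transient autonomic gain change.
    """
    def kern(gen, coeffs):
        import warnings as _warnings
        with _warnings.catch_warnings():
            # the default dictionaries are truncated at 50 lags by design
            _warnings.filterwarnings("ignore", message="basis truncation drift")
            basis = meixner.meixner_basis(pole, gen, len(coeffs))
        return basis.reconstruct(np.asarray(coeffs, float))

    base = {
        "ABR": (kern(1, [6.0, -4.0, 2.0]), 1.0),
        "RCC": (kern(0, [30.0, -15.0, 8.0]), -1.0),
        "BPC": (kern(2, [-0.09, 0.05, -0.02]), 4.0),
        "RPC": (kern(2, [-0.9, 0.5, -0.2]), 1.0),
    }
    branches = {}
    stimulus_gain = stimulus_gain or {}
    for name, (k, delay) in base.items():
        if name in stimulus_gain:
            factor, end_s = stimulus_gain[name]
            branches[name] = BranchTruth([k, factor * k, k], delay,
                                         switch_times=[0.0, end_s])
        else:
            branches[name] = BranchTruth([k], delay)
    return GroundTruth(branches=branches, seed=seed)


def make_subject(truth: GroundTruth, *, pre_s: float = 600.0, stim_s: float = 60.0,
                 post_s: float = 600.0, fs: float = FS, vt_raw_fs: float = 10.0,
                 snr: float | None = 10.0) -> SyntheticSubject:
    """Simulate one full recording around a cold-face stimulus.

    ``snr`` (output-variance / noise-variance) overrides ``truth.noise_sd``
    when given: the noise SD of each output channel is set from the realized
    noise-free output variance.  Pass ``snr=None`` to use ``truth.noise_sd``
    as-is (absent entries mean noise-free).
    """
    duration = pre_s + stim_s + post_s
    if pre_s < 60.0 + MEMORY * DT:
        raise ValueError("pre-stimulus rest too short for baseline windows and warm-up")
    ss = np.random.SeedSequence(truth.seed)
    rng_in, rng_noise, _ = [np.random.default_rng(s) for s in ss.spawn(3)]

    dsbp, dvt = generate_inputs(truth.input_spec, duration, fs, rng_in)
    clean, _ = synthesize_outputs(truth, dsbp, dvt, pre_s, rng=None)

    if snr is not None:
        noise_sd = {ch: float(np.std(v)) / np.sqrt(snr) for ch, v in clean.items()}
    else:
        noise_sd = dict(truth.noise_sd)
    outputs = {ch: v + noise_sd.get(ch, 0.0) * rng_noise.standard_normal(v.size)
               for ch, v in clean.items()}
    truth.noise_sd = noise_sd

    t = dsbp.times
    x = t / duration
    lv = truth.mean_levels

    def trend(name):
        c = truth.trend_coeffs.get(name, [0.0])
        return np.polynomial.polynomial.polyval(x, c)

    rri_u = UniformSeries(0.0, fs, lv["RRI"] + outputs["dRRI"] + trend("RRI"),
                          "RRI", "ms")
    sbp_u = UniformSeries(0.0, fs, lv["SBP"] + dsbp.values + trend("SBP"),
                          "SBP", "mmHg")
    dbp_u = UniformSeries(
        0.0, fs,
        lv["DBP"] + truth.input_spec.dbp_ratio * dsbp.values + trend("DBP"),
        "DBP", "mmHg")
    pat_u = UniformSeries(
        0.0, fs,
        lv["PATamp_mean"] + lv["PATamp_sd"] * (outputs["dPATampN"] + trend("PATampN")),
        "PATamp", "a.u.")
    channels = to_beat_series(rri_u, {"SBP": sbp_u, "DBP": dbp_u, "PATamp": pat_u})

    vt_2hz = lv["VT"] + dvt.values + trend("VT")
    t_raw = np.arange(0.0, t[-1] + 1e-9, 1.0 / vt_raw_fs)
    from scipy.interpolate import CubicSpline
    vt_raw = UniformSeries(0.0, vt_raw_fs, CubicSpline(t, vt_2hz)(t_raw), "VT", "L")

    return SyntheticSubject(channels=channels, tidal_volume=vt_raw,
                            cfs_onset=pre_s, truth=truth)


# ---------------------------------------------------------------------------
# plain-text persistence: one CSV per channel plus JSON sidecars


def write_subject(subject: SyntheticSubject, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {"cfs_onset_s": subject.cfs_onset, "beat_channels": [],
                "uniform_channels": []}
    for name, bs in subject.channels.items():
        path = outdir / f"{name}.csv"
        np.savetxt(path, np.column_stack([bs.times, bs.values]), delimiter=",",
                   header="time_s,value", comments="", fmt="%.9g")
        manifest["beat_channels"].append(
            {"name": name, "units": bs.units, "file": path.name})
    vt = subject.tidal_volume
    np.savetxt(outdir / "VT.csv", np.column_stack([vt.times, vt.values]),
               delimiter=",", header="time_s,value", comments="", fmt="%.9g")
    manifest["uniform_channels"].append(
        {"name": "VT", "units": vt.units, "file": "VT.csv", "fs_hz": vt.fs})
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    if subject.truth is not None:
        (outdir / "truth.json").write_text(json.dumps(_truth_to_json(subject.truth),
                                                      indent=2))


def _truth_to_json(truth: GroundTruth) -> dict:
    return {
        "seed": truth.seed,
        "noise_sd": truth.noise_sd,
        "mean_levels": truth.mean_levels,
        "trend_coeffs": truth.trend_coeffs,
        "input_spec": asdict(truth.input_spec),
        "branches": {
            name: {"delay_s": bt.delay_s,
                   "switch_times": list(bt.switch_times),
                   "kernels": [k.tolist() for k in bt.kernels]}
            for name, bt in truth.branches.items()
        },
    }


def _truth_from_json(blob: dict) -> GroundTruth:
    branches = {name: BranchTruth([np.asarray(k) for k in b["kernels"]],
                                  b["delay_s"], b["switch_times"])
                for name, b in blob["branches"].items()}
    return GroundTruth(branches=branches, input_spec=InputSpec(**blob["input_spec"]),
                       noise_sd=blob["noise_sd"], mean_levels=blob["mean_levels"],
                       trend_coeffs=blob["trend_coeffs"], seed=blob["seed"])


def read_subject(indir: str | Path) -> SyntheticSubject:
    indir = Path(indir)
    manifest = json.loads((indir / "manifest.json").read_text())
    channels = {}
    for entry in manifest["beat_channels"]:
        data = np.loadtxt(indir / entry["file"], delimiter=",", skiprows=1)
        channels[entry["name"]] = BeatSeries(data[:, 0], data[:, 1],
                                             entry["name"], entry["units"])
    uc = manifest["uniform_channels"][0]
    data = np.loadtxt(indir / uc["file"], delimiter=",", skiprows=1)
    vt = UniformSeries(float(data[0, 0]), uc["fs_hz"], data[:, 1], uc["name"],
                       uc["units"])
    truth = None
    if (indir / "truth.json").exists():
        truth = _truth_from_json(json.loads((indir / "truth.json").read_text()))
    return SyntheticSubject(channels=channels, tidal_volume=vt,
                            cfs_onset=manifest["cfs_onset_s"], truth=truth)
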