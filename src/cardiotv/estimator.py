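"""Time-varying MISO kernel estimation.

Two models are fitted, each a sum of two convolution branches driving one
output:

* **HRV model** — dRRI(t) = sum_i h_ABR(t,i) dSBP(t-i-tau_ABR)
  + sum_i h_RCC(t,i) dVT(t-i-tau_RCC) + eps
* **peripheral-resistance model** — dPATampN(t) = sum_i h_BPC(t,i)
  dMAP(t-i-tau_BPC) + sum_i h_RPC(t,i) dVT(t-i-tau_RPC) + eps

Each kernel spans 50 lags at 0.5 s and is expanded on a Meixner dictionary,
so only a handful of expansion coefficients are estimated.  Fitting proceeds
in four stages:

1. **Structure search** — exhaustive grid over per-branch delay, order of
   generalization and number of basis functions; each candidate is scored by
   a time-invariant least-squares fit and the minimum-description-length
   criterion ``MDL = (n/2) ln(SSR/n) + (p/2) ln(n)``; the global minimum wins
   (ties go to the earliest candidate in iteration order: branch-1 delay,
   gen order, n_funcs, then branch-2 likewise, all ascending).
2. **Forgetting-factor selection** — recursive least squares is run for each
   lambda in [0.85, 0.97]; the lambda minimizing the summed squared one-step
   prediction error over the non-warm-up region is kept.
3. **RLS tracking** — exponentially weighted recursive least squares yields
   coefficient (hence kernel) trajectories over time.
4. **Surrogate stabilization** — residuals are AAFT-randomized and added back
   to the model prediction; refitting on 50 such surrogate outputs and taking
   the elementwise median kernel damps estimation variability.

Negative delays (respiratory-cardiac coupling) are legal: estimation is
offline, so a branch may read "future" input samples.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd

from .branches import BRANCHES, DT, MEMORY, MODELS, check_delay, delay_to_samples
from .meixner import meixner_basis
from .series import UniformSeries

__all__ = [
    "BranchStructure",
    "ModelStructure",
    "KernelTrack",
    "ModelFit",
    "FitOptions",
    "branch_grid",
    "build_design",
    "mdl_score",
    "structure_search",
    "rls_track",
    "select_lambda",
    "aaft_surrogate",
    "stabilized_estimate",
    "fit_hrv_model",
    "fit_pr_model",
]

log = logging.getLogger(__name__)

LAMBDA_RANGE = (0.85, 0.97)
DEFAULT_LAMBDA_GRID = tuple(np.round(np.arange(0.85, 0.9701, 0.02), 4))
DEFAULT_POLE = 0.9
DEFAULT_INIT_SCALE = 100.0
DEFAULT_N_SURROGATES = 50


# ---------------------------------------------------------------------------
# structures


@dataclass(frozen=True)
class BranchStructure:
    """Delay and basis choice for one branch."""

    branch: str
    delay_s: float
    gen_order: int
    n_funcs: int
    pole: float = DEFAULT_POLE

    def __post_init__(self) -> None:
        spec = BRANCHES[self.branch]
        check_delay(self.branch, self.delay_s)
        g_lo, g_hi = spec.gen_order_range
        if not (g_lo <= self.gen_order <= g_hi):
            raise ValueError(
                f"{self.branch}: order of generalization {self.gen_order} outside "
                f"[{g_lo}, {g_hi}]")
        f_lo, f_hi = spec.n_funcs_range
        if not (f_lo <= self.n_funcs <= f_hi):
            raise ValueError(
                f"{self.branch}: number of basis functions {self.n_funcs} outside "
                f"[{f_lo}, {f_hi}]")

    @property
    def delay_samples(self) -> int:
        return delay_to_samples(self.delay_s)


@dataclass(frozen=True)
class ModelStructure:
    """One candidate model: two branch structures plus the forgetting factor."""

    model: str
    branches: tuple[BranchStructure, BranchStructure]
    lam: float | None = None
    memory: int = MEMORY
    dt: float = DT

    def __post_init__(self) -> None:
        if self.model not in MODELS:
            raise ValueError(f"unknown model {self.model!r}")
        expect = MODELS[self.model]
        got = tuple(b.branch for b in self.branches)
        if got != expect:
            raise ValueError(f"model {self.model!r} needs branches {expect}, got {got}")
        if self.lam is not None and self.lam != 1.0:
            lo, hi = LAMBDA_RANGE
            if not (lo <= self.lam <= hi):
                raise ValueError(
                    f"forgetting factor {self.lam:g} outside [{lo}, {hi}] "
                    "(1.0 is allowed for the growing-window mode)")

    @property
    def n_params(self) -> int:
        return sum(b.n_funcs for b in self.branches)


@dataclass
class KernelTrack:
    """Time-indexed impulse responses for one fitted model."""

    model: str
    structure: ModelStructure
    lam: float
    time: np.ndarray                 # seconds relative to onset, valid rows only
    kernels: dict                    # branch -> (T, memory)
    coeffs: dict                     # branch -> (T, n_funcs)
    residuals: np.ndarray            # one-step (a priori) prediction errors
    prediction: np.ndarray
    spread: dict | None = None       # branch -> (T, memory) interquartile range


@dataclass
class ModelFit:
    """Full provenance of one model fit."""

    model: str
    structure: ModelStructure
    lam: float
    mdl_table: pd.DataFrame
    lambda_sse: dict
    initial: KernelTrack
    stabilized: KernelTrack
    seed: int | None = None


@dataclass
class FitOptions:
    """Knobs of the full fitting pipeline."""

    profile: str = "fast"            # grid profile: "fast" or "full"
    pole: float = DEFAULT_POLE
    lambda_grid: tuple = DEFAULT_LAMBDA_GRID
    n_surrogates: int = DEFAULT_N_SURROGATES
    init_scale: float = DEFAULT_INIT_SCALE
    seed: int = 0
    refit_structure_per_surrogate: bool = False


# ---------------------------------------------------------------------------
# grids


def _float_range(lo: float, hi: float, step: float) -> tuple:
    return tuple(float(x) for x in np.round(np.arange(lo, hi + 1e-9, step), 4))


def branch_grid(branch: str, profile: str = "fast") -> dict:
    """Candidate grids for one branch.

    ``full``: the whole admissible ranges (delays on the 0.5 s grid, every
    order of generalization and basis count).  ``fast``: the same 0.5 s delay
    grid but thinned basis grids — the two smallest admissible basis counts
    and the lowest orders of generalization — keeping a structure search
    affordable at desk scale while preserving exact delay resolution.
    """
    spec = BRANCHES[branch]
    delays = _float_range(*spec.delay_range_s, DT)
    g_lo, g_hi = spec.gen_order_range
    f_lo, f_hi = spec.n_funcs_range
    if profile == "full":
        return {"delays": delays, "gen_orders": tuple(range(g_lo, g_hi + 1)),
                "n_funcs": tuple(range(f_lo, f_hi + 1))}
    if profile == "fast":
        return {"delays": delays,
                "gen_orders": tuple(range(g_lo, min(g_lo + 2, g_hi) + 1)),
                "n_funcs": tuple(range(f_lo, min(f_lo + 1, f_hi) + 1))}
    raise ValueError(f"unknown profile {profile!r}")


@lru_cache(maxsize=256)
def _basis_matrix(pole: float, gen_order: int, n_funcs: int, memory: int) -> np.ndarray:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # truncation drift is expected mid-search
        return meixner_basis(pole, gen_order, n_funcs, memory).matrix


# ---------------------------------------------------------------------------
# design matrices


def _branch_block(u: np.ndarray, basis: np.ndarray, delay_samples: int) -> np.ndarray:
    """Regressor block z[t, k] = sum_i basis[i, k] u[t - i - d] (NaN-free,
    entries outside the valid range are garbage and must be masked)."""
    n = u.size
    memory, n_funcs = basis.shape
    block = np.zeros((n, n_funcs))
    idx = np.arange(n) - delay_samples
    ok = (idx >= 0) & (idx <= n + memory - 2)
    for k in range(n_funcs):
        conv = np.convolve(u, basis[:, k])
        block[ok, k] = conv[idx[ok]]
    return block


def _branch_valid(n: int, memory: int, d: int) -> np.ndarray:
    t = np.arange(n)
    return (t >= memory - 1 + d) & (t <= n - 1 + d)


def build_design(inputs: dict, structure: ModelStructure):
    """Design matrix for one model structure.

    ``inputs`` maps branch name to its input array (2 Hz, aligned with the
    output).  Returns ``(X, valid)``: the (n, p) regressor matrix and the
    boolean mask of rows whose lagged sums lie entirely inside the record
    (the complement is the warm-up / edge region).
    """
    blocks, valids = [], []
    for bs in structure.branches:
        u = np.asarray(inputs[bs.branch], dtype=float)
        basis = _basis_matrix(bs.pole, bs.gen_order, bs.n_funcs, structure.memory)
        blocks.append(_branch_block(u, basis, bs.delay_samples))
        valids.append(_branch_valid(u.size, structure.memory, bs.delay_samples))
    X = np.hstack(blocks)
    valid = np.logical_and.reduce(valids)
    if not valid.any():
        raise ValueError("record too short: no sample has a complete lag history")
    return X, valid


# ---------------------------------------------------------------------------
# MDL and structure search


def mdl_score(ssr: float, n_samples: int, n_params: int) -> float:
    """Minimum description length for a linear regression fit (lower wins)."""
    if n_samples <= n_params:
        raise ValueError("need more samples than parameters")
    if ssr < 0:
        raise ValueError("negative sum of squared residuals")
    if ssr == 0.0:
        warnings.warn("perfect fit: MDL is -inf", stacklevel=2)
        return -np.inf
    return 0.5 * n_samples * np.log(ssr / n_samples) + 0.5 * n_params * np.log(n_samples)


def structure_search(output: np.ndarray, inputs: dict, *, model: str,
                     grids: dict | None = None, profile: str = "fast",
                     pole: float = DEFAULT_POLE, memory: int = MEMORY):
    """Exhaustive MDL search over delays, generalization orders and basis counts.

    Every candidate is fitted by time-invariant least squares on a fixed
    evaluation region (samples valid for *every* delay in the grid, so SSRs
    are comparable) and scored by MDL.  Returns ``(structure, table)`` with
    the winning :class:`ModelStructure` (lambda unset) and the full score
    table.  Rank-deficient candidates are skipped with a log entry.
    """
    b1, b2 = MODELS[model]
    y = np.asarray(output, dtype=float)
    n = y.size
    if grids is None:
        grids = {b: branch_grid(b, profile) for b in (b1, b2)}
    for b in (b1, b2):
        if not all(grids[b].get(k) for k in ("delays", "gen_orders", "n_funcs")):
            raise ValueError(f"empty grid for branch {b}")

    all_d = [delay_to_samples(d) for b in (b1, b2) for d in grids[b]["delays"]]
    eval_mask = _branch_valid(n, memory, max(max(all_d), 0)).copy()
    dmin = min(min(all_d), 0)
    if dmin < 0:
        eval_mask &= np.arange(n) <= n - 1 + dmin
    n_eval = int(eval_mask.sum())
    y_e = y[eval_mask]
    yty = float(y_e @ y_e)

    # per-branch blocks at the maximal basis count; smaller counts are column
    # prefixes because the dictionary is nested
    def blocks_for(branch):
        g = grids[branch]
        nf_max = max(g["n_funcs"])
        out = {}
        for d_s in g["delays"]:
            d = delay_to_samples(d_s)
            for gen in g["gen_orders"]:
                basis = _basis_matrix(pole, gen, nf_max, memory)
                u = np.asarray(inputs[branch], dtype=float)
                out[(d_s, gen)] = _branch_block(u, basis, d)[eval_mask]
        return out

    blocks1, blocks2 = blocks_for(b1), blocks_for(b2)
    cross: dict = {}
    g1t_y = {k: v.T @ y_e for k, v in blocks1.items()}
    g2t_y = {k: v.T @ y_e for k, v in blocks2.items()}
    g11 = {k: v.T @ v for k, v in blocks1.items()}
    g22 = {k: v.T @ v for k, v in blocks2.items()}

    rows = []
    best = None
    grid1 = list(itertools.product(grids[b1]["delays"], grids[b1]["gen_orders"],
                                   grids[b1]["n_funcs"]))
    grid2 = list(itertools.product(grids[b2]["delays"], grids[b2]["gen_orders"],
                                   grids[b2]["n_funcs"]))
    for (d1, gen1, nf1), (d2, gen2, nf2) in itertools.product(grid1, grid2):
        k1, k2 = (d1, gen1), (d2, gen2)
        if (k1, k2) not in cross:
            cross[(k1, k2)] = blocks1[k1].T @ blocks2[k2]
        G = np.block([[g11[k1][:nf1, :nf1], cross[(k1, k2)][:nf1, :nf2]],
                      [cross[(k1, k2)][:nf1, :nf2].T, g22[k2][:nf2, :nf2]]])
        c = np.concatenate([g1t_y[k1][:nf1], g2t_y[k2][:nf2]])
        p = nf1 + nf2
        try:
            theta = np.linalg.solve(G, c)
        except np.linalg.LinAlgError:
            # singular Gram matrix (e.g. a silent input channel): fall back to
            # the minimum-norm solution; skip only if that fails too
            theta = np.linalg.lstsq(G, c, rcond=None)[0]
        if not np.all(np.isfinite(theta)):
            log.info("skipping rank-deficient candidate %s",
                     (d1, gen1, nf1, d2, gen2, nf2))
            continue
        ssr = max(yty - float(theta @ c), 0.0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            score = mdl_score(ssr, n_eval, p)
        rows.append({f"{b1}_delay_s": d1, f"{b1}_gen": gen1, f"{b1}_nf": nf1,
                     f"{b2}_delay_s": d2, f"{b2}_gen": gen2, f"{b2}_nf": nf2,
                     "ssr": ssr, "mdl": score})
        if best is None or score < best[0]:
            best = (score, (d1, gen1, nf1, d2, gen2, nf2))
    if best is None:
        raise ValueError("every candidate in the grid was rank-deficient")
    d1, gen1, nf1, d2, gen2, nf2 = best[1]
    structure = ModelStructure(model, (
        BranchStructure(b1, d1, gen1, nf1, pole),
        BranchStructure(b2, d2, gen2, nf2, pole),
    ))
    return structure, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# recursive least squares


def rls_track(output: np.ndarray, X: np.ndarray, valid: np.ndarray, lam: float,
              init_scale: float = DEFAULT_INIT_SCALE):
    """Exponentially weighted RLS over the valid rows.

    Coefficients start at zero with inverse-correlation state
    ``init_scale * I`` (a weak prior; larger values approach plain least
    squares).  Returns ``(theta_track, residuals, prediction)`` where
    ``residuals`` are a priori one-step errors ``y(t) - x(t)' theta(t-1)``.

    With ``lam = 1`` the final coefficient vector equals the batch (growing
    window) least-squares solution regularized by ``I / init_scale``.
    """
    if not (0.0 < lam <= 1.0):
        raise ValueError("forgetting factor must lie in (0, 1]")
    y = np.asarray(output, dtype=float)
    rows = np.flatnonzero(valid)
    p = X.shape[1]
    theta = np.zeros(p)
    P = init_scale * np.eye(p)
    track = np.empty((rows.size, p))
    resid = np.empty(rows.size)
    pred = np.empty(rows.size)
    for j, t in enumerate(rows):
        x = X[t]
        yhat = x @ theta
        e = y[t] - yhat
        Px = P @ x
        denom = lam + x @ Px
        k = Px / denom
        theta = theta + k * e
        P = (P - np.outer(k, Px)) / lam
        P = 0.5 * (P + P.T)
        track[j] = theta
        resid[j] = e
        pred[j] = yhat
        if not np.isfinite(denom) or denom <= 0:
            raise FloatingPointError(
                f"RLS inverse-correlation state blew up at step {j} "
                f"(denominator {denom:g}); check input scaling or lambda")
    return track, resid, pred


def select_lambda(output: np.ndarray, X: np.ndarray, valid: np.ndarray,
                  lambda_grid=DEFAULT_LAMBDA_GRID,
                  init_scale: float = DEFAULT_INIT_SCALE):
    """Forgetting factor minimizing the summed squared one-step error."""
    lambda_grid = tuple(lambda_grid)
    if not lambda_grid:
        raise ValueError("empty forgetting-factor grid")
    sse = {}
    for lam in lambda_grid:
        _, resid, _ = rls_track(output, X, valid, lam, init_scale)
        sse[lam] = float(resid @ resid)
    best = min(sse, key=lambda l: sse[l])
    return best, sse


# ---------------------------------------------------------------------------
# AAFT surrogates and stabilization


def aaft_surrogate(residuals: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Amplitude-adjusted Fourier-transform surrogate of a residual series.

    The surrogate has exactly the original amplitude distribution (its sorted
    values equal the original's sorted values) and approximately the original
    magnitude spectrum, with randomized Fourier phases.
    """
    x = np.asarray(residuals, dtype=float)
    n = x.size
    if n < 8:
        raise ValueError("need at least 8 samples for an AAFT surrogate")
    if np.ptp(x) == 0.0:
        warnings.warn("constant residual series: surrogate equals the original",
                      stacklevel=2)
        return x.copy()
    order = np.argsort(x)
    ranks = np.empty(n, dtype=int)
    ranks[order] = np.arange(n)
    # 1. rank-remap onto a Gaussian reference
    gauss = np.sort(rng.standard_normal(n))
    y = gauss[ranks]
    # 2. phase-randomize (conjugate-symmetric, so the result is real)
    spec = np.fft.rfft(y)
    phases = rng.uniform(0.0, 2.0 * np.pi, spec.size)
    phases[0] = 0.0
    if n % 2 == 0:
        phases[-1] = 0.0
    randomized = np.fft.irfft(np.abs(spec) * np.exp(1j * phases), n)
    # 3. rank-remap the original amplitudes onto the randomized series
    rand_order = np.argsort(randomized)
    rand_ranks = np.empty(n, dtype=int)
    rand_ranks[rand_order] = np.arange(n)
    return np.sort(x)[rand_ranks]


def _expand_track(theta_track: np.ndarray, structure: ModelStructure):
    """Coefficient trajectories -> per-branch kernel trajectories."""
    kernels, coeffs = {}, {}
    offset = 0
    for bs in structure.branches:
        basis = _basis_matrix(bs.pole, bs.gen_order, bs.n_funcs, structure.memory)
        c = theta_track[:, offset:offset + bs.n_funcs]
        coeffs[bs.branch] = c
        kernels[bs.branch] = c @ basis.T
        offset += bs.n_funcs
    return kernels, coeffs


def _make_track(model, structure, lam, time, theta_track, resid, pred) -> KernelTrack:
    kernels, coeffs = _expand_track(theta_track, structure)
    return KernelTrack(model, structure, lam, time, kernels, coeffs, resid, pred)


def stabilized_estimate(output: np.ndarray, X: np.ndarray, valid: np.ndarray,
                        structure: ModelStructure, lam: float, *,
                        time: np.ndarray | None = None,
                        n_surrogates: int = DEFAULT_N_SURROGATES,
                        rng: np.random.Generator | int = 0,
                        init_scale: float = DEFAULT_INIT_SCALE) -> KernelTrack:
    """AAFT-surrogate stabilization of the RLS kernel track.

    The initial fit's residuals are AAFT-randomized and added back to its
    one-step prediction; coefficients are re-estimated on each of the
    ``n_surrogates`` synthetic outputs (structure and lambda held fixed) and
    the final kernel is the elementwise median over the re-estimates, with the
    interquartile range retained as an uncertainty band.
    """
    if n_surrogates < 1:
        raise ValueError("need at least one surrogate re-estimate")
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    y = np.asarray(output, dtype=float)
    rows = np.flatnonzero(valid)
    if time is None:
        time = rows.astype(float)
    theta0, resid0, pred0 = rls_track(y, X, valid, lam, init_scale)

    stacks = {bs.branch: [] for bs in structure.branches}
    for k in range(n_surrogates):
        try:
            surrogate = pred0 + aaft_surrogate(resid0, rng)
            y_k = y.copy()
            y_k[rows] = surrogate
            theta_k, _, _ = rls_track(y_k, X, valid, lam, init_scale)
        except Exception as exc:
            raise RuntimeError(f"surrogate re-estimate {k + 1} failed") from exc
        kernels_k, _ = _expand_track(theta_k, structure)
        for b, h in kernels_k.items():
            stacks[b].append(h)

    kernels, spread = {}, {}
    for b, stack in stacks.items():
        arr = np.stack(stack)
        kernels[b] = np.median(arr, axis=0)
        q75, q25 = np.percentile(arr, [75, 25], axis=0)
        spread[b] = q75 - q25
    # median kernels need not lie exactly in the basis span; keep projected
    # coefficients for reference
    coeffs = {}
    offset = 0
    for bs in structure.branches:
        basis = _basis_matrix(bs.pole, bs.gen_order, bs.n_funcs, structure.memory)
        coeffs[bs.branch] = kernels[bs.branch] @ basis
        offset += bs.n_funcs
    return KernelTrack(structure.model, structure, lam, np.asarray(time, float),
                       kernels, coeffs, resid0, pred0, spread=spread)


# ---------------------------------------------------------------------------
# full fits


def _fit_model(model: str, output: UniformSeries, inputs: dict,
               options: FitOptions | None = None, **kw) -> ModelFit:
    options = options or FitOptions()
    for key, val in kw.items():
        setattr(options, key, val)
    b1, b2 = MODELS[model]
    for name, series in [("output", output), *inputs.items()]:
        if abs(series.fs - output.fs) > 1e-9 or len(series) != len(output) \
                or abs(series.start_time - output.start_time) > 1e-9:
            raise ValueError(f"{model} model: input {name!r} is not aligned "
                             "with the output series")
    y = output.values
    u = {b: inputs[b].values for b in (b1, b2)}
    try:
        structure, table = structure_search(
            y, u, model=model, profile=options.profile, pole=options.pole)
        X, valid = build_design(u, structure)
        lam, sse = select_lambda(y, X, valid, options.lambda_grid, options.init_scale)
        time = output.times[valid]
        rng = np.random.default_rng(np.random.SeedSequence(options.seed))
        initial_theta, resid, pred = rls_track(y, X, valid, lam, options.init_scale)
        initial = _make_track(model, structure, lam, time, initial_theta, resid, pred)
        stabilized = stabilized_estimate(
            y, X, valid, structure, lam, time=time,
            n_surrogates=options.n_surrogates, rng=rng,
            init_scale=options.init_scale)
    except Exception as exc:
        raise RuntimeError(f"{model} model fit failed: {exc}") from exc
    structure = ModelStructure(model, structure.branches, lam)
    return ModelFit(model, structure, lam, table, sse, initial, stabilized,
                    seed=options.seed)


def fit_hrv_model(drri: UniformSeries, dsbp: UniformSeries, dvt: UniformSeries,
                  options: FitOptions | None = None, **kw) -> ModelFit:
    """Fit the heart-rate variability model (ABR + RCC -> dRRI)."""
    return _fit_model("hrv", drri, {"ABR": dsbp, "RCC": dvt}, options, **kw)


def fit_pr_model(dpatn: UniformSeries, dmap: UniformSeries, dvt: UniformSeries,
                 options: FitOptions | None = None, **kw) -> ModelFit:
    """Fit the peripheral-resistance model (BPC + RPC -> dPATampN)."""
    return _fit_model("pr", dpatn, {"BPC": dmap, "RPC": dvt}, options, **kw)
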