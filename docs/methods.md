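# Methods

## Models

Both models are open-loop, two-input, single-output convolution models at
2 Hz with kernel memory M = 50 lags of 0.5 s (25 s). The heart-rate model
maps systolic-pressure fluctuations (arterial baroreflex, ABR) and
tidal-volume fluctuations (respiratory-cardiac coupling, RCC) to
R-R-interval fluctuations; the peripheral-resistance model maps
mean-arterial-pressure fluctuations (baroreflex control of vascular
conductance, BPC) and tidal volume (respiratory-peripheral coupling, RPC) to
fluctuations of the normalized peripheral-arterial-tonometry pulse
amplitude. Causality is imposed through per-branch latencies restricted to
physiologically admissible ranges: ABR 0.5–3 s, RCC −3–0 s (respiratory
coupling may act ahead of measured tidal volume, so negative delays read
"future" samples — legal offline), BPC 3.5–8 s, RPC 0–3 s, all on the 0.5 s
grid. The models are identified in the feedforward direction only; the
closed-loop feedback from heart rate and resistance back to pressure is
deliberately outside the model class.

## Preprocessing

Order: PAT-amplitude normalization (beat level) → interpolation to 2 Hz →
5th-order polynomial detrend → zero-phase lowpass. PATamp is z-scored
against the window 1–5 min before stimulus onset ([−300, −60) s); a constant
baseline is a hard error. MAP is SBP/3 + 2·DBP/3 per beat. Beat series are
cubic-spline interpolated (linear available via config) onto a grid anchored
so sample time 0 is the stimulus onset; no extrapolation. The lowpass is a
Kaiser-window FIR with passband edge 0.5 Hz and stopband edge 0.85 Hz,
designed for 45 dB attenuation so the passband deviation stays below
0.05 dB; the filter is applied once and its integer group delay compensated,
keeping descriptor time courses aligned with the onset (applying it twice,
filtfilt-style, would double both attenuation and passband droop and is not
what is wanted for a one-sided spec). Tidal volume is anti-alias filtered
(80 dB, so the respiratory band is not colored) before decimation to 2 Hz.
Detrending before lowpassing follows the listed processing order; the two
operations do not commute, and a regression test pins the implemented order.

## Basis dictionary

Kernels are expanded on discrete Meixner functions. Laguerre functions
(generalization order 0) are generated by the all-pass recurrence with pole
`a`; general orders come from the orthonormal-polynomial construction: the
degree-k orthonormal polynomials of the negative-binomial weight
w(x) = C(x+j, j)·a^(2x), times √w. The two constructions agree to machine
precision at j = 0 (tested), and the leading function's first sample,
(1−a²)^((j+1)/2), shrinks with j — higher generalization orders rise more
slowly, suiting sympathetically mediated kernels with sluggish onsets.
Dictionaries are built on an extended support, truncated to M lags, and
re-orthonormalized with the Cholesky factor of the truncated Gram matrix (a
triangular transform: span nesting and signs preserved). A warning reports
truncation drift above 1e-6; at pole 0.9 with high generalization orders the
functions genuinely do not decay inside 25 s and the re-orthonormalized
truncation is the usable dictionary. The default pole 0.9 makes the slowest
low-order function decay below ~1% of its peak by lag 50; it is
config-exposed and could in principle be searched as well.

## Structure selection

An exhaustive grid over (delay, generalization order, basis count) per
branch is scored by time-invariant least squares plus the classical minimum
description length criterion for linear regression,
MDL = (n/2)·ln(SSR/n) + (p/2)·ln(n). All candidates are scored on one fixed
evaluation region (samples valid for every delay in the grid) so SSRs are
comparable. Ties go to the first candidate in iteration order (branch-1
delay, generalization order, basis count ascending, then branch 2). A
singular candidate Gram matrix (e.g. a silent input channel) falls back to
the minimum-norm solution, which assigns the silent branch an exactly zero
kernel; only non-finite solutions are skipped. Two grid profiles exist:
`full` (the whole admissible ranges) and the default `fast`, which keeps the
full 0.5 s delay grids — delay resolution is the point of the search — but
thins the basis grids to the two smallest admissible counts and lowest
generalization orders, keeping a search affordable at desk scale.

## Time-varying tracking

Coefficients are tracked by exponentially weighted recursive least squares.
The forgetting factor λ is selected from a grid in [0.85, 0.97] (step 0.02)
by the summed squared one-step (a priori) prediction error over the
non-warm-up region; λ = 1 is supported as a growing-window mode and then
equals the batch least-squares solution regularized by I/δ, where δ is the
initial inverse-correlation scale (default 100; use a large δ to reproduce
plain least squares — the equivalence is tested at δ = 1e8 to below 1e-6
kernel difference). Coefficients start at zero; the first M + max-delay
samples are warm-up and excluded from selection and descriptors. The
covariance state is symmetrized each step for numerical hygiene.

## Surrogate stabilization

The initial fit's residuals are turned into amplitude-adjusted
Fourier-transform surrogates (rank-remap to a Gaussian, conjugate-symmetric
phase randomization, rank-remap of the original amplitudes back, so the
surrogate's sorted values equal the original's exactly), added back to the
model's one-step prediction, and the coefficients re-estimated with
structure and λ held fixed; after 50 refits the elementwise median over
(t, i) is the final kernel and the interquartile range is kept as an
uncertainty band. The median kernel need not lie exactly in the basis span;
reported coefficients are its projection. Re-running the structure search
per surrogate is supported behind a flag but off by default — it multiplies
cost ~50× for no observed benefit on synthetic data. In a 20-realization
Monte-Carlo at SNR 10 and λ = 0.97 (the value selected on stationary
records) stabilization reduces the median elementwise across-realization
kernel variance to ≈ 0.7× the single-pass value; at λ = 0.9 the benefit is
neutral — the surrogate-median jitter roughly cancels the smoothing gain.

## Descriptors

Per time step the kernel is zero-padded to 256 points (≈ 0.0078 Hz
resolution, ≥ 14 bins in the LF band) and |H| averaged over half-open bands
[0.04, 0.15), [0.15, 0.4), [0.04, 0.4) Hz, so LF and HF tile the overall
band with no double-counted bin. PATampN has arbitrary units, so BPC and RPC
gains are meaningful only relative to their own baseline; `relative_gain`
divides (or differences) by the baseline-window mean and flags the result.

Time-varying spectra of ΔRRI, ΔSBP and ΔPATampN come from an RLS-tracked AR
model (default order 8, config-exposed) with the same AAFT stabilization
(median over coefficient tracks), an exponentially weighted innovation
variance matching the RLS memory, and band powers by integrating the
one-sided AR spectrum. The series is demeaned first and the first RLS
convergence steps are excluded from the variance estimate — without these
the spectrum acquires a spurious near-DC pole and a positively biased level.
Steps with an unstable AR polynomial are masked, not fabricated.

Binned summaries use baseline [−240, −60) s (1–4 min pre-onset — deliberately
different from the 1–5 min normalization baseline; both windows are part of
the procedure) and four half-minute bins from onset; beat-level physiological
measurements are summarized by medians, spectral indices and gains by means,
with change-from-baseline columns.

## Synthetic data

The generator defines the study conditions: 10 min rest + 60 s stimulus +
10 min recovery at 2 Hz. Pressure fluctuations are an AR(2) resonator at
0.1 Hz (pole radius 0.95, SD 4 mmHg) — a Mayer-wave-like LF process;
diastolic fluctuations are 0.7× systolic. Tidal volume is a narrowband AR(2)
process at the breathing frequency (0.25 Hz, pole radius 0.85, SD 0.25 L
around a 0.5 L mean): real respiration has breath-to-breath variability, and
that bandwidth is also what makes the respiratory branch identifiable — a
pure tone would excite only two effective degrees of freedom. Truth kernels
are fixed Meixner-dictionary combinations with fast early peaks (baroreflex
LF gain ≈ 15 ms/mmHg, respiratory-cardiac LF gain ≈ 68 ms/L, both branches
of the vascular model negative, as vasoconstriction responses); a sharp
kernel onset is physiologic and is what renders the latency observable.
Stimulus effects are piecewise-constant kernel switches at onset (and back
at stimulus end). Output noise is white Gaussian; `make_subject(snr=10)`
scales it to the realized noise-free output variance. Beat times follow the
integrate-to-threshold rule t_{k+1} = t_k + RRI(t_k)/1000 with the
generating value recorded at the interval's starting beat, which makes the
conversion invertible by resampling. The PATamp channel maps the normalized
fluctuation through an affine transform (baseline 100 ± 20 a.u.), so the
z-score normalization is exercised nontrivially; its baseline SD rescales
the recovered BPC/RPC kernels, which is precisely why those gains are
analysed relative to baseline. Slow quadratic drifts are added per channel
and removed by detrending.

What the generator does not emulate: ectopic beats and artifacts, amplitude
drift in the breathing pattern, closed-loop feedback from outputs to
pressure, non-Gaussian noise, and cohort-calibrated spectra (no quantitative
description of the subjects' input spectra is available; synthetic spectra
were chosen for band coverage and realism, not fidelity to any cohort — the
synthetic LF/HF ratio of R-R variability, for instance, is higher than
typical resting values). Passing tests therefore demonstrate correctness of
the estimation machinery under the stated conditions, not clinical validity.

## Numerical choices and verification sizes

Verification uses 21-minute records at SNR 10 (variance ratio), 50 seeded
runs for recovery rates, 20 subjects for the cohort direction check, and 20
realizations for the stabilization Monte-Carlo. Two accuracy floors are
worth knowing. First, beat-domain sampling: cubic interpolation of ~1.1 Hz
beat samples attenuates respiratory-band (~0.3 Hz) content by a few percent,
so even noise-free end-to-end recovery of the respiratory-cardiac kernel
bottoms out near 3% — on uniform (pre-beat) signals recovery is exact to
≤ 1e-4. Second, spectral sampling: the LF band power of a single 21-minute
realization scatters 10–20% around the process's ensemble spectrum (a batch
least-squares oracle shows the same scatter), so the AR-spectrum accuracy
check uses 4.2-hour records and averages the signed error over five
realizations; the white-noise LFP/HFP check compares against the bandwidth
ratio 0.11/0.25.

Degenerate inputs are errors, not guesses: constant PAT baseline, SBP < DBP
(named beat), nonpositive R-R intervals, grids outside admissible ranges,
empty frequency bands (the error names the padding needed), too-short
records. A constant residual series yields a pass-through surrogate with a
warning.
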