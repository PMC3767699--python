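# Methods

## Synthetic two-session hemoglobin data

The generator emulates a two-session resting-state optical-imaging study:
`n_subjects = 18`, `n_sessions = 2`, `n_channels = 46`, `fs = 25` Hz,
`duration = 660` s (the analysis discards the first 60 s, leaving 15,000
samples). Amplitudes are expressed in units of the latent source's
standard deviation; no study reports absolute hemoglobin noise levels for
this layout, so the noise defaults below are chosen once as plausible for
continuous-wave optical recordings and are not fitted.

**Latent sources.** Spontaneous "neural" activity is modelled as a
Gaussian process exactly band-limited to 0.009–0.08 Hz (white noise
masked in the Fourier domain, standardized per channel) and mixed through
the Cholesky factor of a channel-correlation template. The default
template is `0.35 + 0.55·0.8^|i−j|` off the diagonal — a dense positive
baseline plus distance decay, positive semi-definite by construction —
which gives the edge-strength spread the strength–reliability analysis
needs. Both the subject-shared and the session-specific sources use the
same template; only their realizations differ.

**Planting the reliability level.** Subject i's session-s signal is

    x_is = sqrt(a)·u_i + sqrt(1−a)·e_is,

where u_i is drawn once per subject and reused in both sessions and e_is
is fresh per session; both are unit-variance processes with the same
correlation template C. The measured quantity downstream is the empirical
Pearson correlation r̂ between channel pairs. To first order (delta
method), the deviation of r̂ from C decomposes into a pure-u term A (shared
across sessions), a pure-e term B, and u×e cross-covariance terms X:

    δr̂ = a·A + (1−a)·B + sqrt(a(1−a))·X.

Because x itself has covariance C for every a, the total variance of δr̂
is independent of a, which forces Var(X) = 2·Var(A); the cross terms are
conditionally independent across sessions. Hence

    ICC(r̂) = a²·Var(A) / [a²·Var(A) + (1−a)²·Var(A) + a(1−a)·Var(X)] = a²,

independent of the template, the autocorrelation structure and the
recording length. The generator therefore uses the variance share
`a = sqrt(icc_target)`, so the edge-wise ICC converges to `icc_target`
as the cohort grows — the calibration the acceptance checks recover
(mean edge ICC within ± 0.05 of the planted 0.7 at 200 subjects). The
identity is first-order: at the band-limited recording's effective
sample size (≈ 2·bandwidth·duration ≈ 85 for 10 min of 0.009–0.08 Hz
signal) the neglected higher-order correlation-sampling terms attenuate
the recovered value by a few hundredths, which the recovery band absorbs.

**Confounds.** Per session and signal: global sinusoids with random-walk
phase jitter (0.01 rad/sample) and per-channel loading/lag at 1 Hz
(cardiac, amplitude 0.4), 0.3 Hz (respiratory, 0.3) and 0.1 Hz (Mayer,
0.2), plus white instrument noise (σ = 0.3). HbR is the neural source
scaled by −0.4 (anti-correlated, smaller amplitude — the sign and ratio
only set hemodynamic plausibility; Pearson networks are scale-invariant)
with its own proportionally scaled confounds; HbT = HbO + HbR
elementwise. After band-pass filtering the confound residue contributes
< 0.2% of in-band variance, so the planted ICC survives the pipeline.

**Artifacts.** `plant_artifacts` adds, on designated channels: step
jumps, slow U-shaped raised-cosine bumps, fast spike trains (~0.08 s
pulses), and a rank-one global interference whose waveform is
`sin(θ) − 0.3·cos(2θ)` with slow phase jitter — dominant spectral peak at
the fundamental, nonzero skewness. The skewed waveform matters: the ICA
contrast below is skewness-based, and superficial hemodynamic
interference is asymmetric in practice; a pure sinusoid would be a
degenerate input for that contrast. The unmodified input dataset serves
as the ground-truth clean copy.

**Determinism.** All draws flow through `numpy.random.SeedSequence`
substreams keyed by (seed, subject, session-stream), so subject i's data
are bit-identical regardless of cohort size and datasets can be streamed
subject-by-subject (the 200-subject recovery study never materializes the
full cohort).

## Preprocessing

**MBLL.** Dual-wavelength (690/830 nm) optical-density changes are
inverted per channel through the 2×2 extinction system with
source–detector distance 3.2 cm and DPF 6.0 at both wavelengths
(standard tabulated extinction coefficients ship as defaults; they affect
scale only, not correlations, and are overridable).

**Band-pass.** 4th-order Butterworth, 0.009–0.08 Hz, applied
forward–backward (zero phase) as second-order sections — the filter
family is a conventional choice for slow hemodynamics; SOS keeps the
recursion stable at a normalized low cutoff of 7×10⁻⁴. Measured gains:
1.01 at 0.04 Hz, 0.11 at 0.1 Hz, 0.003 at 1 Hz, < 10⁻¹² at DC.

**PCA/ICA.** Per subject/session/signal (temporal ICA on the
channels×samples matrix): the smallest principal subspace retaining
> 99% variance is whitened and unmixed by deflation-mode FastICA with a
skewness contrast g(u) = u² (options: cube), seeded initial vectors,
tolerance 10⁻⁵, max 500 iterations; non-converged components are
returned as-is and flagged. A component is classified as noise if **any**
of three criteria fires: (i) temporal — max robust z of the first
differences > 6, or ≥ 10 samples beyond 5 robust SD; (ii) spectral —
dominant Welch frequency (segment min(N, 4096), 50% overlap) outside
0.01–0.1 Hz; (iii) spatial — participation ratio of the mixing column
> 0.7 × channel count. These thresholds are explicit stand-ins for what
is usually a partly visual judgement, and all are configurable.
Reconstruction zeroes the flagged mixing columns; if everything is
flagged, the least-suspicious component is kept rather than erasing the
record. Note the spectral criterion's band (0.01–0.1 Hz) deliberately
differs from the filter band (0.009–0.08 Hz); with flat in-band sources
the dominant Welch bin occasionally falls below 0.01 Hz, so a small
false-flag rate (~5–10% of clean components) is inherent to criterion
(ii) at this spectral resolution.

The pipeline's two arms are band-pass only, and ICA (on unfiltered data)
followed by band-pass; the order is configurable.

## Networks and graph metrics

Edges are Pearson correlations; constant channels are a hard error (they
indicate a dead channel or degenerate configuration). Thresholding keeps
the K = round(S·n(n−1)/2) strongest edges by **signed** r (an
`absolute` option exists); rounding is half-away-from-zero for
platform-independent counts, and ties break by (row, col) order, making
the sweep deterministic and nested.

Conventions at sparse thresholds (all documented choices, switchable
where noted): clustering C = 0 for degree-<2 nodes; L_p averages over
reachable pairs only; efficiency gives disconnected pairs 0; betweenness
counts unordered pairs without endpoint normalization; hierarchy β is
−slope of the OLS fit of log C(v) on log k(v) over nodes with k ≥ 2 and
C > 0 (undefined and reported missing when fewer than two eligible nodes
or no degree variation); assortativity is Newman's degree–degree Pearson
r over edge endpoints (undefined on regular graphs). Undefined values
propagate as missing, never as zero.

**Modularity.** Q = Σ_m [l_m/L − (d_m/2L)²]. The partition comes from a
deterministic greedy agglomeration: starting from singletons, repeatedly
merge the connected pair with the largest ΔQ, ties broken by the
lexicographic order of the communities' smallest node labels, stopping
when no merge gains. Determinism is required for reproducible ICCs;
exhaustive partition enumeration on ≤8-node graphs bounds the greedy
result in tests.

**Null models.** (1) Degree-preserving Maslov–Sneppen rewiring, default
100 nulls × 100 attempted swaps per edge (conventional values; the
emulated analysis does not state its own). (2) A moment-matched random
correlation-matrix generator (factor construction): R = D^(−1/2) W Wᵀ
D^(−1/2) with W ~ N(ν, δ²)^(n×m), ν² = μ/m, δ² = (1−μ)/m. Normalizing by
the realized diagonal removes part of the raw variance (c_ij co-varies
with c_ii); to first order the off-diagonal variance after normalization
is (1 − μ⁴ − 4μ² + 4μ³)/m, and m is rounded from that relation — the
observed moments are then matched within a few percent. Outputs are exact
correlation matrices (unit diagonal, PSD) and are thresholded exactly
like real ones, preserving the transitive structure correlations impose.
γ = C_p/⟨C_p^null⟩, λ = L_p/⟨L_p^null⟩, σ = γ/λ. Null ensembles consume
per-(subject, session, signal, sparsity) derived seeds, so reruns are
bit-stable regardless of evaluation order.

## Reliability

ICC is the one-way random-effects single-measure form (random subject
effects; MS_b with df n−1, MS_w with df n(k−1)); negative estimates are
clamped to 0 and flagged. Grades are half-open on the left with the top
closed at 1.0 (0.6 → good, 0.75 → excellent) — prose definitions of these
ranges overlap at the endpoints, so a convention has to be fixed.

AUC is trapezoidal over the sparsity grid. Missing metric values (β and r
at extreme sparsity, typically) are handled by: dropping that sparsity
point listwise from the ICC-vs-threshold profile; bridging interior gaps
with a single trapezoid; shrinking the integration range when leading or
trailing stretches are missing (the realized range is recorded in the
output).

Session similarity is the Pearson correlation of the 1035-edge vectors
between sessions, per subject and at the group-mean level, with two-sided
p from the t distribution (n_edges − 2 df). Between-session tests are
classical paired t-tests on per-subject AUCs (all differences exactly
zero → t = 0, p = 1 by convention). The nodal analysis uses a two-factor
repeated-measures ANOVA (statsmodels AnovaRM) with nodes as observational
units and metric type × signal type as within factors, followed by
post-hoc paired t-tests on marginal means; a fully degenerate table
(identical cells) reports F = 0, p = 1. p-values are reported unadjusted
and no sphericity correction is applied — deliberate, documented
limitations.

## Problem sizes

Defaults mirror the emulated study (99-point grid, 100 nulls). The
analysis drivers choose a scaled-down but faithful configuration — grid
0.05…0.95 step 0.05, 10 nulls × 10 swaps per edge — so the complete
18 × 2 × 3-signal sweep runs in minutes; the acceptance script uses 200
subjects for the parameter-recovery study (estimator noise at 18 subjects
is ± 0.07 per edge, far larger than the ± 0.05 recovery band), 150
replicates of 1000 × 2 tables for ICC recovery, and 100-null ensembles on
100-node graphs for the small-world checks. Test fixtures are smaller
still (≤ 12 channels, ≤ 4 subjects, coarse grids).

## What the synthetic data do and do not show

The generator reproduces the *statistical skeleton* the reliability
analysis rests on: a planted, analytically known edge-ICC level; known
band limits; known artifact types with ground-truth clean copies; the
HbT identity. It does not model neurovascular coupling dynamics
(balloon/Windkessel), optode geometry, scalp coupling, motion coherence
across channels, or session-to-session probe repositioning. Passing
tests therefore demonstrate that the *estimators and pipeline* are
correct and recover planted truth — not that any particular real-world
recording will show a specific reliability level. Real-data headline
values (e.g., which hemoglobin signal is most reliable) depend on
signal-to-noise structure the generator does not attempt to fit.

## Known limitations

- The greedy modularity optimizer is deterministic but not optimal;
  Q values are lower bounds on the best partition's Q.
- Criterion (ii)'s false-flag rate on flat in-band components (above).
- The correlation-matrix null matches first and second off-diagonal
  moments only; higher-order structure (e.g., community structure) is
  not preserved.
- ICC is the single-measure one-way form; two-way forms (ICC(2,1),
  ICC(3,1)) and bootstrap confidence intervals are out of scope.
- Edge ranking uses signed correlations by default; with predominantly
  negative matrices the `absolute` option is the sensible choice.
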