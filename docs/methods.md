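# Methods

## Approximate entropy: conventions

`compute_apen` implements the classic self-match-included formulation with
delayed embedding: at dimension d there are M_d = N − (d−1)τ vectors
x_d(i) = (u(i), u(i+τ), …, u(i+(d−1)τ)); matches use the Chebyshev
(max-norm) distance with a non-strict `≤ r` comparison and count the
self-match j = i, so every match frequency is at least 1/M_d and the
logarithm is always defined. ApEn = Φ^m − Φ^{m+1}. Tolerances are computed
from the sample SD (n−1 denominator); at N ≈ 10⁴ the distinction from the
population SD is negligible, and the exact r used is recorded in every
result.

The optimized kernel is a numba-compiled pair loop with early exit on the
first mismatching coordinate; `kinentropy.reference.apen_reference` is a
deliberately naive O(M²) evaluation of the same definition, kept as an
in-repo oracle. The two agree to < 1e−10 across random series, dimensions
and delays (tested).

Two analytic caveats worth stating precisely:

* **Nonnegativity is not exact at degenerate tolerances.** Because Φ^m and
  Φ^{m+1} average over different numbers of vectors, a series in which
  essentially no pairs match (r → 0 on continuous data) gives
  ApEn ≈ ln(M_{m+1}/M_m) < 0, of order −τ/N. The value is returned
  unclipped; at the conventional r = 0.2·SD the statistic is comfortably
  positive (property-tested on 1,000 random series). Running with r = 0 on
  a non-constant series is permitted but flagged in the result's notes.
* **ApEn is not globally monotone in r.** For iid noise the self-match
  floor biases the conditional match probability upward at small r, so
  ApEn(r) rises before it falls; for strongly delayed embeddings a shallow
  rise can reappear at very large r. In the tolerance regime the pipeline
  actually uses (r between 0.2 and 2 × SD, quasi-periodic signals) the
  non-increasing property holds and is tested there.

Minimum data: the (m+1)-dimensional pass must have at least 10 embedding
vectors (N − mτ ≥ 10); shorter series raise a distinct "insufficient
embedding" error that the pipeline converts into a per-recording failure.

## Delay selection

The autocorrelation profile uses the shared-denominator (biased) estimator —
acf(k) = Σ(x_t − x̄)(x_{t+k} − x̄) / Σ(x_t − x̄)² — which guarantees
acf(0) = 1 and |acf| ≤ 1; it is computed via FFT. Shifts are 0-based
(shift 0 = no shift); reports that call the unshifted series "lag 1" use a
1-based display convention whose lag equals shift + 1.

The delay τ is the smallest shift k ≥ 1 with |acf(k)| < 0.1. The absolute
value operationalizes "closest to zero" as a magnitude criterion: a strongly
negative ACF is still strongly (anti-)correlated and does not qualify. A
signed-threshold mode (`acf(k) < 0.1`) is available for sensitivity
analysis. The search range defaults to every possible shift (K = N − 1) and
can be restricted via `max_shift_fraction`. One consequence of the biased
estimator: at lags approaching N the ACF always decays toward zero, so with
the full search range some τ is effectively always found (possibly so large
that the embedding check then fails). A genuine "no usable delay" outcome
therefore arises in practice only under a restricted search range, which is
how the `tau_not_found` fixture (a trend-dominated, near-constant channel)
is meant to be analyzed.

## Statistical battery

* Unit of analysis: the participant × dance mean of per-recording values,
  compared unpaired between sides. Keys present on only one side are kept
  in the aggregate table but logged and excluded from the contrast.
* Parametric path: two-sided Welch t (unequal variances,
  Welch–Satterthwaite fractional df). Chosen as the canonical default for
  unpaired two-sample comparison; it is also what R's default `t.test`
  computes.
* Nonparametric fallback: two-sided Mann–Whitney, triggered per contrast
  when Shapiro–Wilk rejects normality (p < 0.05) on either side. Exact
  distribution when both n ≤ 20 and no ties; otherwise the tie-corrected
  normal approximation with continuity correction.
* Variance homogeneity: Levene with median centering (Brown–Forsythe),
  reported as evidence, not used to switch tests (Welch does not assume
  equal variances).
* Outliers: Tukey fences on each side's values — beyond 1.5·IQR "outlier",
  beyond 3·IQR "extreme" — using linear-interpolation quantiles (the
  convention matters at n ≈ 5–10 and is pinned by test). Flags are
  informational; no value is ever removed, and a test verifies that
  flagging does not alter any downstream statistic.
* Multiplicity: per-contrast p-values are reported unadjusted by default;
  a Holm step-down flag exists for sensitivity analysis.
* Degenerate contrasts (both sides constant and equal) report statistic 0,
  p = 1, flagged rather than NaN.

Group descriptives (recording length per recording; τ and ACF-at-τ per
recording × channel) are compared PD vs OA with the same Welch machinery,
and across dance types with one-way fixed-effects ANOVA (df = (k−1, N−k)).

## Synthetic cohorts

Each channel is θ(t) = mean + Σ_h A_h sin(2π·h·f·t + φ_h + h·J(t)) + ε(t):

| parameter | default | rationale |
|---|---|---|
| base_freq f | 0.9 Hz | a typical social-dance stepping rate |
| harmonics (knee flexion) | 30° + 8° at 2f | hinge-joint range of motion during stepping |
| harmonics (hip flexion / abduction / rotation) | 20°+5° / 8° / 8° | smaller proximal excursions |
| noise_sd (SD of ε) | 2.0° | a few degrees of cycle-to-cycle variability, realistic for older adults |
| ar_coeff | 0.3 | gives ε short memory so the ACF is not a pure delta |
| phase_jitter_sd J | 0 rad/cycle | rhythm kept metronomic by default; J is a per-cycle random walk when enabled |
| asymmetry_gamma | 1.0 (cohort) | multiplier on the affected (left) side's noise_sd for PD-like participants; < 1 = more regular affected side |

ε is AR(1) with innovation SD chosen so its stationary SD equals noise_sd
(verified to < 5% relative error at 10⁴ samples). Left and right use
identical deterministic parameters — contralateral phase relationships are
not modelled because every downstream statistic (ACF, ApEn, mean) is
phase-invariant — so at γ = 1 sides differ only by noise realization, and
amplitude/mean stay side-equal so mean-angle contrasts are null by
construction. Sub-seeds derive from the master seed keyed on (group,
recording, channel, side), making whole cohorts byte-reproducible.

The affected side is fixed to the left by default (configurable), matching
the clinical presentation the pipeline is designed around, and reduced
noise models reduced movement complexity — i.e. lower ApEn on the affected
side.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: between-participant heterogeneity (all simulated
participants share one parameter set, so between-participant variance is
pure estimator noise and simulated effect sizes are far cleaner than
clinical ones — demo t statistics in the hundreds are expected, not
realistic), biomechanical coupling between joints, partner interaction,
tempo changes within a recording, and sensor artifacts. Monte-Carlo power
at γ = 0.25 is a check of the pipeline's machinery under its own
assumptions, not an estimate of clinical power.

## Calibration conditions and problem sizes

The calibration presets simulate single-dance cohorts of 30 s recordings at
100 Hz, knee flexion only, 10 recordings per cohort distributed round-robin
over participants (5 participants for the symmetric/type-I preset, 7 for
the asymmetric preset) — the scale of a community dance class session. The
test suite runs 200 symmetric and 100 asymmetric cohorts; the acceptance
script reports the same quantities at 60 and 40 cohorts. Every replicate
writes CSVs to disk and runs the full pipeline, file I/O included.

## Numerical and design choices

* ACF via FFT (statsmodels `acf`, `adjusted=False`), identical to the
  direct-summation formula to 1e−10 (tested).
* Recording CSVs are written with `%.17g` and read with round-trip float
  parsing, so write → read is exact and repeated writes are byte-identical.
* Uniform-sampling validation tolerates 1% deviation in the time step;
  sampling frequency is inferred from the median step.
* Upper-limb (elbow) channels are parsed but excluded from analysis by the
  default channel allow-list, reflecting that lower-limb motion is the
  analysis target; override via `PipelineConfig.channels`.
* The pipeline is deterministic end to end: identical inputs produce
  byte-identical summaries (tested through the CLI).

## Known limitations

* ApEn is a biased estimator at short N and its value depends jointly on
  (m, r, τ, N); comparisons are only meaningful at matched parameters, which
  the pipeline enforces by recording them with every value.
* The delay search and entropy are O(N) and O(M²) per series respectively;
  multi-minute recordings at 100 Hz are fine (~seconds), but hour-long
  captures would warrant windowing, which is out of scope.
* Sample entropy, multiscale entropy and surrogate-data significance
  testing of individual ApEn values are deliberately not provided.
* No repeated-measures or mixed-effects modelling: contrasts treat
  participant × dance datapoints as independent, so participants
  contributing multiple dances are represented multiple times.
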