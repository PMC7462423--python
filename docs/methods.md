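# Methods

This note documents the models, estimators, parameter choices and known
limitations of the package, in the order of the analysis pipeline.

## Discretization and timescales

Spike times (seconds) are binarized into half-open bins [k·w, (k+1)·w),
0-based, with a bin marked 1 iff at least one spike fell in it. A spike
exactly at the recording duration is dropped. Binary occupancy (rather
than spike counts) is used at every bin width, including the coarsest
750-ms bins: it keeps every state alphabet binary, which keeps the joint
state spaces of the information measures small and the plug-in estimates
well-populated. `bin_spikes(..., binary=False)` provides a counts-per-bin
switch for sensitivity checks at coarse bins.

The ten standard timescales are defined by (bin width, delay set):
(0.05 ms, 1..60), then (1.6, 3.5, 7.5, 16.15, 34.8, 75, 161.6, 348.1,
750 ms) each with delays 1..4. Only the *span* of source lags
(w·min delay, w·max delay) is fundamental; the delay sets are the unique
uniform reconstruction consistent with every span having a max/min ratio
of 4 (60 for the first). The nominal "center" labels (3, 5, 11, 23, 48,
104, 225, 485, 1044, 2250 ms) are carried verbatim for reporting; they
are neither midpoints nor geometric means of the spans and are never used
in computation. Timescales 1–3 are grouped as *synaptic* (monosynaptic
lag windows), 7–9 as *extrasynaptic*; the group labels drive the
cross-timescale comparisons.

## Information estimators

All estimators are plug-in (maximum likelihood) over empirical joint
tables, in bits. No debiasing is applied: the analysis design handles
entropy differences by normalization (below) rather than bias correction,
and every comparison is between quantities estimated on the same sample.

* **Normalized sender MI**: MI(J;K)/min(H(J),H(K)) at zero lag, at the
  triad's analysis bin width. The denominator is the maximum attainable
  MI, so the measure is a proportion in [0, 1]. Pairs with a constant
  raster (zero entropy) are flagged missing, never divided by zero.
* **Transfer entropy**: order-1 receiver history — the single bin
  immediately preceding the predicted bin, at the analysis bin width.
  Higher-order histories would explode the state space at 0.05-ms bins
  (and sparsify counts at 750-ms bins). Per timescale, TE is maximized
  over the delay set; ties break toward the smallest delay.
* **Multivariate TE and PID**: each sender enters at its own peak delay
  (the delay its significant edge was established at). TE_J, TE_K, mvTE
  and redundancy are all computed from one aligned four-variable joint
  table (receiver future, receiver past, sender J, sender K), so the
  accounting identity

      unique_J + unique_K + redundancy + synergy = mvTE

  holds to machine precision by construction, and the Williams–Beer
  minimum structure guarantees every term is nonnegative: the specific
  information of a receiver transition about a sender is a KL divergence
  (hence ≥ 0), redundancy is the expectation of the pointwise minimum,
  and synergy reduces to the expectation of (joint − pointwise maximum),
  which monotonicity of specific information keeps nonnegative.
* **Redundancy modes**: `imin` (default) is the conditional Williams–Beer
  form, Red = Σ p(i_t, i_{t−1}) · min_S Ispec(i_t; S | i_{t−1}). The
  supplementary material defining the original redundancy equations is
  not available in the main text, so this standard conditional I_min form
  is a documented assumption. `lower_bound` is the minimal redundancy
  consistent with nonnegative unique terms, max(0, TE_J + TE_K − mvTE) —
  the parameter-free reading of a redundancy lower bound; under it
  synergy is max(0, mvTE − TE_J − TE_K).
* **Normalization**: every information term is divided by the receiving
  neuron's single-bin entropy (proportions written pH^rec); sender MI is
  already normalized by construction (pMI^max). Normalizing twice is a
  guarded error; zero-entropy receivers yield flagged missing values. The
  full pipeline can run unnormalized (`normalized=False`). Logs are base
  2 throughout; normalized quantities are base-invariant.

## Surrogate significance and network assembly

The null for a directed pair jitters each *source* spike independently by
uniform(−h, +h), clipped to the recording, re-sorted; the target and its
history structure are untouched. The half-window default is h = 5× the
timescale's maximum lag span — wide enough to destroy coupling anywhere
in the searched delay window, narrow enough to preserve slow rate
fluctuations. The jitter distribution and window are design choices, not
values taken from a published protocol; the uniform window is the
standard surrogate for destroying fine-timescale coupling.

The p-value is the add-one rank estimator p = (1 + #{null ≥ obs}) /
(1 + n_jitter), never exactly zero; with the default 5,000 jitters the
smallest attainable p ≈ 2×10⁻⁴ resolves α = 0.001. Requesting an α that
n_jitter cannot resolve is a configuration error — reduced-jitter runs
must rescale α accordingly (tests and examples use e.g. 199 jitters at
α = 0.01). Edges are tested independently per timescale with no
edge-level multiple-comparison correction, matching the design the
pipeline reproduces. Calibration is verified empirically: on independent
Poisson pairs the significant-edge rate falls within the 99% binomial
band around α.

Triads are all unordered pairs of distinct in-neighbors of each receiver,
so the count per receiver is C(indegree, 2) exactly.

## Decile statistics

Per network, triads are sorted by sender MI and split into ten
equal-count bins; when the count is not divisible by ten the remainder is
assigned one-per-decile to the *lowest*-MI deciles (any fixed rule works;
this one is deterministic and documented). Per-decile medians of MI,
synergy, redundancy, mvTE and (mvTE − redundancy) feed all downstream
statistics; a triad-level mode (no deciles) is available as a
cross-check. Spearman correlations and OLS fits are computed on the ten
decile medians; fits default to log₁₀–log₁₀ space. Nonpositive medians
cannot be log-transformed and are *excluded and counted*, not floored —
I_min terms are nonnegative and exact zeros are rare, and flooring would
bias slopes.

Wilcoxon signed-rank and rank-sum tests are implemented in closed
normal-approximation form with tie-corrected variances, reporting signed
Z (checked against the exact degenerate regimes: 75 uniformly signed
values give Z = 7.52; fully separated 75-vs-75 groups give Z = 10.57).
Exact small-sample versions are out of scope. Bonferroni–Holm adjustment
uses the step-down statsmodels implementation. Bootstrap CIs are
percentile (2.5/97.5) over resampled medians, deterministic given a seed;
the full-scale default is 10,000 iterations.

The saturation point is, per network, the decile-median MI at which
decile-median synergy peaks; a peak on a boundary decile is returned but
flagged (a monotone curve has no interior saturation). Its resolution is
limited by decile quantization: with MI log-uniform over 1.7 decades the
decile medians are ~0.17 dex apart, so a planted peak at MI 0.07 is
recovered as a mixture of the two adjacent decile medians (≈0.058/0.086)
whose across-network bootstrap CI covers the planted value.

## Synthetic data

The generators emulate the statistical structure the analysis assumes,
not biophysics:

* **Correlated senders**: superposition of a shared Poisson source (rate
  c·min(rate_J, rate_K)) with independent Poisson remainders. This
  preserves marginal rates exactly, gives independent senders at c = 0
  and identical ones at c = 1 (equal rates), and estimated sender MI is
  monotone in c. A Gaussian-copula thinning construction was considered
  and rejected: the shared-drive mixture has analytic limits at both ends
  of the dial.
* **Triad gates**: sender states are binarized at an internal gate bin
  (default 1 ms, decoupled from the analysis bin width); each
  gate-satisfying bin triggers a receiver spike at a fixed lag with the
  given reliability, over independent background. Note the XOR gate is
  only *purely* synergistic when sender occupancy is near 0.5: at sparse
  occupancy XOR degenerates toward OR and individual-sender TE (hence
  I_min redundancy) is substantial. Validation of the pure-synergy regime
  therefore uses coarse gate bins (~20 ms at 30 spikes/s, occupancy
  ≈ 0.45), where simulation matches exact-table enumeration of the gate.
* **Networks**: rates lognormal (default log-mean ln 2, log-sd 0.6 —
  median 2 spikes/s with realistic skew); each planted edge copies source
  spikes into the target at a fixed lag (default range 1–10 ms, the
  monosynaptic window) with reliability 0.3–0.9. Lag and reliability
  defaults are placeholders for unknown in vivo values, not claims.
* **Planted regime populations**: per-triad MI log-uniform, synergy a
  power law in MI with multiplicative lognormal noise (or a log-quadratic
  peak for saturation fixtures); redundancy and uniques constructed to
  satisfy the accounting identity with nonnegative terms.

What passing tests on these data do **not** show: robustness to bursting
or avalanche dynamics, nonstationary rates, spike-sorting contamination,
inhibitory couplings, or electrode-geometry effects — none of which the
generators emulate.

## Problem sizes and numerical choices

Tests and the validation script run at reduced scale chosen for adequate
statistical power: recordings of 60–300 s (vs hour-scale sessions),
populations of 12–30 neurons (vs hundreds), 99–200 jitters with α
rescaled to 0.01–0.05 (vs 5,000 at 0.001), and 200–2,000 bootstrap
iterations (vs 10,000). Planted-edge recovery is assessed at a timescale
whose lag span (3.5–14 ms) covers the generator's 1–10 ms lags; edges
with lags below one bin still register because each source spike's
induced delay depends on its bin phase, leaving most coincidences at
delay 1. False-positive accounting excludes structurally dependent pairs
(common planted source, two-step chains), which carry genuine — not
spurious — dependence.

Internal tolerances: the PID identity and nonnegativity are enforced at
1e-10 (violations raise a consistency error); probability tables must sum
to 1 within 1e-12. Ties in the delay search break toward the smallest
delay; ties in ranks use average ranks. All randomness flows through
explicit `numpy` generators seeded per stage from one seed sequence, so
every pipeline output is bit-reproducible given its seed.

## Known limitations

* Plug-in TE is positively biased at small samples; comparisons are
  within-sample and the surrogate test calibrates the detection step, but
  absolute TE values at short durations should not be compared across
  very different firing rates without care.
* Order-1 receiver history misses longer self-dependencies (bursting).
* PID is restricted to two senders (triads); higher-order decompositions
  are out of scope, as are alternative redundancy measures beyond the two
  implemented modes.
* The delimited spike-table format is the only interchange format; no
  binary container is provided.
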