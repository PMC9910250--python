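# Methods

This note records the models, conventions and numerical choices behind
`sleepfbn`, in the spirit of a statistical-methods appendix: what is
computed, under which assumptions, which knobs matter, and what the
synthetic generators do and do not emulate.

## 1. EEG model and preprocessing

**Acquisition conditions.** The pipeline assumes 8-channel sleep EEG
(C3, C4, P3, P4, O1, O2, P7, P8 of the 10–20 system; Cz reference) sampled
at 128 Hz, with ten 15-s windows per subject × timepoint drawn from stage-2
NREM sleep. Sleep staging is out of scope: windows are taken from the
supplied recording sequentially or at seeded random non-overlapping
positions, standing in for epochs a technician would mark. No
re-referencing and no artifact correction are applied (beyond a finite-value
check); neither is part of the analysis chain.

**Filtering.** The 0.30–30 Hz band-pass is realized as a 4th-order
Butterworth applied forward–backward (`sosfiltfilt`), i.e. zero-phase with
8th-order magnitude. Zero phase matters because phase distortion between
channels would bias the Pearson correlations that define the networks. Only
the corner frequencies are analysis conditions; the order and realization
are conventions of clinical EEG practice. Filtering is idempotent (to <1 %
RMS) only for signals whose power lies strictly inside the passband — power
at the corners is attenuated again on re-application, which is expected
filter behaviour, not an error.

**Segment extraction.** `n` non-overlapping windows of `dur` seconds
(defaults 10 × 15 s = 1920 samples at 128 Hz). The random strategy samples
uniformly among all non-overlapping placements via the gap method and is a
pure function of its seed. Start indices are kept as provenance and the
non-overlap invariant is enforced on them.

## 2. Network construction

Edges are absolute Pearson correlations |r| between filtered channels,
giving a weighted symmetric adjacency with zero diagonal; entries live in
[0, 1]. The absolute value treats anticorrelation as connectivity strength —
a deliberate, prominently documented convention (the alternatives, signed r
or r², change none of the machinery but do change BNE). Networks are
unthresholded by default; `threshold`/`binarize` options exist for
sensitivity analyses only.

The ten per-segment adjacencies are averaged element-wise into one network
per subject × timepoint, and metrics are computed on the mean network. The
alternative order (metrics per segment, then averaged) is available as
`aggregation="metrics-per-segment"`; the default matches reporting one
network per patient per visit.

## 3. The five topological features

For weight matrix W (n = 8), with ŵ = W / max(W):

| metric | definition | degenerate cases |
|---|---|---|
| D | node strength Σ_j W_ij, mean over nodes | empty graph → 0 |
| C | Σ_{jk}(ŵ_ij ŵ_ik ŵ_jk)^{1/3} / (k_i(k_i−1)), mean over nodes | nodes with <2 neighbours → 0 |
| L | mean shortest-path distance, edge length 1/W_ij | unreachable pairs excluded, fraction reported; fully disconnected → error (NaN in tables) |
| E | mean 1/distance over ordered pairs | 1/∞ = 0, so disconnection is handled |
| BNE | Σ|λ_i(W)| (graph energy) | 0 iff no edges |

The clustering form is the geometric-mean (Onnela) weighted triangle count;
distances use the standard 1/weight mapping. Both are the dominant
conventions in weighted brain-network analysis. Shortest paths are computed
by Dijkstra (`scipy.sparse.csgraph`); eigenvalues by `eigvalsh`.

**Brain network energy.** The trial literature cites "brain network energy"
without reproducing a formula; this package's operational definition is the
spectral graph energy, Σ|λ_i| of the weight matrix — the standard "energy"
of spectral graph theory, analytically checkable (K_n has energy 2(n−1);
energy ≥ Σλ²/λ_max). A Laplacian-energy reading exists in the literature
and is noted here as an alternative; it is not implemented as the default.

## 4. Synthetic EEG generator

Channels mix latent band-limited Gaussian sources:

    x_i = sqrt(max(0, 1 − k_i)) p_i + Σ_j sqrt(c_ij) s_ij + σ e_i,  k_i = Σ_j c_ij

with one private source p_i per channel, one shared source s_ij per coupled
pair, and independent sensor noise e_i; all sources have unit variance and a
common NREM-II-like spectrum (relative band powers: delta 0.5–4 Hz 0.55,
theta 0.2, alpha 0.1, sigma/spindle 12–14 Hz 0.1, beta 0.05), synthesized in
the frequency domain with exact expected-variance normalization. For an
isolated coupled pair the population correlation is c/(1+σ²), monotone in
the planted coupling — the property every recovery test leans on. Signals
are scaled to 40 µV RMS, a typical pediatric sleep-EEG amplitude.

Sensor noise is spectrally flat over the 0.3–30 Hz analysis band rather
than broadband white: out-of-band noise power would be removed by the
band-pass anyway, and keeping the generator in-band makes the pre-filter
spectral bookkeeping exact (≥ 90 % of power in-band by construction).
Gaussianity is sufficient because the pipeline consumes only second-order
structure. The generator deliberately does **not** emulate sleep-stage
architecture, EMG/EOG artifacts, electrode drift, or pathology-specific
rhythms — so passing recovery tests demonstrate correctness of the
estimation chain under the stated model, not robustness to real-world
artifacts.

**Default planted coupling.** Three strong edges (C3–C4 0.65, P3–P4 0.55,
O1–O2 0.45) over a graded weak background: the remaining 25 pairs receive
distinct couplings linearly spaced over (0.01, 0.15), assigned by a
deterministic greedy rule that gives larger values to pairs with more spare
per-channel headroom so every channel's total source-sharing stays ≤ 0.98
(keeping private-source weights positive and planted correlations
analytic). All 28 pair couplings are distinct by design: with exact zeros on
25 of 28 pairs, a rank correlation between planted and recovered weights is
capped near 0.54 by the tied block regardless of recovery quality, so a
graded background is what makes rank-based recovery a meaningful statistic.
The background's lower end sits at the |PCC| estimator's noise floor for
the 10 × 15 s segment budget; the upper end is the largest value assignable
without clipping any pair.

**Cohort model.** Each simulated subject carries a multiplicative coupling
factor ~N(1, 0.10) (truncated at 0.05) shared across timepoints — the
between-subject variability of connectivity. Planted interventions scale
the coupling per (arm, timepoint); `calibrate_coupling_scale` converts a
target standardized BNE effect into a scale decrement using a paired probe
run (BNE responds approximately linearly to scale near 1).

## 5. Trial-table generators

**Scales.** Long-format scores per subject × timepoint × measure from a
per-(subject, measure) random intercept (SD 15 score units) plus residual
noise (SD 5), truncated to each scale's valid range. Baseline means and the
measure set default to the treatment-arm baselines of the motivating trial
(e.g. GMFM-88 total 52.41, ADL 34.54, SDSC 49.43). Effects are standardized
mean shifts in units of the total SD √(15²+5²) and are zero at baseline by
construction. Arm sizes default to 15 vs 10; timepoints to baseline, 1M,
3M, 6M, 24M.

**Volumes.** Paired baseline/6-month volumes per subject × AAL region for
the nine regions of the motivating trial's volumetry table, drawn from the
published regional means and SDs, with measurement noise of 2 % of the
regional mean at each timepoint and planted fractional changes applied at
6M. A TOTAL pseudo-region equals the regional sum plus a subject-specific
remainder that is constant across timepoints, carrying the between-subject
variance the modelled regions do not — so regional and total analyses are
mutually consistent. Default n = 9 subjects (the analyzable-imaging subset
of the motivating trial).

## 6. Statistical engines

- **Normality gate.** Shapiro–Wilk at α = 0.05 per group (per difference
  vector for paired designs); the parametric branch requires all relevant
  vectors to pass. Constant vectors fail the gate; n = 2 passes by
  convention (normality is unassessable). The gate is deterministic and the
  chosen test is recorded in every result.
- **Independent:** pooled-variance Student's t vs Mann–Whitney U (exact
  where SciPy can). **Paired:** paired t vs Wilcoxon signed-rank; constant
  or all-zero difference vectors are degenerate errors, not silent results.
- **Longitudinal:** one-way repeated-measures ANOVA (pingouin). Sphericity
  handling follows the SPSS-style workflow: Greenhouse–Geisser-corrected p
  when Mauchly's test rejects sphericity, uncorrected otherwise
  (`correction="auto"`; "always"/"never" available). Unconditional GG is
  measurably conservative under sphericity (type-I ≈ 0.035 at n = 14, five
  timepoints) while the gated version is calibrated (≈ 0.049); the gated
  default is therefore the one that actually attains the nominal level.
  With two timepoints the design reduces exactly to the paired t (F = t²).
  Missing data are handled complete-case; no imputation.
- **Categorical:** Pearson χ² without continuity correction; Fisher's exact
  substituted (and logged) for 2×2 tables with any expected cell < 5. At
  the motivating trial's group sizes this routes most tables to Fisher,
  which is conservative by construction (exact size 0.040 at 15 vs 10,
  p = 0.5); the χ² branch is calibrated in its asymptotic-validity regime
  (exact size 0.0569 at n = 50 per group, computed by binomial enumeration).
- **Volumes:** per-region paired contrast plus two percent-change summaries:
  the mean of per-subject percent changes, and the percent change of group
  means (the convention behind whole-gray-matter change figures). Rounded
  to 2 decimals to match clinical reporting.
- **Multiplicity.** No correction across scales or regions (matching the
  motivating trial's plan); the number of contrasts performed is logged.
- Between-group contrasts at a follow-up use raw values at that timepoint,
  not change-from-baseline, matching endpoint-table layout.

## 7. Pipeline, determinism and problem sizes

A `PipelineConfig` fully determines a run; every output CSV carries the
config's SHA-256 hash and seed in a leading comment, and identically
configured runs are byte-identical. Per-recording seeds derive from the
master seed through one `default_rng` stream in a fixed iteration order.

Problem sizes used by the shipped tests and the acceptance script: 150-s
recordings (the minimum holding ten 15-s windows), 50-seed recovery
experiments, 2000-simulation null calibrations, 200-seed power experiments,
and full 25-subject × 3-timepoint cohort runs — sizes at which each check's
Monte-Carlo error is small relative to its acceptance margin while the whole
suite completes in minutes.

## 8. Known limitations

- The EDF writer covers the pipeline's needs (16-bit, µV, uniform sampling,
  one data-record layout) and is not a general EDF+ implementation
  (no annotations, discontinuous records, or per-signal rates).
- BNE's operational definition (adjacency graph energy) is one defensible
  reading of an under-specified quantity; conclusions that hinge on its
  absolute scale should be cross-checked against the Laplacian variant.
- The |r| convention discards the sign of coupling; anticorrelated and
  correlated pairs are indistinguishable downstream.
- Synthetic cohorts share one base coupling topology across subjects;
  individual-topology variability is modelled only as a scalar factor.
- The statistical engines implement the common clinical test-selection
  convention; they are not a substitute for a prespecified analysis plan,
  and the RM-ANOVA assumes complete cases.
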