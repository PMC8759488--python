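# Methods

## Response-curve models

A gene's transcript counts across the concentration gradient
x ∈ {0, 0.05, 0.1, 0.5, 1, 5, 10} μM (4 replicates per dose) are summarized
as per-concentration means — the *response curve* — and fit with:

- **Sigmoid (4PL)**: f(x) = a + (b − a)/(1 + e^(−k(x−th))). `a` and `b`
  are the left and right plateaus in counts (minimum and maximum transcript
  number for an increasing curve), `th` the inflection concentration (μM),
  `k` the slope (μM⁻¹). Direction is the sign of k·(b − a). The exponent is
  clamped at ±700 so extreme slopes cannot overflow.
- **Biphasic**: sum s₁ + s₂ or product s₁·s₂/c of two 4PL components. The
  raw product of two count-scale sigmoids has counts² units, so product mode
  carries one extra fitted positive constant `c` returning it to the count
  scale. The sum of a rising and a falling component gives a valley or a
  shoulder; the normalized product of a rising and a falling component gives
  a clean bump that returns to baseline.

Fitting is nonlinear least squares (`scipy.optimize.least_squares`, trust
region reflective, analytic Jacobians) over a deterministic multi-start
grid: slope seeds k₀ ∈ {±1, ±5, ±20, ±100} crossed with every interior grid
concentration as th₀ (for biphasic fits, ordered pairs of interior
concentrations and four plateau-assignment patterns per mode). All starts
are screened by their initial SSE and the 10 best are refined; no random
initialization anywhere, so fits are exactly reproducible. Bounds:
a, b ∈ [0, 2·max(response)], th within the concentration range, |k| ≤ 10⁴.
The biphasic fitter additionally seeds one start at the sigmoid solution
with a flat second component, which makes the model nesting
(biphasic SSE ≤ sigmoid SSE) hold by construction.

By default the fit targets per-concentration means; `fit_target="points"`
fits replicate-level data instead. Fitting is on the linear μM axis as the
model is written; `axis="log"` fits on log10 concentration with 0 μM mapped
one half dilution step below the lowest nonzero dose, which is standard
dose–response practice when the gradient spans decades.

## Scaled error and classification

The classification statistic must be dimensionless so one cutoff (0.4)
applies to genes expressed at tens or thousands of counts. We define

    scaled_error = SSE / range²,   range = max(means) − min(means),

i.e. the SSE of the curve after normalizing it by its range. Under this
definition the three regimes separate decisively on a 7-point gradient: a
correct sigmoid fit of a noisy sigmoidal gene scores ~10⁻³–10⁻², the best
possible monotone fit of a genuinely biphasic (plateau bump/valley) curve
scores ≥ 1.09 (an isotonic-regression lower bound), and pure replicate
noise scores 0.2–0.6 — so the 0.4 cutoff classifies real shapes confidently
while leaving a minority of no-signal genes unclassifiable, matching how
such panels behave in practice. The frequently seen alternative RMSE/range
is available as `error_kind="rmse"`, but note that against a 0.4 cutoff it
is nearly degenerate: the best monotone fit of *any* unimodal 7-point curve
sits at 0.395–0.414 of the range (the isotonic bound is √(1.2/7) ≈ 0.414),
putting every biphasic-vs-sigmoidal decision on the knife edge.

Classification order: (0) curves whose range is below 1% of their mean
level (`eps_flat_frac`) short-circuit to **flat** — this avoids dividing by
a vanishing range; (1) sigmoid scaled error strictly < threshold →
**sigmoidal**; (2) else biphasic scaled error strictly < threshold →
**biphasic** (the better of sum and product mode); (3) else
**unclassified**. Inflection points are `th` (sigmoid) or both component
`th`s (biphasic, sorted); a gene is `in_window` when any inflection lies in
the closed critical window, default [0.05, 0.5] μM. Ties at the threshold
are excluded by the strict inequality, as the cutoff is stated.

Known limitation: a no-response gene with ordinary replicate noise has a
range dominated by noise and is usually absorbed as a low-amplitude
sigmoidal or biphasic fit rather than labeled flat — the flat short-circuit
only catches essentially constant curves. Fitted amplitude (b − a relative
to level) should be consulted alongside the label.

## Differential expression

Each concentration > 0 is tested against the 0 μM control within the same
timepoint with a two-sample t-test on log2(count + 1); log2 fold change is
the difference of mean log2 counts. The default is the pooled-variance
(Student) test: with 4 replicates per group it is exactly calibrated under
the multiplicative-lognormal null (empirical α ≈ nominal), whereas Welch's
unequal-variance variant (available via `equal_var=False`) is measurably
conservative at such small groups because of its estimated degrees of
freedom. Benjamini–Hochberg correction (statsmodels) is applied within each
(concentration, timepoint) stratum — matching how per-concentration
significance is reported — and two regimes are flagged: q < 0.1 and raw
p < 0.01. Testing is unpaired; counts are assumed already normalized.

## Single-nuclei proportions and rank ordering

"Expressing" means count > `expression_floor` (default 0). Proportions are
computed per (gene, cluster, library); strata with zero cells are reported
missing (NaN) rather than zero, since they carry no information. The
detection filter retains genes whose proportion exceeds `min_prop`
(default 0.05) in at least one stratum, with strict inequality; a pooled
option evaluates the floor per cluster after cell-count-weighted pooling of
libraries. Each retained (gene, cluster) is classified by the descending
order of its three library proportions; proportions within `tie_tol`
(default 0) are annotated as tied rather than ordered arbitrarily, because
silently breaking ties would fabricate orderings. The ordering summary
counts categories per gene across clusters; category counts always sum to
the number of classifiable pairs.

## Cross-platform concordance

Single-nuclei libraries are aggregated to pseudobulk by summing counts per
gene and scaling to counts per million (depth invariant by construction).
Fold changes are log2 with a pseudocount of 1 on both platforms, and
concordance is the Pearson correlation over a designated gene set — by
default the genes significant at raw p < 0.01 at the top dose, i.e. the
tissue-validated drug-responsive set.

## Synthetic data: what it emulates, and what it does not

`generate_counts` multiplies each planted response function by unit-mean
lognormal noise parameterized by its coefficient of variation (default
CV = 0.1; the replicate-level variance of normalized panel counts is not
otherwise constrained, and a multiplicative model matches count data whose
variance grows with the mean). Counts are non-negative reals on the
normalized-count scale, not integer reads. Planted defaults for the
standard 100-gene panel: 60 sigmoidal genes (baseline 50–500 counts,
4–15× dynamic range, th log-uniform over 0.05–5 μM, transition width about
one dilution step, both directions equally likely), 30 biphasic genes
(bumps and valleys with 8–15× amplitude, first transition at 0.06–0.09 μM
and second at 1.5–4 μM — the plateau placement a 7-point gradient can
actually resolve, and consistent with transitions near the critical
window), 10 flat genes (100–1000 counts).

`generate_cell_matrix` draws each cell's expression as a Bernoulli event at
the planted (gene, cluster, library) proportion, with expressing cells
receiving 1 + Poisson counts whose mean can carry per-library fold changes.
The pipeline's planted proportions carry the tissue-level log2 fold changes
(clipped at ±2) into the treated library plus a per-gene platform effect of
0.5 log2 units, reflecting that two platforms assaying different material
(whole tissue vs nuclei) agree only up to gene-level discordance; baseline
proportions are log-uniform over 0.01–0.5 so a realistic minority of genes
falls below the 5% detection floor.

Not emulated: ambient RNA, doublets, per-cell depth variation, probe
chemistry, or mapping/clustering artifacts — passing tests demonstrate the
statistical machinery on clean planted structure, not robustness to those
real-data features.

## Problem sizes and numerics

The standard study panel is 100 genes × 7 concentrations × 4 replicates at
one timepoint, with 8 clusters × 3 libraries × 400 cells in the
single-nuclei stage; classification of the panel takes ~30 s and the whole
pipeline under a minute. Degenerate inputs are handled explicitly: constant
series yield NaN scaled error and classify as flat; fewer than five
distinct concentrations is an error (four parameters need five supports);
zero-variance DE comparisons with equal means return p = 1; empty
(cluster, library) strata propagate as unclassifiable rank orders rather
than zeros. All randomness flows from explicit integer seeds through
`numpy.random.default_rng`; identical seeds give bit-identical outputs,
including the summary JSON.
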