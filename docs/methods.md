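# Methods

## Data model

The unit of analysis is a complete samples × genes matrix of
quantification cycles (Cq). Upstream of it sit technical triplicates and
plate controls; downstream sit the four stability algorithms and the
rank aggregation. All standard deviations in the package use the n−1
denominator, and all logarithms are base 2 unless a geNorm base is
passed explicitly.

Cq values must lie in (0, 45] cycles. The protocols this package targets
run 45 amplification cycles, so any later "signal" is an artifact; a
value outside the range is treated as a parse error, not clipped.

### Replicate collapsing and QC

A triplicate (sample, gene) set is averaged into one cell when its
sample SD is below `replicate_sd = 0.5` cycles; otherwise the cell
becomes missing and the set is reported as flagged. Singleton sets are
defined to have SD 0 and are kept — data is never discarded silently.
Because all four algorithms require a complete matrix, samples with any
missing cell are dropped up front with a logged warning rather than
imputed; imputation would leak structure into exactly the dispersion
statistics being ranked.

Plate controls pool across plates: the run passes when the SD of the
per-plate control Cq values is below 0.5 cycles. Fewer than two control
values is an error, since a single value has no dispersion.

### Efficiency correction

Amplification efficiency E (%) comes from a standard curve, the OLS
regression of Cq on log₁₀ relative dilution:

    E = (10^(−1/slope) − 1) × 100 .

A perfect-doubling assay has slope −1/log₁₀2 ≈ −3.3219. Assays are gated
at 95 ≤ E ≤ 105 and R² > 0.99 (strict inequality on R², closed interval
on E, matching how such gates are conventionally quoted). A non-negative
fitted slope marks a curve invalid instead of raising, because garbage
wells produce such fits and the caller should see them listed.

Raw Cq values are re-expressed on the ideal-doubling scale per gene:

    Cq_corr = Cq_min + ΔCq · log₂(amp),   amp = 1 + E/100,

where Cq_min is the lowest observed Cq of that gene (its
highest-expression sample, the calibrator) and ΔCq = Cq − Cq_min. This
is the unique affine transform that (a) is the identity at E = 100 %,
(b) leaves the calibrator unchanged, and (c) makes corrected
fold-changes satisfy 2^(−ΔCq_corr) = amp^(−ΔCq_raw). Cq_min is
recomputed within whatever sample set is being analyzed, so a subset
analysis is self-contained. When a subset is drawn (`subsample`), rows
are chosen uniformly without replacement with a user seed and kept in
input order.

## The four stability algorithms

All four consume the same complete matrix and report lower-is-better
values plus competition ranks.

**Comparative ΔCt.** For each ordered gene pair the SD across samples of
the per-sample Cq difference; a gene's score is the mean over its G−1
partners. Two genes whose difference is constant across samples are
either both stable or co-regulated — the method cannot tell, which is
its known blind spot.

**geNorm.** Relative quantities Q_ig = base^(Cq_min,g − Cq_ig)
(base 2 by default; efficiency is already folded in by the corrected-Cq
transform). M_g is the mean over partners of SD_i(log₂(Q_g/Q_k)); with
base 2 the initial all-gene M equals the ΔCt score gene-for-gene, a
relationship the test suite asserts to 1e-10 on random matrices. The
highest-M gene is excluded and M recomputed until two genes remain. The
value reported per gene is its M at exclusion; the final two genes share
the final M and rank 1, with the next gene at rank 3 (competition
ranking). A within-step tie on the highest M excludes the alphabetically
last gene, so runs are deterministic. The pairwise variation V_{n/n+1}
is the SD across samples of log₂(NF_n/NF_{n+1}), where NF_n is the
per-sample geometric mean of Q over the n top-ranked genes; the smallest
n with V < 0.15 is the recommended number of reference genes, falling
back to all G with a warning when no V crosses the cutoff.

**NormFinder.** On log-scale expression y_ig = −Cq_ig the model is
y_ig = α_g + β_i + ε_ig, with the shared per-sample effect β_i
representing RNA input and RT-yield differences. With v_g the sample
variance over samples of the doubly-centered residual
r_ig = y_ig − ȳ_i· − ȳ_·g + ȳ, the per-gene residual variance is the
moment estimate

    σ̂²_g = (v_g − Σ_k v_k / (G(G−1))) · G/(G−2),  floored at 0,

and the stability value is σ̂_g. The floor makes near-noiseless genes
report exactly 0. The estimator is unbiased under the model; the test
suite verifies mean σ̂² within 5 % of truth over 500 simulations at
n = 200, G = 8. Fewer than three genes makes the variance separation
non-identifiable and is an error. Condition groups are accepted (per
group ≥ 2 samples; residual variances estimated within groups and pooled
with size weights), but the default — and the reported ranking — is the
single-group analysis; no between-group term is added.

**BestKeeper.** The sample SD of each gene's Cq across samples
(option `mad`: mean absolute deviation about the arithmetic mean, the
original descriptor). SD is the default because it matches how published
panel tables label the column. The BestKeeper index (per-sample
geometric mean of Cq over genes) and each gene's Pearson correlation
with it are computed and reported, but never used for ranking. Unlike
the other three, BestKeeper is deliberately sensitive to a shared
per-sample shift; the suite asserts both directions of that contrast.

## Comprehensive ranking

Per gene, the geometric mean of its four per-algorithm ranks, computed
as product-then-4th-root. The product of small integer ranks is exact in
floating point, so equal rank multisets give bitwise-equal geomeans
regardless of column order — log-sum averaging does not, and the
difference matters because final ranks are competition ranks of the
geomean and must treat exact ties as ties. Output order among exact ties
is fixed by best single-algorithm rank, then gene name; the printed
geomean is rounded to 2 decimals while full precision is kept
internally.

Genes are classed "high expression" when mean raw Cq < 25 and "low"
otherwise (the boundary Cq = 25 belongs to "low"; the convention is
arbitrary but must be owned by one side). The report pairs suggested
references with target expression class, and a user-supplied advisory
exclusion list (e.g. a gene known to track leukocyte counts and hence
unsuitable for immunology work) annotates the text only — statistics and
ranks are never altered by it.

## Synthetic data generator

The generator emulates a multi-condition blood screening study:

    Cq_ig = μ_g + δ_i + Δ_{c(i),g} + ε_ig ,

with per-gene baselines μ_g spread over 22–31 cycles (the range typical
of abundant housekeeping transcripts in blood), a shared sample shift
δ_i ~ N(0, τ) with loading 1 on every gene, optional condition effects
Δ, and gene noise ε_ig ~ N(0, σ_g). Defaults: 13 genes × 60 samples,
τ = 0.5 cycles, σ_g ascending linearly 0.05–0.8 cycles, triplicates with
0.1-cycle well noise, four cyclically assigned conditions, outlier rate
0 (an outlier well adds +2 cycles). Ascending σ_g *is* the planted
stability truth, and the unit-loading δ_i is exactly the variation the
ΔCt/geNorm/NormFinder family is built to ignore and BestKeeper is not —
which makes the generator a sharp discriminating test between the two
families. One seeded RNG stream drives a dataset; the same seed gives
byte-identical files.

What the generator does not emulate: co-regulated gene groups (all ε are
independent, so it cannot probe the ΔCt/geNorm blind spot), inter-plate
batch effects, heavy-tailed or Cq-dependent noise, amplification-curve
artifacts, or missingness from failed wells other than the outlier
mechanism. Passing the recovery tests therefore shows the algorithms
rank independent per-gene noise correctly at realistic sizes, not that
they are robust to co-regulation.

Dilution series are generated from the exact slope relationship
slope = −1/log₁₀(amp) with optional Gaussian well noise, so fitting them
round-trips the true efficiency (to 4 decimals noiselessly; unbiased
within 1 % at 0.05-cycle noise over 100 seeds).

## Problem sizes and numerical choices

Simulation-backed tests run at 13 genes × 60 samples (20 seeds for rank
recovery), n = 200 × G = 8 × 500 replicates for estimator unbiasedness,
and n = 500 for monotonicity checks; these sizes put Monte-Carlo error
well inside the asserted tolerances while keeping the whole suite in a
few seconds. Exact-equality assertions (geNorm/ΔCt equivalence, shift
invariance) use absolute tolerances of 1e-9–1e-12, i.e. machine
precision for the sizes involved.

## Known limitations

* The full-matrix requirement is strict: a gene measured in only part of
  the panel silently costs those samples; the log tells you, the
  statistics do not.
* NormFinder's multi-group mode reports pooled within-group variation
  only; the classical between-group term is out of scope.
* BestKeeper's auxiliary regression statistics (beyond index
  correlations) and geNorm's normalization-factor export for downstream
  target quantification are not implemented.
* Instrument fluorescence parsing and baseline/threshold determination
  are out of scope; the pipeline starts at exported Cq values.
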