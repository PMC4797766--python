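# refstab

Reference-gene stability analysis for RT-qPCR.

Relative quantification of gene expression by RT-qPCR normalizes every
target gene against a reference ("housekeeping") gene, so the whole
analysis stands or falls with how stably that reference is expressed in
the tissue at hand. Before any expression study in a new species or
tissue, practitioners therefore screen a panel of candidate housekeeping
genes and rank them by expression stability. `refstab` implements that
screening pipeline end to end for anyone running such a panel — the
motivating use case is a 13-gene screen in beluga whale
(*Delphinapterus leucas*) blood, but nothing is specific to it:

* **Cq preprocessing** — parse wide/long Cq tables, average technical
  triplicates whose SD < 0.5 cycles (noisier sets are flagged to
  missing), pool plate controls (pass iff SD < 0.5), subsample
  reproducibly.
* **Amplification efficiency** — fit five-point 10-fold standard curves
  by OLS of Cq on log₁₀ dilution, estimate the efficiency
  E = (10^(−1/slope) − 1)·100 %, gate assays at 95–105 % and R² > 0.99,
  and re-express raw Cq on the ideal-doubling scale via
  Cq_corr = Cq_min + ΔCq·log₂(1 + E/100).
* **Four stability algorithms**, all "lower = more stable":
  comparative ΔCt (mean across partners of the SD of pairwise Cq
  differences), geNorm (stepwise-exclusion M values plus the pairwise
  variation V_{n/n+1} that decides how many references are needed,
  cutoff 0.15), NormFinder (model-based per-gene residual SD after
  removing a shared per-sample effect), and BestKeeper (per-gene Cq
  dispersion and correlation with the geometric-mean index).
* **Comprehensive ranking** — per gene, the geometric mean of its four
  per-algorithm ranks (competition ties: 1, 1, 3), sorted ascending.
* **Synthetic data** — a generator with known ground truth
  (Cq_ig = μ_g + δ_i + Δ_{c(i),g} + ε_ig) so every stage is testable
  without any instrument export.

The packaged data files under `refstab/data` carry the published
per-gene efficiencies and per-algorithm stability ranks for the beluga
blood panel (60- and 30-sample analyses), usable as worked inputs.

## Worked example

Simulate a small screen (6 genes, 40 samples, triplicates) and run the
full pipeline — collapse, efficiency correction, four algorithms,
comprehensive ranking:

```sh
refstab simulate --genes 6 --samples 40 --seed 42 --out demo/
refstab run --cq demo/cq_long.csv --layout long
```

```text
gene  geomean  rank  delta_ct_value  delta_ct_rank  bestkeeper_value  bestkeeper_rank  normfinder_value  normfinder_rank  genorm_value  genorm_rank
G01   1        1     0.4752          1              0.431             1                0                 1                0.1831        1
G02   1.68     2     0.5101          2              0.4587            2                0.2279            2                0.1831        1
G03   3        3     0.5727          3              0.5662            3                0.3472            3                0.3711        3
G04   4        4     0.66            4              0.6045            4                0.4993            4                0.5471        4
G05   5        5     0.7392          5              0.826             5                0.6058            5                0.6952        5
G06   6        6     0.8183          6              0.8513            6                0.7216            6                0.8183        6
```

with the recommendation block on stderr:

```text
Most stable genes (comprehensive ranking): G01, G02, G03, G04.
Pairwise variation: V2/3 below 0.15; 2 reference genes suffice.
Suggested references for high-expression targets: G01, G02.
Suggested references for low-expression targets: G03, G04.
```

The generator draws per-gene noise SDs ascending from G01 to G06, so the
recovered order matches the planted truth; the two final geNorm genes
share M = 0.1831 and rank 1 (hence ranks 1, 1, 3). V2/3 below the 0.15
cutoff means a normalization factor built from the two best genes is
already adequate.

The same pipeline runs on real exports: a wide CSV
(`sample_id,GAPDH,PGK1,...`) or a long one
(`sample_id,gene,replicate,cq`), plus an efficiency table
(`gene,efficiency_percent,efficiency_sd,r2`). `refstab rank --ranks ranks.csv`
aggregates an existing per-algorithm rank table; `refstab curve` fits and
gates standard curves; `--subsample 30 --seed 17` analyzes a reproducible
random subset.

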