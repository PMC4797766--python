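"""The four expression-stability algorithms for candidate reference genes.

All four consume a complete samples x genes Cq matrix and produce one
non-negative stability value per gene, lower meaning more stably expressed:

* **comparative delta-Ct** — for every ordered gene pair the SD across
  samples of the Cq difference; a gene's score is the mean of its pair SDs.
  Constant pairwise differences mean the two genes move together.
* **geNorm** — the same pairwise machinery expressed on relative
  quantities Q = base^(Cq_min - Cq). M_g is the mean across partners of
  the SD of log2(Q_g/Q_k); the gene with the highest M is excluded and M
  recomputed until two genes remain (they share the final M and rank 1).
  With base 2, the initial all-gene M equals the delta-Ct score exactly.
  geNorm also yields the pairwise variation V_{n/n+1}: the SD across
  samples of the log-ratio of normalization factors (geometric means of Q)
  built from the n and n+1 top-ranked genes. V below 0.15 is the
  conventional signal that n reference genes suffice.
* **NormFinder** — a model-based score. On log-scale expression
  y_ig = -Cq_ig the model is y_ig = alpha_g + beta_i + eps_ig with
  per-gene noise SD sigma_g; the stability value is a moment estimate of
  sigma_g from the doubly-centered residuals, so a gene is penalised only
  for variation that the shared per-sample effect cannot absorb.
* **BestKeeper** — purely descriptive: the dispersion (SD, optionally the
  mean absolute deviation) of each gene's raw Cq across samples, plus each
  gene's Pearson correlation with the BestKeeper index (per-sample
  geometric mean of Cq over all genes). Unlike the other three it is NOT
  invariant to a shared per-sample shift — a gene can look unstable simply
  because RNA input varied.

All SDs use the n-1 denominator; all logs are base 2 unless the geNorm
base is overridden.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .cq_io import CqMatrix
from .ranking import rank_values

Algorithm = Literal["delta_ct", "genorm", "normfinder", "bestkeeper"]

ALGORITHMS: tuple[Algorithm, ...] = (
    "delta_ct", "bestkeeper", "normfinder", "genorm",
)

#: geNorm convention: M above this flags a gene as unreliable
GENORM_M_CUTOFF = 1.5
#: pairwise variation below this means n reference genes are enough
GENORM_V_CUTOFF = 0.15


@dataclass
class StabilityResult:
    """Per-gene stability values and competition ranks of one algorithm."""

    algorithm: Algorithm
    values: pd.Series  # indexed by gene, lower = more stable
    ranks: pd.Series   # competition ranking (1,1,3 on a two-way tie)
    #: geNorm only: genes in exclusion order, least stable first
    exclusion_trace: list[str] | None = None

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            f"{self.algorithm}_value": self.values,
            f"{self.algorithm}_rank": self.ranks,
        })


@dataclass
class PairwiseVariationSeries:
    """geNorm V_{n/n+1} for n = 2..G-1."""

    entries: list[tuple[int, float]]
    cutoff: float = GENORM_V_CUTOFF

    def as_series(self) -> pd.Series:
        return pd.Series({f"V{n}/{n + 1}": v for n, v in self.entries})


def _require_complete(matrix: CqMatrix, algorithm: str) -> pd.DataFrame:
    if not matrix.is_complete():
        raise ValueError(
            f"{algorithm}: matrix has missing cells; drop incomplete samples "
            "first (CqMatrix.drop_incomplete_samples)"
        )
    return matrix.values.astype(float)


# ---------------------------------------------------------------------------
# comparative delta-Ct

def delta_ct_stability(matrix: CqMatrix) -> StabilityResult:
    """Mean across partner genes of the SD of pairwise Cq differences."""
    df = _require_complete(matrix, "delta_ct")
    n, g = df.shape
    if g < 2 or n < 2:
        raise ValueError("delta_ct: need >=2 genes and >=2 samples")
    arr = df.to_numpy()
    # pair_sd[g, k] = SD_i(Cq_ig - Cq_ik)
    diffs = arr[:, :, None] - arr[:, None, :]
    pair_sd = diffs.std(axis=0, ddof=1)
    scores = pair_sd.sum(axis=1) / (g - 1)  # diagonal is 0
    values = pd.Series(scores, index=df.columns, name="delta_ct")
    return StabilityResult("delta_ct", values, rank_values(values))


# ---------------------------------------------------------------------------
# geNorm

def _genorm_m(log_q: np.ndarray) -> np.ndarray:
    """M_g = mean over partners k of SD_i(log_q_ig - log_q_ik)."""
    g = log_q.shape[1]
    diffs = log_q[:, :, None] - log_q[:, None, :]
    pair_sd = diffs.std(axis=0, ddof=1)
    return pair_sd.sum(axis=1) / (g - 1)


def genorm(
    matrix: CqMatrix, amp_factor_base: float = 2.0
) -> tuple[StabilityResult, PairwiseVariationSeries]:
    """geNorm stepwise M ranking plus the pairwise-variation series.

    The value reported for each gene is its M at the step it was excluded;
    the two genes remaining at the end share the final M and rank 1. A tie
    on the highest M within a step excludes the alphabetically last gene so
    runs are deterministic.
    """
    df = _require_complete(matrix, "genorm")
    n, g = df.shape
    if g < 3:
        raise ValueError("genorm: stepwise exclusion needs >=3 genes")
    if n < 2:
        raise ValueError("genorm: need >=2 samples")
    if not amp_factor_base > 1.0:
        raise ValueError("genorm: amplification-factor base must exceed 1")

    # log2 relative quantity; constant per-gene offsets cancel in the
    # pairwise SDs but keep the conventional calibrator anyway
    arr = df.to_numpy()
    log_q = np.log2(amp_factor_base) * (arr.min(axis=0, keepdims=True) - arr)

    genes = list(df.columns)
    remaining = list(range(g))
    excluded: list[str] = []          # least stable first
    m_at_exclusion: dict[str, float] = {}

    while len(remaining) > 2:
        m = _genorm_m(log_q[:, remaining])
        worst_m = m.max()
        # tie on the worst M: drop the alphabetically last gene
        tied = [remaining[i] for i in range(len(remaining))
                if m[i] == worst_m]
        drop = max(tied, key=lambda j: genes[j])
        m_at_exclusion[genes[drop]] = float(m[remaining.index(drop)])
        excluded.append(genes[drop])
        remaining.remove(drop)

    final_m = float(_genorm_m(log_q[:, remaining])[0])
    final_pair = sorted(genes[j] for j in remaining)
    for name in final_pair:
        m_at_exclusion[name] = final_m

    # stability order: final pair first (alphabetical), then reverse exclusion
    order = final_pair + excluded[::-1]
    values = pd.Series([m_at_exclusion[name] for name in order],
                       index=order, name="genorm").reindex(df.columns)

    # competition ranks along the exclusion order (equal values share)
    rank_map: dict[str, int] = {}
    for pos, name in enumerate(order):
        if pos and values[name] == values[order[pos - 1]]:
            rank_map[name] = rank_map[order[pos - 1]]
        else:
            rank_map[name] = pos + 1
    ranks = pd.Series([rank_map[name] for name in df.columns],
                      index=df.columns, dtype=int, name="genorm_rank")

    # pairwise variation of normalization factors over the top-n genes
    col = {name: i for i, name in enumerate(genes)}
    v_entries = []
    for n_top in range(2, g):
        top_n = [col[name] for name in order[:n_top]]
        top_n1 = [col[name] for name in order[:n_top + 1]]
        nf_n = log_q[:, top_n].mean(axis=1)    # log2 geometric mean of Q
        nf_n1 = log_q[:, top_n1].mean(axis=1)
        v_entries.append((n_top, float((nf_n - nf_n1).std(ddof=1))))

    result = StabilityResult("genorm", values, ranks, exclusion_trace=excluded)
    return result, PairwiseVariationSeries(v_entries)


# ---------------------------------------------------------------------------
# NormFinder

def _normfinder_sigma2(y: np.ndarray) -> np.ndarray:
    """Moment estimate of per-gene residual variance under y = a_g + b_i + e."""
    n, g = y.shape
    r = (y - y.mean(axis=1, keepdims=True) - y.mean(axis=0, keepdims=True)
         + y.mean())
    v = r.var(axis=0, ddof=1)
    sigma2 = (v - v.sum() / (g * (g - 1))) * g / (g - 2)
    return np.maximum(sigma2, 0.0)


def normfinder_stability(
    matrix: CqMatrix, groups: Sequence[str] | None = None
) -> StabilityResult:
    """Model-based stability: estimated per-gene residual SD.

    Expression is taken as y_ig = -Cq_ig (log2 scale up to a per-gene
    constant, which the model absorbs). The shared per-sample effect b_i
    models RNA input and RT-yield differences; the stability value is the
    moment estimate of SD(eps) for each gene, floored at zero.

    With ``groups`` (one label per sample, >=2 samples each) the residual
    variance is estimated within each group and pooled, weighted by group
    size. No between-group term is added; a single pooled ranking is
    reported either way.
    """
    df = _require_complete(matrix, "normfinder")
    n, g = df.shape
    if g < 3:
        raise ValueError(
            "normfinder: variance separation needs >=3 genes"
        )
    y = -df.to_numpy()
    if groups is None:
        sigma2 = _normfinder_sigma2(y)
    else:
        labels = np.asarray(list(groups))
        if labels.shape[0] != n:
            raise ValueError("normfinder: one group label per sample required")
        sigma2 = np.zeros(g)
        total = 0
        for lab in pd.unique(labels):
            sub = y[labels == lab]
            if sub.shape[0] < 2:
                raise ValueError(
                    f"normfinder: group {lab!r} has <2 samples"
                )
            sigma2 += sub.shape[0] * _normfinder_sigma2(sub)
            total += sub.shape[0]
        sigma2 /= total
    values = pd.Series(np.sqrt(sigma2), index=df.columns, name="normfinder")
    return StabilityResult("normfinder", values, rank_values(values))


# ---------------------------------------------------------------------------
# BestKeeper

def bestkeeper(
    matrix: CqMatrix, dispersion: Literal["sd", "mad"] = "sd"
) -> tuple[StabilityResult, pd.Series]:
    """Per-gene Cq dispersion plus correlation with the BestKeeper index.

    ``dispersion`` is the sample SD by default or the mean absolute
    deviation about the arithmetic mean (the original BestKeeper
    descriptor). The returned Series holds each gene's Pearson r with the
    index (per-sample geometric mean of Cq over genes); it is reported for
    inspection but never used for ranking.
    """
    df = _require_complete(matrix, "bestkeeper")
    if df.shape[0] < 2:
        raise ValueError("bestkeeper: need >=2 samples")
    arr = df.to_numpy()
    if dispersion == "sd":
        disp = arr.std(axis=0, ddof=1)
    elif dispersion == "mad":
        disp = np.abs(arr - arr.mean(axis=0, keepdims=True)).mean(axis=0)
    else:
        raise ValueError(f"unknown dispersion {dispersion!r}")
    values = pd.Series(disp, index=df.columns, name="bestkeeper")

    index = np.exp(np.log(arr).mean(axis=1))  # geometric mean of Cq
    with np.errstate(invalid="ignore"):
        corr = pd.Series(
            [float(np.corrcoef(arr[:, j], index)[0, 1])
             if arr[:, j].std() > 0 else float("nan")
             for j in range(arr.shape[1])],
            index=df.columns, name="index_correlation",
        )
    return StabilityResult("bestkeeper", values, rank_values(values)), corr


# ---------------------------------------------------------------------------
# convenience driver

def run_all(
    matrix: CqMatrix,
    methods: Sequence[Algorithm] = ALGORITHMS,
    groups: Sequence[str] | None = None,
    bestkeeper_dispersion: Literal["sd", "mad"] = "sd",
    genorm_base: float = 2.0,
) -> tuple[dict[Algorithm, StabilityResult], PairwiseVariationSeries | None]:
    """Run the requested algorithms on one complete matrix."""
    results: dict[Algorithm, StabilityResult] = {}
    vseries = None
    for method in methods:
        if method == "delta_ct":
            results[method] = delta_ct_stability(matrix)
        elif method == "genorm":
            results[method], vseries = genorm(matrix, genorm_base)
        elif method == "normfinder":
            results[method] = normfinder_stability(matrix, groups=groups)
        elif method == "bestkeeper":
            results[method], _ = bestkeeper(matrix, bestkeeper_dispersion)
        else:
            raise ValueError(f"unknown method {method!r}")
    return results, vseries
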