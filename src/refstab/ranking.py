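"""Comprehensive ranking and reporting of candidate reference genes.

The four stability algorithms rarely agree exactly, so the field's usual
summary is rank aggregation: each gene gets the geometric mean of its four
per-algorithm ranks, and the final comprehensive ranking sorts by that
geometric mean. Competition ranking is used throughout — tied values share
the best rank and the following value skips (1, 1, 3).

Also here: the V-based recommendation of how many reference genes to use,
and the per-gene expression summary that splits the panel into high
(mean Cq < 25) and low (mean Cq >= 25) expression classes. Pairing a
reference gene with a target of similar expression level improves
normalization, which is why the report lists top genes per class.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

if TYPE_CHECKING:  # pragma: no cover
    from .stability import PairwiseVariationSeries, StabilityResult

from .cq_io import CqMatrix

#: mean raw Cq below this = "high expression"; the boundary itself is low
EXPRESSION_CLASS_BOUNDARY = 25.0


def rank_values(values: pd.Series | Sequence[float]) -> pd.Series:
    """Ascending competition ranks: (0.336, 0.336, 0.345) -> (1, 1, 3)."""
    s = pd.Series(values, dtype=float)
    if not np.isfinite(s.to_numpy()).all():
        raise ValueError("rank_values: values must be finite")
    ranks = stats.rankdata(s.to_numpy(), method="min")
    return pd.Series(ranks.astype(int), index=s.index, name="rank")


@dataclass
class ComprehensiveRanking:
    """Per-gene algorithm ranks, their geometric mean, and the final order."""

    table: pd.DataFrame  # columns: <algo>_rank..., geomean, rank

    @property
    def genes_in_order(self) -> list[str]:
        return list(self.table.sort_values("rank").index)

    def geomean(self, gene: str, decimals: int = 2) -> float:
        return round(float(self.table.loc[gene, "geomean"]), decimals)


def comprehensive_rank(
    ranks: pd.DataFrame | Mapping[str, Sequence[int]],
) -> ComprehensiveRanking:
    """Aggregate per-algorithm ranks by geometric mean.

    ``ranks``: one row per gene, one column per algorithm (DataFrame), or a
    mapping gene -> rank tuple. Final ranks are competition ranks of the
    geometric mean; exact geomean ties are broken for the ORDER (not the
    rank) by best single-algorithm rank, then gene name.
    """
    df = pd.DataFrame(ranks).T if isinstance(ranks, Mapping) else ranks.copy()
    if df.isna().any().any():
        missing = df.index[df.isna().any(axis=1)][0]
        raise ValueError(f"gene {missing!r} is missing an algorithm rank")
    arr = df.to_numpy(dtype=float)
    if (arr < 1).any():
        raise ValueError("ranks must be positive integers")
    # product-then-root: exact for integer ranks, so equal rank multisets
    # give bitwise-equal geomeans regardless of column order
    geomean = np.prod(arr, axis=1) ** (1.0 / arr.shape[1])

    out = df.copy()
    out.columns = [str(c) for c in out.columns]
    out["geomean"] = geomean
    out["rank"] = rank_values(out["geomean"]).to_numpy()
    # deterministic order among exact geomean ties: best single rank, then name
    order = sorted(
        out.index,
        key=lambda gene: (out.loc[gene, "geomean"],
                          df.loc[gene].min(), str(gene)),
    )
    return ComprehensiveRanking(out.loc[order])


def recommend_gene_count(
    vseries: "PairwiseVariationSeries", cutoff: float = 0.15
) -> tuple[int, bool]:
    """Smallest n with V_{n/n+1} < cutoff; (G, warned=True) if none.

    Returns ``(n, below_cutoff)``. ``below_cutoff`` False means no V value
    crossed the threshold and the fallback "use all G genes" applies.
    """
    if not vseries.entries:
        raise ValueError("empty pairwise-variation series")
    for n, v in vseries.entries:
        if v < cutoff:
            return n, True
    g = vseries.entries[-1][0] + 1
    return g, False


@dataclass
class ExpressionSummary:
    """Per-gene raw-Cq location and spread with the expression class."""

    table: pd.DataFrame  # columns: mean_cq, min_cq, max_cq, range, expression_class


def summarize_expression(matrix: CqMatrix) -> ExpressionSummary:
    """Mean/min/max raw Cq per gene and the high/low expression class."""
    if matrix.scale != "raw":
        raise ValueError("expression summary is defined on raw Cq")
    df = matrix.values
    mean = df.mean(axis=0)
    table = pd.DataFrame({
        "mean_cq": mean,
        "min_cq": df.min(axis=0),
        "max_cq": df.max(axis=0),
        "range": df.max(axis=0) - df.min(axis=0),
        "expression_class": np.where(
            mean < EXPRESSION_CLASS_BOUNDARY, "high", "low"
        ),
    })
    return ExpressionSummary(table)


@dataclass
class Report:
    """Assembled per-gene results plus the recommendation text."""

    table: pd.DataFrame
    recommendation: str

    def to_tsv(self) -> str:
        out = self.table.copy()
        out["geomean"] = out["geomean"].round(2)
        return out.to_csv(sep="\t", index=True, index_label="gene",
                          float_format="%.4g")


def build_report(
    results: Mapping[str, "StabilityResult"],
    comprehensive: ComprehensiveRanking | None = None,
    vseries: "PairwiseVariationSeries | None" = None,
    expression: ExpressionSummary | None = None,
    v_cutoff: float = 0.15,
    exclude_advisory: Iterable[str] = (),
) -> Report:
    """One row per gene, sorted by final rank, plus recommendation text.

    ``exclude_advisory`` lists genes the user deems unsuitable on grounds
    outside the statistics (e.g. known condition-linked regulation); they
    are annotated in the text but their ranks are never altered.
    """
    if not results:
        raise ValueError("no stability results given")
    gene_sets = {frozenset(r.values.index) for r in results.values()}
    if len(gene_sets) != 1:
        raise ValueError("stability results cover different gene sets")
    genes = next(iter(gene_sets))

    frames = []
    if comprehensive is not None:
        if frozenset(comprehensive.table.index) != genes:
            raise ValueError("comprehensive ranking covers a different gene set")
        frames.append(comprehensive.table[["geomean", "rank"]])
    for name in ("delta_ct", "bestkeeper", "normfinder", "genorm"):
        if name in results:
            frames.append(results[name].as_frame())
    table = pd.concat(frames, axis=1)
    sort_col = "rank" if comprehensive is not None else table.columns[1]
    table = table.sort_values(sort_col, kind="stable")

    lines = []
    if comprehensive is not None:
        ordered = [g for g in comprehensive.genes_in_order]
        usable = [g for g in ordered if g not in set(exclude_advisory)]
        lines.append("Most stable genes (comprehensive ranking): "
                     + ", ".join(ordered[:4]) + ".")
        for g in ordered:
            if g in set(exclude_advisory):
                lines.append(
                    f"Note: {g} ranks {comprehensive.table.loc[g, 'rank']} "
                    "but is flagged as unsuitable by the user; statistics "
                    "are reported unchanged."
                )
        if vseries is not None:
            n, ok = recommend_gene_count(vseries, cutoff=v_cutoff)
            if ok:
                lines.append(
                    f"Pairwise variation: V{n}/{n + 1} below {v_cutoff:g}; "
                    f"{n} reference genes suffice."
                )
            else:
                lines.append(
                    f"Pairwise variation never fell below {v_cutoff:g}; "
                    f"consider using all {n} genes (warning)."
                )
        if expression is not None:
            cls = expression.table["expression_class"]
            for klass in ("high", "low"):
                top = [g for g in usable if cls.get(g) == klass][:2]
                if top:
                    lines.append(
                        f"Suggested references for {klass}-expression "
                        "targets: " + ", ".join(top) + "."
                    )
    return Report(table=table, recommendation="\n".join(lines))
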