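"""Amplification-efficiency estimation and efficiency-corrected Cq.

An ideal PCR doubles the template every cycle; real assays amplify by a
factor ``amp = 1 + E/100`` per cycle where E is the efficiency in percent
(100% = perfect doubling). E is estimated from a standard curve — an OLS
regression of Cq on log10 of a serial template dilution — via

    E = (10^(-1/slope) - 1) * 100 .

A 10-fold dilution series with perfect doubling has slope
-1/log10(2) = -3.321928. Assays are conventionally accepted when E lies in
95-105% and the curve's R^2 exceeds 0.99.

Because different genes amplify with different efficiencies, raw Cq values
are not directly comparable across genes. The corrected-Cq transform
re-expresses each gene's Cq spread on the ideal-doubling scale, using the
lowest observed Cq of that gene (its highest-expression sample) as
calibrator:

    Cq_corr = Cq_min + dCq * log2(amp),    dCq = Cq - Cq_min .

At E = 100% this is the identity; the per-gene minimum is always unchanged.
Corrected fold-changes satisfy 2^(-dCq_corr) = amp^(-dCq_raw).
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cq_io import CqMatrix

DEFAULT_E_MIN = 95.0
DEFAULT_E_MAX = 105.0
DEFAULT_R2_MIN = 0.99

#: slope of a perfect-doubling standard curve on a log10 dilution axis
PERFECT_SLOPE = -1.0 / np.log10(2.0)


@dataclass
class StandardCurve:
    """OLS fit of Cq against log10 relative dilution for one assay."""

    gene: str
    points: list[tuple[float, float]]  # (log10 dilution, Cq)
    slope: float
    intercept: float
    r2: float
    valid: bool

    @property
    def efficiency_percent(self) -> float:
        if not self.valid:
            return float("nan")
        return float((10.0 ** (-1.0 / self.slope) - 1.0) * 100.0)


@dataclass
class EfficiencyRecord:
    """Per-gene amplification efficiency as used downstream."""

    gene: str
    efficiency_percent: float
    efficiency_sd: float = float("nan")
    r2: float = float("nan")

    @property
    def amp_factor(self) -> float:
        """Fold amplification per cycle, 1 + E/100 (2.0 at E = 100%)."""
        return 1.0 + self.efficiency_percent / 100.0


@dataclass
class GateResult:
    passed: bool
    reasons: list[str]

    def __bool__(self) -> bool:
        return self.passed


def fit_standard_curve(
    points: Sequence[tuple[float, float]], gene: str = ""
) -> StandardCurve:
    """Fit Cq = intercept + slope * log10(dilution) by ordinary least squares.

    Requires at least three points on at least three distinct dilution
    levels. A non-negative slope (Cq not decreasing with template) marks
    the curve invalid rather than raising: such fits happen with garbage
    wells and the caller decides what to do.
    """
    pts = [(float(x), float(y)) for x, y in points]
    if len(pts) < 3 or len({x for x, _ in pts}) < 3:
        raise ValueError(
            f"standard curve for {gene or '<gene>'} needs >=3 points on "
            ">=3 distinct dilution levels"
        )
    x = np.array([p[0] for p in pts])
    y = np.array([p[1] for p in pts])
    fit = stats.linregress(x, y)
    valid = fit.slope < 0
    return StandardCurve(gene=gene, points=pts, slope=float(fit.slope),
                         intercept=float(fit.intercept),
                         r2=float(fit.rvalue ** 2), valid=valid)


def curve_to_record(curves: Sequence[StandardCurve]) -> EfficiencyRecord:
    """Average >=1 curve fits of one gene into an efficiency record."""
    if not curves:
        raise ValueError("no curves given")
    genes = {c.gene for c in curves}
    if len(genes) > 1:
        raise ValueError(f"curves from different genes: {sorted(genes)}")
    es = np.array([c.efficiency_percent for c in curves])
    if np.isnan(es).any():
        raise ValueError(f"invalid curve among inputs for {curves[0].gene!r}")
    sd = float(np.std(es, ddof=1)) if len(es) > 1 else 0.0
    return EfficiencyRecord(
        gene=curves[0].gene,
        efficiency_percent=float(es.mean()),
        efficiency_sd=sd,
        r2=float(np.mean([c.r2 for c in curves])),
    )


def gate_efficiency(
    rec: EfficiencyRecord,
    e_min: float = DEFAULT_E_MIN,
    e_max: float = DEFAULT_E_MAX,
    r2_min: float = DEFAULT_R2_MIN,
) -> GateResult:
    """Accept an assay iff e_min <= E <= e_max and R^2 > r2_min."""
    reasons = []
    if not (e_min <= rec.efficiency_percent <= e_max):
        reasons.append(
            f"efficiency {rec.efficiency_percent:.2f}% outside "
            f"[{e_min:g}, {e_max:g}]%"
        )
    if not rec.r2 > r2_min:
        reasons.append(f"R^2 {rec.r2:.4g} not > {r2_min:g}")
    return GateResult(passed=not reasons, reasons=reasons)


def correct_cq(
    matrix: CqMatrix,
    effs: Sequence[EfficiencyRecord] | dict[str, EfficiencyRecord],
    assume_perfect: bool = False,
) -> CqMatrix:
    """Apply the efficiency correction gene by gene.

    Every gene column needs an :class:`EfficiencyRecord` unless
    ``assume_perfect`` supplies amp_factor 2 for the missing ones. The
    per-gene minimum Cq (calibrator) is computed over the samples present
    in ``matrix``, so a subset analysis is self-contained.
    """
    if matrix.scale != "raw":
        raise ValueError("correct_cq expects a raw-scale matrix")
    by_gene = ({r.gene: r for r in effs} if not isinstance(effs, dict)
               else dict(effs))
    out = matrix.values.copy()
    for gene in out.columns:
        rec = by_gene.get(gene)
        if rec is None:
            if not assume_perfect:
                raise KeyError(
                    f"no efficiency record for gene {gene!r} "
                    "(pass assume_perfect=True to use amp_factor 2)"
                )
            amp = 2.0
        else:
            amp = rec.amp_factor
        if not amp > 1.0:
            raise ValueError(f"gene {gene!r}: amp_factor {amp} must exceed 1")
        col = out[gene].to_numpy(dtype=float)
        cq_min = np.nanmin(col)
        out[gene] = cq_min + (col - cq_min) * np.log2(amp)
    return CqMatrix(out, scale="corrected", sample_meta=matrix.sample_meta)


# ---------------------------------------------------------------------------
# table I/O

def read_efficiency_table(path: str | Path | io.TextIOBase) -> list[EfficiencyRecord]:
    """Read a ``gene,efficiency_percent[,efficiency_sd][,r2]`` CSV."""
    df = pd.read_csv(path, comment="#")
    df = df.rename(columns={c: c.lower() for c in df.columns})
    if "gene" not in df.columns or "efficiency_percent" not in df.columns:
        raise ValueError(
            "efficiency table needs columns gene, efficiency_percent"
        )
    recs = []
    for _, row in df.iterrows():
        recs.append(EfficiencyRecord(
            gene=str(row["gene"]),
            efficiency_percent=float(row["efficiency_percent"]),
            efficiency_sd=float(row.get("efficiency_sd", float("nan"))),
            r2=float(row.get("r2", float("nan"))),
        ))
    return recs


def read_standard_curves(path: str | Path | io.TextIOBase) -> list[StandardCurve]:
    """Read a ``gene,log10_dilution,cq`` CSV, one fitted curve per gene."""
    df = pd.read_csv(path, comment="#")
    df = df.rename(columns={c: c.lower() for c in df.columns})
    needed = {"gene", "log10_dilution", "cq"}
    if not needed.issubset(df.columns):
        raise ValueError(f"standard-curve table needs columns {sorted(needed)}")
    curves = []
    for gene, grp in df.groupby("gene", sort=False):
        pts = list(zip(grp["log10_dilution"].astype(float),
                       grp["cq"].astype(float)))
        curves.append(fit_standard_curve(pts, gene=str(gene)))
    return curves


def beluga_efficiencies() -> list[EfficiencyRecord]:
    """The packaged published efficiencies for the 13-gene beluga panel."""
    ref = resources.files("refstab.data") / "beluga_efficiencies.csv"
    with ref.open("r", encoding="utf-8") as fh:
        return read_efficiency_table(fh)
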