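"""Synthetic qPCR Cq datasets with known ground truth.

The generator emulates a reference-gene screening study on blood samples:
a panel of candidate housekeeping genes measured by RT-qPCR in technical
triplicate across tens of samples drawn under several body conditions.
The generative model for the replicate-averaged Cq of sample i, gene g is

    Cq_ig = mu_g + delta_i + Delta_{c(i),g} + eps_ig

* ``mu_g`` — per-gene baseline Cq (defaults spread over 22-31 cycles,
  the range typical for abundant housekeeping transcripts in blood),
* ``delta_i ~ N(0, tau)`` — a shared per-sample shift with loading 1 on
  every gene, modelling RNA input and RT-yield differences; exactly the
  variation the delta-Ct/geNorm/NormFinder family is built to ignore and
  BestKeeper is not,
* ``Delta_{c,g}`` — optional condition-linked regulation (a gene with a
  nonzero Delta is a pseudo-housekeeper and should sink in the rankings),
* ``eps_ig ~ N(0, sigma_g)`` — gene-specific biological/technical noise;
  ascending sigma_g IS the true stability order.

Technical triplicates add N(0, replicate_sd) noise per well, and a small
outlier rate turns single wells into +2-cycle stragglers so that the
replicate-SD filter has something to catch. One seeded RNG stream drives
everything; the same seed gives byte-identical outputs.

Dilution series for standard-curve fitting are generated from the exact
relationship slope = -1/log10(amp_factor), plus optional well noise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .cq_io import CQ_MAX, CQ_MIN, CqMatrix, ReplicateSet

#: default panel: 13 genes, baselines spread over Cq 22-31
DEFAULT_N_GENES = 13
DEFAULT_N_SAMPLES = 60
DEFAULT_TAU = 0.5
DEFAULT_SIGMA_RANGE = (0.05, 0.8)
DEFAULT_REPLICATE_SD = 0.1
DEFAULT_CONDITIONS = ("healthy", "inflammation", "skin", "internal")


def _default_genes(n: int) -> list[str]:
    return [f"G{i + 1:02d}" for i in range(n)]


@dataclass
class SyntheticGroundTruth:
    """Generator parameters and the implied true stability order."""

    genes: list[str]
    mu: np.ndarray               # baseline Cq per gene
    sigma: np.ndarray            # per-gene noise SD (cycles)
    tau: float = DEFAULT_TAU     # shared sample-shift SD (cycles)
    condition_effects: dict[str, dict[str, float]] = field(default_factory=dict)
    efficiency_percent: np.ndarray | None = None  # per-gene true E
    replicate_sd: float = DEFAULT_REPLICATE_SD
    n_replicates: int = 3
    outlier_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.mu = np.asarray(self.mu, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        if len(self.genes) != len(self.mu) or len(self.genes) != len(self.sigma):
            raise ValueError("genes, mu and sigma must have equal length")
        if (self.sigma < 0).any() or self.tau < 0 or self.replicate_sd < 0:
            raise ValueError("noise SDs must be non-negative")
        if not 0 <= self.outlier_rate <= 1:
            raise ValueError("outlier_rate must be a probability")
        if self.n_replicates < 1:
            raise ValueError("need >=1 technical replicate")
        if self.efficiency_percent is not None:
            self.efficiency_percent = np.asarray(self.efficiency_percent,
                                                 dtype=float)
            if (self.efficiency_percent <= -100).any():
                raise ValueError("efficiency must exceed -100%")

    @property
    def true_stability_order(self) -> list[str]:
        """Genes sorted by true noise SD, most stable first."""
        return [self.genes[i] for i in np.argsort(self.sigma, kind="stable")]

    def to_json(self) -> str:
        d = asdict(self)
        d["mu"] = self.mu.tolist()
        d["sigma"] = self.sigma.tolist()
        if self.efficiency_percent is not None:
            d["efficiency_percent"] = self.efficiency_percent.tolist()
        d["true_stability_order"] = self.true_stability_order
        return json.dumps(d, indent=2)


def default_truth(
    n_genes: int = DEFAULT_N_GENES,
    sigma_range: tuple[float, float] = DEFAULT_SIGMA_RANGE,
    tau: float = DEFAULT_TAU,
    seed: int = 0,
    outlier_rate: float = 0.0,
    condition_effects: dict[str, dict[str, float]] | None = None,
) -> SyntheticGroundTruth:
    """The standard study design: baselines 22-31, sigma evenly spread."""
    genes = _default_genes(n_genes)
    mu = np.linspace(22.0, 31.0, n_genes)
    sigma = np.linspace(sigma_range[0], sigma_range[1], n_genes)
    return SyntheticGroundTruth(
        genes=genes, mu=mu, sigma=sigma, tau=tau,
        condition_effects=condition_effects or {},
        efficiency_percent=np.full(n_genes, 97.0),
        outlier_rate=outlier_rate, seed=seed,
    )


@dataclass
class SyntheticDataset:
    """Everything the generator emits for one seed."""

    truth: SyntheticGroundTruth
    matrix: CqMatrix             # replicate-free mean Cq (scale=raw)
    replicates: list[ReplicateSet]
    long_table: pd.DataFrame     # sample_id, gene, replicate, cq (+condition)


def generate_cq_dataset(
    truth: SyntheticGroundTruth,
    n_samples: int = DEFAULT_N_SAMPLES,
    conditions: tuple[str, ...] = DEFAULT_CONDITIONS,
) -> SyntheticDataset:
    """Draw one dataset from the generative model; deterministic per seed."""
    rng = np.random.default_rng(truth.seed)
    genes = truth.genes
    g = len(genes)

    cond = np.array([conditions[i % len(conditions)] for i in range(n_samples)])
    delta = rng.normal(0.0, truth.tau, size=n_samples)
    eps = rng.normal(0.0, 1.0, size=(n_samples, g)) * truth.sigma
    cq = truth.mu[None, :] + delta[:, None] + eps
    for c, effects in truth.condition_effects.items():
        mask = cond == c
        for gene, shift in effects.items():
            cq[mask, genes.index(gene)] += shift
    cq = np.clip(cq, CQ_MIN + 1e-6, CQ_MAX)

    sample_ids = [f"S{i + 1:03d}" for i in range(n_samples)]
    reps: list[ReplicateSet] = []
    rows = []
    for i, sid in enumerate(sample_ids):
        for j, gene in enumerate(genes):
            wells = cq[i, j] + rng.normal(0.0, truth.replicate_sd,
                                          size=truth.n_replicates)
            if truth.outlier_rate > 0:
                stray = rng.random(truth.n_replicates) < truth.outlier_rate
                wells = wells + 2.0 * stray
            wells = np.clip(wells, CQ_MIN + 1e-6, CQ_MAX)
            reps.append(ReplicateSet(sid, gene, [float(w) for w in wells]))
            for k, w in enumerate(wells, start=1):
                rows.append((sid, gene, k, float(w), cond[i]))

    matrix = CqMatrix(
        pd.DataFrame(cq, index=pd.Index(sample_ids, name="sample_id"),
                     columns=genes),
        scale="raw",
        sample_meta=pd.DataFrame(
            {"condition": cond},
            index=pd.Index(sample_ids, name="sample_id")),
    )
    long_table = pd.DataFrame(
        rows, columns=["sample_id", "gene", "replicate", "cq", "condition"])
    return SyntheticDataset(truth=truth, matrix=matrix, replicates=reps,
                            long_table=long_table)


def generate_dilution_series(
    gene: str,
    true_efficiency: float,
    intercept: float = 38.0,
    noise_sd: float = 0.0,
    levels: int = 5,
    step: float = 10.0,
    seed: int = 0,
) -> list[tuple[float, float]]:
    """Standard-curve points (log10 dilution, Cq) from a known efficiency.

    Dilution level j holds relative concentration step^(-j), j = 0..levels-1,
    so the x-axis runs 0, -1, -2, ... for a 10-fold series. The noiseless
    slope is -1/log10(1 + E/100); ``intercept`` is the Cq of the undiluted
    level. Fitting these points recovers E exactly at noise 0.
    """
    if true_efficiency <= -100:
        raise ValueError("efficiency must exceed -100%")
    if levels < 3:
        raise ValueError("need >=3 dilution levels")
    if step <= 1:
        raise ValueError("dilution step must exceed 1")
    rng = np.random.default_rng(seed)
    amp = 1.0 + true_efficiency / 100.0
    slope = -1.0 / np.log10(amp)
    pts = []
    for j in range(levels):
        x = -j * np.log10(step)
        cq = intercept + slope * x + rng.normal(0.0, noise_sd)
        pts.append((float(x), float(cq)))
    return pts


def write_dataset(ds: SyntheticDataset, outdir: str | Path) -> dict[str, Path]:
    """Emit cq_wide.csv, cq_long.csv, truth.json and curves.csv."""
    from .cq_io import write_cq_table  # local import keeps module load light

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "wide": outdir / "cq_wide.csv",
        "long": outdir / "cq_long.csv",
        "truth": outdir / "truth.json",
        "curves": outdir / "curves.csv",
    }
    write_cq_table(ds.matrix, paths["wide"])
    with paths["long"].open("w", encoding="utf-8", newline="") as fh:
        fh.write(f"# seed={ds.truth.seed}\n")
        ds.long_table.to_csv(fh, index=False)
    paths["truth"].write_text(ds.truth.to_json(), encoding="utf-8")

    rows = []
    effs = (ds.truth.efficiency_percent
            if ds.truth.efficiency_percent is not None
            else np.full(len(ds.truth.genes), 100.0))
    for j, gene in enumerate(ds.truth.genes):
        pts = generate_dilution_series(
            gene, float(effs[j]), intercept=float(ds.truth.mu[j] + 6.0),
            noise_sd=0.05, seed=ds.truth.seed + j + 1)
        rows += [(gene, x, cq) for x, cq in pts]
    pd.DataFrame(rows, columns=["gene", "log10_dilution", "cq"]).to_csv(
        paths["curves"], index=False)
    return paths
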