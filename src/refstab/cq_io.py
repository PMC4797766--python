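"""Reading, validating, collapsing and QC of raw qPCR Cq data.

A quantification cycle (Cq) is the PCR cycle at which a well's fluorescence
crosses the detection threshold; lower Cq means more template. Instruments
report one Cq per well, experiments run each (sample, gene) reaction in
technical triplicate, and every plate carries an identical "plate control"
reaction so that runs from many plates can be pooled. This module turns such
replicate-level data into a single complete samples x genes matrix:

* parse wide (one column per gene) or long (one row per well) tables,
* average technical replicates whose SD is below a threshold and flag the
  rest as missing,
* check plate-control consistency,
* subsample rows reproducibly.

Cq values must lie in (0, 45]: the protocols this package targets run 45
amplification cycles, so no genuine signal can appear later.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("refstab")

CQ_MIN = 0.0
CQ_MAX = 45.0

#: triplicates whose sample SD (n-1 denominator) reaches this many cycles
#: are considered unreliable and their cell becomes missing
DEFAULT_REPLICATE_SD_THRESHOLD = 0.5

#: plate controls must agree across plates to below this SD (cycles)
PLATE_CONTROL_SD_LIMIT = 0.5

_META_COLUMNS = ("condition", "animal_id")


class CqParseError(ValueError):
    """Raised when an input table cannot be interpreted as Cq data."""


def _check_cq_range(value: float, where: str) -> None:
    if not np.isfinite(value) or not (CQ_MIN < value <= CQ_MAX):
        raise CqParseError(
            f"Cq value {value!r} at {where} outside valid range "
            f"({CQ_MIN}, {CQ_MAX}]"
        )


@dataclass
class ReplicateSet:
    """Technical replicates of one (sample, gene) reaction."""

    sample_id: str
    gene: str
    cq_values: list[float]
    sd_threshold: float = DEFAULT_REPLICATE_SD_THRESHOLD

    def __post_init__(self) -> None:
        if len(self.cq_values) == 0:
            raise CqParseError(
                f"empty replicate set for ({self.sample_id}, {self.gene})"
            )
        for v in self.cq_values:
            _check_cq_range(v, f"({self.sample_id}, {self.gene})")

    @property
    def sd(self) -> float:
        """Sample SD (n-1 denominator); 0 for a singleton."""
        if len(self.cq_values) < 2:
            return 0.0
        return float(np.std(self.cq_values, ddof=1))

    @property
    def mean(self) -> float:
        return float(np.mean(self.cq_values))

    @property
    def status(self) -> Literal["kept", "flagged"]:
        return "kept" if self.sd < self.sd_threshold else "flagged"


@dataclass
class PlateControlSeries:
    """Plate-control Cq values, one per plate, and the pooled-SD verdict."""

    plate_ids: list[str]
    cq: list[float]
    sd: float
    passed: bool


@dataclass
class CqMatrix:
    """Samples x genes Cq matrix with a scale flag and optional metadata.

    ``values`` is a pandas DataFrame indexed by sample id with one column
    per gene. ``scale`` records whether the values are instrument-reported
    ("raw") or efficiency-corrected ("corrected"); the stability algorithms
    do not care which, but the distinction must never be lost silently.
    """

    values: pd.DataFrame
    scale: Literal["raw", "corrected"] = "raw"
    sample_meta: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            raise CqParseError("duplicate sample ids")
        if self.values.columns.has_duplicates:
            raise CqParseError("duplicate gene ids")
        if self.scale not in ("raw", "corrected"):
            raise CqParseError(f"unknown scale {self.scale!r}")
        arr = self.values.to_numpy(dtype=float)
        present = ~np.isnan(arr)
        if present.any():
            bad = present & ~((arr > CQ_MIN) & (arr <= CQ_MAX))
            if bad.any():
                i, j = np.argwhere(bad)[0]
                raise CqParseError(
                    f"Cq value {arr[i, j]} for sample "
                    f"{self.values.index[i]!r}, gene "
                    f"{self.values.columns[j]!r} outside ({CQ_MIN}, {CQ_MAX}]"
                )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_genes(self) -> int:
        return self.values.shape[1]

    def is_complete(self) -> bool:
        return not self.values.isna().any().any()

    def drop_incomplete_samples(self) -> "CqMatrix":
        """Drop samples with any missing cell (logged); keeps gene set."""
        keep = ~self.values.isna().any(axis=1)
        dropped = list(self.values.index[~keep])
        if dropped:
            logger.warning(
                "cq_io: dropping %d incomplete sample(s): %s",
                len(dropped), ", ".join(map(str, dropped)),
            )
        meta = None
        if self.sample_meta is not None:
            meta = self.sample_meta.loc[self.values.index[keep]]
        return CqMatrix(self.values.loc[keep], scale=self.scale,
                        sample_meta=meta)


# ---------------------------------------------------------------------------
# parsing

def read_cq_table(
    path: str | Path | io.TextIOBase,
    layout: Literal["wide", "long"] = "wide",
) -> CqMatrix | list[ReplicateSet]:
    """Read a delimited Cq table.

    Wide layout: header ``sample_id,<gene>,<gene>,...`` with optional
    ``condition`` / ``animal_id`` metadata columns; one row per sample.
    A leading ``# scale=raw|corrected`` comment line is honoured.

    Long layout: columns ``sample_id,gene,replicate,cq`` (plus optional
    metadata); returns one :class:`ReplicateSet` per (sample, gene).

    The delimiter (comma or tab) is sniffed from the header line.
    """
    if isinstance(path, (str, Path)):
        text = Path(path).read_text(encoding="utf-8")
    else:
        text = path.read()

    scale: Literal["raw", "corrected"] = "raw"
    lines = text.splitlines()
    data_lines = []
    for ln in lines:
        if ln.startswith("#"):
            stripped = ln.lstrip("#").strip()
            if stripped.startswith("scale="):
                value = stripped.split("=", 1)[1].strip()
                if value not in ("raw", "corrected"):
                    raise CqParseError(f"unknown scale {value!r} in header")
                scale = value  # type: ignore[assignment]
            continue
        if ln.strip():
            data_lines.append(ln)
    if not data_lines:
        raise CqParseError("no samples: file has no data rows")

    sep = "\t" if "\t" in data_lines[0] else ","
    try:
        df = pd.read_csv(io.StringIO("\n".join(data_lines)), sep=sep,
                         dtype={0: str})
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise CqParseError(f"malformed table: {exc}") from exc
    if df.shape[0] == 0:
        raise CqParseError("no samples: file has a header but no data rows")

    if layout == "long":
        return _parse_long(df)
    if layout == "wide":
        return _parse_wide(df, scale)
    raise ValueError(f"unknown layout {layout!r}")


def _parse_wide(df: pd.DataFrame, scale: str) -> CqMatrix:
    cols = list(df.columns)
    if not cols or cols[0].lower() not in ("sample_id", "sample"):
        raise CqParseError(
            f"malformed header: first column must be 'sample_id', got {cols[:1]}"
        )
    df = df.rename(columns={cols[0]: "sample_id"})
    if df["sample_id"].duplicated().any():
        dup = df["sample_id"][df["sample_id"].duplicated()].iloc[0]
        raise CqParseError(f"duplicate sample id {dup!r}")
    meta_cols = [c for c in df.columns if c.lower() in _META_COLUMNS]
    gene_cols = [c for c in df.columns
                 if c != "sample_id" and c not in meta_cols]
    if not gene_cols:
        raise CqParseError("malformed header: no gene columns")

    values = df[gene_cols].copy()
    for c in gene_cols:
        try:
            values[c] = pd.to_numeric(values[c])
        except (ValueError, TypeError) as exc:
            bad = df.loc[pd.to_numeric(df[c], errors="coerce").isna()
                         & df[c].notna()]
            row = bad.index[0] + 2 if len(bad) else "?"
            raise CqParseError(
                f"non-numeric Cq in column {c!r}, file row {row}"
            ) from exc
    values.index = pd.Index(df["sample_id"], name="sample_id")

    meta = None
    if meta_cols:
        meta = df[meta_cols].copy()
        meta.columns = [c.lower() for c in meta_cols]
        meta.index = values.index
    return CqMatrix(values, scale=scale, sample_meta=meta)  # range-checked there


def _parse_long(df: pd.DataFrame) -> list[ReplicateSet]:
    df = df.rename(columns={c: c.lower() for c in df.columns})
    required = {"sample_id", "gene", "replicate", "cq"}
    if not required.issubset(df.columns):
        raise CqParseError(
            f"malformed header: long layout needs columns {sorted(required)}, "
            f"got {list(df.columns)}"
        )
    keys = df[["sample_id", "gene", "replicate"]].astype(str)
    dup = keys.duplicated()
    if dup.any():
        k = keys[dup].iloc[0].tolist()
        raise CqParseError(f"duplicate (sample, gene, replicate) key {k}")
    cq = pd.to_numeric(df["cq"], errors="coerce")
    if cq.isna().any():
        row = int(cq.index[cq.isna()][0]) + 2
        raise CqParseError(f"non-numeric Cq at file row {row}")

    sets: list[ReplicateSet] = []
    # groupby(sort=False) preserves input ordering
    for (sample, gene), grp in df.groupby(["sample_id", "gene"], sort=False):
        sets.append(ReplicateSet(str(sample), str(gene),
                                 [float(v) for v in cq[grp.index]]))
    return sets


def write_cq_table(matrix: CqMatrix, path: str | Path) -> None:
    """Write the canonical wide CSV with a ``# scale=`` header comment."""
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as fh:
        fh.write(f"# scale={matrix.scale}\n")
        out = matrix.values.copy()
        if matrix.sample_meta is not None:
            out = pd.concat([matrix.sample_meta, out], axis=1)
        out.to_csv(fh, index=True, index_label="sample_id")


# ---------------------------------------------------------------------------
# replicate collapsing and QC

def collapse_replicates(
    reps: Sequence[ReplicateSet],
    sd_threshold: float = DEFAULT_REPLICATE_SD_THRESHOLD,
    scale: Literal["raw", "corrected"] = "raw",
) -> tuple[CqMatrix, list[ReplicateSet]]:
    """Average technical replicates into a CqMatrix; flag noisy sets.

    A set whose sample SD (n-1 denominator) is below ``sd_threshold`` cycles
    contributes its arithmetic mean; otherwise the cell is left missing and
    the set is returned in the flagged list. Singletons have SD 0 and are
    always kept. Sample/gene ordering follows first appearance.
    """
    seen: set[tuple[str, str]] = set()
    sample_ids: list[str] = []
    gene_ids: list[str] = []
    for r in reps:
        key = (r.sample_id, r.gene)
        if key in seen:
            raise CqParseError(
                f"(sample, gene) pair {key} appears in more than one replicate set"
            )
        seen.add(key)
        if r.sample_id not in sample_ids:
            sample_ids.append(r.sample_id)
        if r.gene not in gene_ids:
            gene_ids.append(r.gene)

    values = pd.DataFrame(np.nan, index=pd.Index(sample_ids, name="sample_id"),
                          columns=gene_ids, dtype=float)
    flagged: list[ReplicateSet] = []
    for r in reps:
        r.sd_threshold = sd_threshold
        if r.status == "kept":
            values.loc[r.sample_id, r.gene] = r.mean
        else:
            flagged.append(r)
    if flagged:
        logger.warning(
            "cq_io: %d replicate set(s) flagged (SD >= %.3g): %s",
            len(flagged), sd_threshold,
            ", ".join(f"({r.sample_id},{r.gene})" for r in flagged),
        )
    return CqMatrix(values, scale=scale), flagged


def plate_control_qc(
    controls: Iterable[tuple[str, float]] | Iterable[float],
) -> PlateControlSeries:
    """Pooled plate-control check: pass iff SD across plates < 0.5 cycles.

    ``controls`` is a sequence of (plate_id, cq) pairs or bare Cq values
    (one per plate, already replicate-averaged). At least two values are
    required for the SD to mean anything.
    """
    plate_ids: list[str] = []
    cqs: list[float] = []
    for i, item in enumerate(controls):
        if isinstance(item, (tuple, list)):
            pid, cq = item
        else:
            pid, cq = f"plate{i + 1}", item
        _check_cq_range(float(cq), f"plate control {pid!r}")
        plate_ids.append(str(pid))
        cqs.append(float(cq))
    if len(cqs) < 2:
        raise ValueError("insufficient controls: need >=2 plate-control Cq values")
    sd = float(np.std(cqs, ddof=1))
    passed = sd < PLATE_CONTROL_SD_LIMIT
    logger.info("cq_io: plate-control SD %.3f across %d plates -> %s",
                sd, len(cqs), "pass" if passed else "FAIL")
    return PlateControlSeries(plate_ids, cqs, sd, passed)


def subsample(matrix: CqMatrix, n: int, seed: int) -> CqMatrix:
    """Uniform sample of ``n`` rows without replacement, input order kept.

    Deterministic for a given seed. ``n`` equal to the sample count returns
    a copy of the input (all rows, original order).
    """
    if n > matrix.n_samples:
        raise ValueError(
            f"cannot subsample {n} of {matrix.n_samples} samples"
        )
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(matrix.n_samples, size=n, replace=False))
    meta = None
    if matrix.sample_meta is not None:
        meta = matrix.sample_meta.iloc[idx]
    return CqMatrix(matrix.values.iloc[idx], scale=matrix.scale,
                    sample_meta=meta)
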