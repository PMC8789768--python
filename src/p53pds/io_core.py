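"""Domain containers and TSV readers/writers.

All on-disk formats are plain tab-separated UTF-8 text with a ``.`` decimal
separator and no quoting, so that outputs diff cleanly between runs.
Expression matrices are genes x samples; every sample-keyed table
(mutation status, survival, drug response, scores) has one row per sample.
Missing or non-numeric cells are rejected at load time rather than imputed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: decimal places written for floating-point TSV cells; round-trip identity
#: holds up to this print precision.
FLOAT_FMT = "%.10g"


class FormatError(ValueError):
    """Malformed on-disk input (bad header, duplicate ids, non-numeric cell)."""


class ValidationError(ValueError):
    """In-memory object violates a domain invariant."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ExpressionMatrix:
    """Genes x samples continuous expression, unitless normalized values."""

    values: pd.DataFrame  # index = gene ids, columns = sample ids

    def __post_init__(self) -> None:
        v = self.values
        if v.index.duplicated().any():
            dup = v.index[v.index.duplicated()][0]
            raise ValidationError(f"duplicate gene id: {dup!r}")
        if v.columns.duplicated().any():
            dup = v.columns[v.columns.duplicated()][0]
            raise ValidationError(f"duplicate sample id: {dup!r}")
        if v.shape[0] < 2 or v.shape[1] < 2:
            raise ValidationError(
                f"expression matrix needs >=2 genes and >=2 samples, got {v.shape}"
            )
        arr = v.to_numpy()
        if not np.issubdtype(arr.dtype, np.number) or not np.isfinite(arr).all():
            bad = np.argwhere(~np.isfinite(v.to_numpy(dtype=float, na_value=np.nan)))
            g, s = bad[0]
            raise ValidationError(
                f"non-finite expression value at gene {v.index[g]!r}, sample {v.columns[s]!r}"
            )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class MutationStatus:
    """Binary TP53 protein-altering mutation label per sample (1 = mutant)."""

    status: pd.Series  # index = sample ids, int values in {0, 1}

    def __post_init__(self) -> None:
        s = self.status
        if s.index.duplicated().any():
            raise ValidationError(f"duplicate sample id: {s.index[s.index.duplicated()][0]!r}")
        if not s.isin([0, 1]).all():
            bad = s[~s.isin([0, 1])]
            raise ValidationError(f"mutation status must be 0/1, got {bad.iloc[0]!r}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.status.index)


@dataclass(frozen=True)
class SurvivalTable:
    """Right-censored time-to-event records: time >= 0, event in {0, 1}."""

    table: pd.DataFrame  # index = sample ids, columns: time, event

    def __post_init__(self) -> None:
        t = self.table
        if t.index.duplicated().any():
            raise ValidationError(f"duplicate sample id: {t.index[t.index.duplicated()][0]!r}")
        for col in ("time", "event"):
            if col not in t.columns:
                raise ValidationError(f"survival table missing column {col!r}")
        if (t["time"] < 0).any():
            raise ValidationError("negative survival time")
        if not t["event"].isin([0, 1]).all():
            raise ValidationError("event indicator must be 0/1")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    @property
    def time(self) -> pd.Series:
        return self.table["time"]

    @property
    def event(self) -> pd.Series:
        return self.table["event"]


@dataclass(frozen=True)
class DeficiencySignature:
    """Per-gene weights in [0, 1], split into up (beta > 0) and down (beta < 0)
    profiles. A gene belongs to at most one profile."""

    up_weights: dict[str, float]
    down_weights: dict[str, float]
    cancer_type_label: str = ""

    def __post_init__(self) -> None:
        overlap = set(self.up_weights) & set(self.down_weights)
        if overlap:
            raise ValidationError(f"gene(s) in both profiles: {sorted(overlap)[:3]}")
        for name, prof in (("up", self.up_weights), ("down", self.down_weights)):
            for g, w in prof.items():
                if not (0.0 <= w <= 1.0):
                    raise ValidationError(f"{name} weight for {g!r} outside [0,1]: {w}")

    @property
    def genes(self) -> set[str]:
        return set(self.up_weights) | set(self.down_weights)

    def is_usable(self) -> bool:
        """Each profile needs at least one strictly positive weight."""
        return any(w > 0 for w in self.up_weights.values()) and any(
            w > 0 for w in self.down_weights.values()
        )


@dataclass(frozen=True)
class PdsResult:
    """Per-sample p53 deficiency score; higher = lower inferred p53 activity."""

    sample_id: str
    es_up: float
    es_down: float
    nes_up: float
    nes_down: float
    pds: float

    def __post_init__(self) -> None:
        if not (-1.0 <= self.es_up <= 1.0 and -1.0 <= self.es_down <= 1.0):
            raise ValidationError("enrichment scores must lie in [-1, 1]")
        if self.pds != self.nes_up - self.nes_down:
            raise ValidationError("pds must equal nes_up - nes_down exactly")


@dataclass(frozen=True)
class DrugResponse:
    """Drug Activity Area per cell line; higher = more sensitive."""

    activity_area: pd.Series  # index = sample (cell-line) ids

    def __post_init__(self) -> None:
        a = self.activity_area
        if a.index.duplicated().any():
            raise ValidationError(f"duplicate sample id: {a.index[a.index.duplicated()][0]!r}")
        if not np.isfinite(a.to_numpy(dtype=float)).all():
            raise ValidationError("non-finite activity area")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.activity_area.index)


@dataclass(frozen=True)
class CohortRecord:
    """One cancer-type row of the mutation-status bookkeeping table."""

    cancer_type: str
    n_samples: int
    n_mutant: int
    n_wildtype: int
    pct_mutant: float

    def __post_init__(self) -> None:
        if self.n_mutant + self.n_wildtype != self.n_samples:
            raise ValidationError(
                f"{self.cancer_type}: n_mutant + n_wildtype != n_samples "
                f"({self.n_mutant} + {self.n_wildtype} != {self.n_samples})"
            )
        exact = 100.0 * self.n_mutant / self.n_samples
        if abs(exact - self.pct_mutant) > 0.05 + 1e-9:
            raise ValidationError(
                f"{self.cancer_type}: pct_mutant {self.pct_mutant} inconsistent "
                f"with counts ({exact:.2f})"
            )


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def _read_tsv(path: str | Path, **kw) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input file not found: {path}")
    return pd.read_csv(path, sep="\t", **kw)


def read_expression(path: str | Path) -> ExpressionMatrix:
    """Load a genes x samples TSV (first column gene ids, header sample ids)."""
    df = _read_tsv(path, index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if df.isna().any().any():
        na = np.argwhere(df.isna().to_numpy())[0]
        raise FormatError(
            f"{path}: missing value at gene {df.index[na[0]]!r}, sample {df.columns[na[1]]!r}"
        )
    try:
        df = df.astype(float)
    except (TypeError, ValueError) as exc:
        raise FormatError(f"{path}: non-numeric expression cell ({exc})") from exc
    try:
        return ExpressionMatrix(df)
    except ValidationError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_expression(expr: ExpressionMatrix, path: str | Path) -> None:
    expr.values.to_csv(path, sep="\t", index_label="gene", float_format=FLOAT_FMT)


def read_mutation_status(path: str | Path) -> MutationStatus:
    """Load a (sample, status) TSV with a header row."""
    df = _read_tsv(path)
    if df.shape[1] < 2:
        raise FormatError(f"{path}: expected columns sample, status")
    s = pd.Series(df.iloc[:, 1].to_numpy(), index=df.iloc[:, 0].astype(str), name="status")
    if s.isna().any():
        raise FormatError(f"{path}: missing status for sample {s.index[s.isna()][0]!r}")
    try:
        return MutationStatus(s.astype(int))
    except (ValidationError, ValueError) as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_mutation_status(status: MutationStatus, path: str | Path) -> None:
    status.status.rename_axis("sample").to_frame().to_csv(path, sep="\t")


def read_survival(path: str | Path) -> SurvivalTable:
    """Load a (sample, time, event) TSV."""
    df = _read_tsv(path)
    needed = {"time", "event"}
    if not needed.issubset(df.columns):
        raise FormatError(f"{path}: expected columns sample, time, event")
    df = df.set_index(df.columns[0])
    df.index = df.index.astype(str)
    try:
        return SurvivalTable(df[["time", "event"]].astype(float).assign(event=lambda d: d["event"].astype(int)))
    except (ValidationError, ValueError) as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_survival(surv: SurvivalTable, path: str | Path) -> None:
    surv.table.rename_axis("sample").to_csv(path, sep="\t", float_format=FLOAT_FMT)


def read_signature(path: str | Path) -> DeficiencySignature:
    """Load a (gene, direction, weight) TSV; direction is ``up`` or ``down``."""
    df = _read_tsv(path)
    needed = {"gene", "direction", "weight"}
    if not needed.issubset(df.columns):
        raise FormatError(f"{path}: expected columns gene, direction, weight")
    up: dict[str, float] = {}
    down: dict[str, float] = {}
    for _, row in df.iterrows():
        gene, direction, w = str(row["gene"]), str(row["direction"]), float(row["weight"])
        if direction not in ("up", "down"):
            raise FormatError(f"{path}: direction must be up|down, got {direction!r}")
        target = up if direction == "up" else down
        if gene in up or gene in down:
            raise FormatError(f"{path}: gene {gene!r} listed more than once")
        target[gene] = w
    try:
        return DeficiencySignature(up, down)
    except ValidationError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_signature(sig: DeficiencySignature, path: str | Path) -> None:
    """Canonical formatting: up profile then down, gene ids sorted within each."""
    rows = [("gene", "direction", "weight")]
    for direction, prof in (("up", sig.up_weights), ("down", sig.down_weights)):
        for g in sorted(prof):
            rows.append((g, direction, FLOAT_FMT % prof[g]))
    Path(path).write_text("\n".join("\t".join(r) for r in rows) + "\n", encoding="utf-8")


def read_drug_response(path: str | Path) -> DrugResponse:
    df = _read_tsv(path)
    if df.shape[1] < 2:
        raise FormatError(f"{path}: expected columns sample, activity_area")
    s = pd.Series(
        df.iloc[:, 1].to_numpy(dtype=float), index=df.iloc[:, 0].astype(str), name="activity_area"
    )
    try:
        return DrugResponse(s)
    except ValidationError as exc:
        raise FormatError(f"{path}: {exc}") from exc


def write_drug_response(resp: DrugResponse, path: str | Path) -> None:
    resp.activity_area.rename_axis("sample").to_frame().to_csv(
        path, sep="\t", float_format=FLOAT_FMT
    )


def read_scores(path: str | Path) -> pd.DataFrame:
    """Load a scores TSV (sample, es_up, es_down, nes_up, nes_down, pds)."""
    df = _read_tsv(path)
    if "pds" not in df.columns:
        raise FormatError(f"{path}: expected a 'pds' column")
    return df.set_index(df.columns[0]).astype(float)


def write_scores(results: Sequence[PdsResult], path: str | Path) -> None:
    df = pd.DataFrame(
        [(r.sample_id, r.es_up, r.es_down, r.nes_up, r.nes_down, r.pds) for r in results],
        columns=["sample", "es_up", "es_down", "nes_up", "nes_down", "pds"],
    ).set_index("sample")
    df.to_csv(path, sep="\t", float_format=FLOAT_FMT)


def read_cohort_table(path: str | Path) -> list[CohortRecord]:
    df = _read_tsv(path)
    return [
        CohortRecord(
            cancer_type=str(r["cancer_type"]),
            n_samples=int(r["n_samples"]),
            n_mutant=int(r["n_mutant"]),
            n_wildtype=int(r["n_wildtype"]),
            pct_mutant=float(r["pct_mutant"]),
        )
        for _, r in df.iterrows()
    ]


def packaged_table1() -> list[CohortRecord]:
    """The TP53 mutation bookkeeping table shipped with the package (20 TCGA
    cancer types, counts of mutant and wild-type patients)."""
    return read_cohort_table(Path(__file__).parent / "data" / "table1.tsv")


# ---------------------------------------------------------------------------
# alignment
# ---------------------------------------------------------------------------


def _ids_of(obj) -> list[str]:
    if isinstance(obj, ExpressionMatrix):
        return obj.sample_ids
    if hasattr(obj, "sample_ids"):
        return list(obj.sample_ids)
    if isinstance(obj, pd.Series) or isinstance(obj, pd.DataFrame):
        return [str(i) for i in obj.index]
    if isinstance(obj, Mapping):
        return [str(k) for k in obj.keys()]
    raise TypeError(f"cannot extract sample ids from {type(obj).__name__}")


def _take(obj, ids: list[str]):
    if isinstance(obj, ExpressionMatrix):
        return ExpressionMatrix(obj.values[ids])
    if isinstance(obj, MutationStatus):
        return MutationStatus(obj.status.loc[ids])
    if isinstance(obj, SurvivalTable):
        return SurvivalTable(obj.table.loc[ids])
    if isinstance(obj, DrugResponse):
        return DrugResponse(obj.activity_area.loc[ids])
    if isinstance(obj, (pd.Series, pd.DataFrame)):
        return obj.loc[ids]
    if isinstance(obj, Mapping):
        return {k: obj[k] for k in ids}
    raise TypeError(f"cannot subset {type(obj).__name__}")


def align_samples(*tables):
    """Restrict two or more sample-keyed tables to their common samples.

    The intersection is taken over sample ids and returned in sorted order,
    so the result is independent of input row order. Dropped counts are
    logged at INFO. Raises ``ValidationError`` on an empty intersection.
    """
    if len(tables) < 2:
        raise ValueError("align_samples needs at least two tables")
    common: set[str] | None = None
    for t in tables:
        ids = set(_ids_of(t))
        common = ids if common is None else common & ids
    assert common is not None
    if not common:
        raise ValidationError("no samples in common across tables")
    order = sorted(common)
    for t in tables:
        dropped = len(_ids_of(t)) - len(order)
        if dropped:
            logger.info(
                "align_samples: dropped %d of %d samples from %s",
                dropped,
                len(_ids_of(t)),
                type(t).__name__,
            )
    return tuple(_take(t, order) for t in tables)
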