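"""Domain types and TSV readers/writers for the miRNA ranking pipeline.

All tabular inputs and outputs are plain tab-separated text:

* expression matrices — features in rows, samples in columns, header row of
  sample IDs, first column the feature ID (log2-scale values);
* sample metadata — columns ``sample_id``, ``group`` and optionally
  ``time``/``event`` for survival analysis;
* interaction tables — two columns ``(mirna_id, mrna_id)`` of experimentally
  validated target pairs, duplicates collapsed;
* label sets — one miRNA ID per line, used only for evaluation;
* score tables — the ranked output of the pipeline, round-trippable.

Identifiers are opaque, case-sensitive strings (whitespace-trimmed); no
attempt is made to harmonize precursor/mature miRNA naming.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("mimrda")

SCORE_COLUMNS = [
    "mirna_id", "p_mirna", "log_fc", "m", "x", "p_nde", "c",
    "p_g", "p_g_fdr", "rank",
]


# ---------------------------------------------------------------------------
# errors

class MimrdaError(Exception):
    """Base class for all package errors."""


class FormatError(MimrdaError):
    """A file does not conform to its expected layout."""


class DuplicateIDError(FormatError):
    """Duplicate feature or sample identifiers in an input table."""


class NonNumericValueError(FormatError):
    """A cell of an expression matrix could not be parsed as a number."""


class ValidationError(MimrdaError):
    """An in-memory object violates a type invariant or precondition."""


class InsufficientReplicationError(ValidationError):
    """A group has fewer than two samples; no within-group variance exists."""


class DegenerateDataError(ValidationError):
    """Input data carry no usable signal (e.g. all variances zero)."""


def setup_logging(level: str = "INFO") -> None:
    logging.basicConfig(
        level=getattr(logging, level.upper()),
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
    )


# ---------------------------------------------------------------------------
# domain types

@dataclass(frozen=True)
class ExpressionMatrix:
    """Features x samples matrix of log2-scale expression values.

    ``data`` is a pandas DataFrame indexed by feature ID with sample IDs as
    columns. Construction validates uniqueness of both axes and finiteness of
    every value.
    """

    data: pd.DataFrame
    feature_kind: str  # "mRNA" | "miRNA"

    def __post_init__(self) -> None:
        if self.feature_kind not in ("mRNA", "miRNA"):
            raise ValidationError(f"unknown feature_kind {self.feature_kind!r}")
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise DuplicateIDError(f"duplicate feature IDs: {dups[:5]}")
        if self.data.columns.has_duplicates:
            dups = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise DuplicateIDError(f"duplicate sample IDs: {dups[:5]}")
        if self.data.size == 0:
            raise ValidationError("empty expression matrix")
        values = self.data.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise NonNumericValueError("expression matrix contains non-numeric cells")
        if not np.isfinite(values).all():
            raise ValidationError("expression matrix contains non-finite values")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()


@dataclass(frozen=True)
class SampleMetadata:
    """Per-sample group assignment with optional survival time/event.

    ``table`` is indexed by sample_id with a ``group`` column taking values
    ``tumor``/``normal``; if survival information is present, ``time`` (days,
    nonnegative) and ``event`` (True = death observed) are both present.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        if self.table.index.has_duplicates:
            raise DuplicateIDError("duplicate sample IDs in metadata")
        if "group" not in self.table.columns:
            raise FormatError("metadata requires a 'group' column")
        bad = set(self.table["group"]) - {"tumor", "normal"}
        if bad:
            raise ValidationError(f"unknown group labels: {sorted(bad)}")
        has_time = "time" in self.table.columns
        has_event = "event" in self.table.columns
        if has_time != has_event:
            raise ValidationError("'time' and 'event' must be present together")
        if has_time:
            t = self.table["time"].to_numpy(dtype=float)
            if (t < 0).any() or not np.isfinite(t).all():
                raise ValidationError("survival times must be finite and nonnegative")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    @property
    def groups(self) -> pd.Series:
        return self.table["group"]

    @property
    def has_survival(self) -> bool:
        return "time" in self.table.columns

    def samples_in(self, group: str) -> list[str]:
        return list(self.table.index[self.table["group"] == group])


@dataclass(frozen=True)
class InteractionTable:
    """Deduplicated set of validated (miRNA, mRNA) interaction pairs."""

    pairs: frozenset[tuple[str, str]]

    def __post_init__(self) -> None:
        for mirna, mrna in self.pairs:
            if not mirna or not mrna:
                raise ValidationError("empty identifier in interaction pair")

    @property
    def mirnas(self) -> set[str]:
        return {p[0] for p in self.pairs}

    @property
    def mrnas(self) -> set[str]:
        return {p[1] for p in self.pairs}

    def targets_of(self, mirna_id: str) -> set[str]:
        return {m for r, m in self.pairs if r == mirna_id}

    def target_map(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {}
        for mirna, mrna in self.pairs:
            out.setdefault(mirna, set()).add(mrna)
        return out

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass(frozen=True)
class LabelSet:
    """Curated disease-associated miRNA IDs, used only for evaluation."""

    mirna_ids: frozenset[str]
    source_name: str = ""

    def __post_init__(self) -> None:
        if not self.mirna_ids:
            raise ValidationError("label set is empty")


# ---------------------------------------------------------------------------
# readers

def _read_tsv(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        return pd.read_csv(path, sep="\t", index_col=0)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty file") from exc


def read_expression(path: str | Path, feature_kind: str,
                    log2_transform: bool = False) -> ExpressionMatrix:
    """Read a features x samples expression TSV.

    Parameters
    ----------
    path:
        TSV with a header row of sample IDs; first column holds feature IDs.
    feature_kind:
        ``"mRNA"`` or ``"miRNA"``.
    log2_transform:
        Apply ``log2(x + 1)`` to the values (for raw counts); by default
        values are assumed to be on the log2 scale already.
    """
    df = _read_tsv(path)
    df.index = df.index.astype(str).str.strip()
    df.columns = df.columns.astype(str).str.strip()
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise NonNumericValueError(f"{path}: {exc}") from exc
    if log2_transform:
        df = np.log2(df + 1.0)
    mat = ExpressionMatrix(data=df, feature_kind=feature_kind)
    logger.info("read %d %s features x %d samples from %s",
                len(mat.feature_ids), feature_kind, len(mat.sample_ids), path)
    return mat


def read_metadata(path: str | Path) -> SampleMetadata:
    """Read a sample metadata TSV (sample_id, group[, time, event])."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "group": str})
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty file") from exc
    if "sample_id" not in df.columns:
        raise FormatError(f"{path}: missing 'sample_id' column")
    df["sample_id"] = df["sample_id"].str.strip()
    df = df.set_index("sample_id")
    if "group" in df.columns:
        df["group"] = df["group"].str.strip()
    if "event" in df.columns:
        df["event"] = df["event"].astype(bool)
    return SampleMetadata(table=df)


def read_interactions(path: str | Path) -> InteractionTable:
    """Read a two-column (mirna_id, mrna_id) interaction TSV.

    A non-data first line (any token repeated in the body being absent is not
    checked; heuristically, a header is a first line whose fields contain no
    dot/dash-digit miRNA-like token AND equal common column names) — in
    practice the header is detected by matching the canonical column names.
    Duplicate pairs collapse under set semantics.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    pairs: set[tuple[str, str]] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = [f.strip() for f in line.split("\t")]
            if len(fields) != 2:
                raise FormatError(
                    f"{path}:{lineno}: expected 2 columns, got {len(fields)}")
            if lineno == 1 and {f.lower() for f in fields} & {
                    "mirna_id", "mirna", "mrna_id", "mrna", "target", "gene"}:
                continue  # header line
            if not fields[0] or not fields[1]:
                raise FormatError(f"{path}:{lineno}: empty identifier")
            pairs.add((fields[0], fields[1]))
    table = InteractionTable(pairs=frozenset(pairs))
    logger.info("read %d interaction pairs (%d miRNAs, %d mRNAs) from %s",
                len(table), len(table.mirnas), len(table.mrnas), path)
    return table


def read_labels(path: str | Path, source_name: str | None = None) -> LabelSet:
    """Read a label file with one miRNA ID per line."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    ids = {line.strip() for line in open(path) if line.strip()}
    return LabelSet(mirna_ids=frozenset(ids),
                    source_name=source_name or path.stem)


# ---------------------------------------------------------------------------
# writers

def write_scores(table: pd.DataFrame, path: str | Path) -> None:
    """Write a global-score table as TSV, sorted by rank.

    The required columns (mirna_id, p_mirna, log_fc, m, x, p_nde, c, p_g,
    p_g_fdr, rank) come first; any extra columns (e.g. flags) follow. Floats
    are written with shortest round-trip repr, so read_scores(write_scores(t))
    reproduces the table exactly.
    """
    missing = [c for c in SCORE_COLUMNS if c not in table.columns]
    if missing:
        raise ValidationError(f"score table missing columns: {missing}")
    extra = [c for c in table.columns if c not in SCORE_COLUMNS]
    out = table[SCORE_COLUMNS + extra]
    if len(out):
        out = out.sort_values("rank")
    out.to_csv(path, sep="\t", index=False)


def read_scores(path: str | Path) -> pd.DataFrame:
    """Read back a score table written by :func:`write_scores`."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", dtype={"mirna_id": str})
    missing = [c for c in SCORE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing columns {missing}")
    return df


def write_metadata(meta: SampleMetadata, path: str | Path) -> None:
    meta.table.to_csv(path, sep="\t", index=True, index_label="sample_id")


def write_expression(expr: ExpressionMatrix, path: str | Path) -> None:
    expr.data.to_csv(path, sep="\t", index=True, index_label="feature_id")


def write_interactions(table: InteractionTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("mirna_id\tmrna_id\n")
        for mirna, mrna in sorted(table.pairs):
            fh.write(f"{mirna}\t{mrna}\n")


# ---------------------------------------------------------------------------
# config

def load_config(path: str | Path) -> dict:
    """Load a YAML (or JSON — YAML is a superset) config mapping."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise FormatError(f"{path}: config must be a mapping")
    return cfg
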