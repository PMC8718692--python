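"""Readers and writers for the external formats the pipeline touches.

The pipeline's universal substrate is :class:`ExpressionMatrix`, a genes x
samples numeric table with declared units.  Beside it live the curated m6A
regulator registry (24 genes split into writer / eraser / reader roles),
GMT gene-set collections, MAF-lite somatic-mutation tables, gene-level
copy-number call matrices and per-sample clinical tables.

All loaders validate their invariants eagerly and raise :class:`FormatError`
or :class:`SchemaError` with coordinates, so that a malformed input fails at
the boundary rather than deep inside an analysis stage.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "FormatError",
    "SchemaError",
    "Regulator",
    "RegulatorRegistry",
    "load_registry",
    "ExpressionMatrix",
    "read_expression",
    "write_expression",
    "GeneSetCollection",
    "read_gmt",
    "write_gmt",
    "MutationTable",
    "read_mutations",
    "CopyNumberCalls",
    "read_cnv",
    "ClinicalTable",
    "read_clinical",
]

PIPELINE_VERSION = "m6ascore-0.1.0"


class FormatError(ValueError):
    """A file is syntactically or semantically malformed."""


class SchemaError(ValueError):
    """A table is missing mandatory columns or uses unknown tokens."""


# ---------------------------------------------------------------------------
# Regulator registry
# ---------------------------------------------------------------------------

ROLES = ("writer", "eraser", "reader")

#: The curated m6A regulator panel: 10 writers, 2 erasers, 12 readers.
#: "WTA" occasionally seen in the literature is a truncation of WTAP and is
#: normalised on load.
_DEFAULT_PANEL: tuple[tuple[str, str], ...] = (
    ("CBLL1", "writer"),
    ("ELAVL1", "writer"),
    ("METTL3", "writer"),
    ("METTL14", "writer"),
    ("METTL16", "writer"),
    ("KIAA1429", "writer"),
    ("RBM15", "writer"),
    ("RBM15B", "writer"),
    ("WTAP", "writer"),
    ("ZC3H13", "writer"),
    ("ALKBH5", "eraser"),
    ("FTO", "eraser"),
    ("YTHDC1", "reader"),
    ("YTHDC2", "reader"),
    ("YTHDF1", "reader"),
    ("YTHDF2", "reader"),
    ("YTHDF3", "reader"),
    ("FMR1", "reader"),
    ("HNRNPA2B1", "reader"),
    ("HNRNPC", "reader"),
    ("IGF2BP1", "reader"),
    ("IGF2BP2", "reader"),
    ("IGF2BP3", "reader"),
    ("LRPPRC", "reader"),
)

#: Symbol aliases normalised on load (logged).
_SYMBOL_ALIASES = {"WTA": "WTAP"}


@dataclass(frozen=True)
class Regulator:
    symbol: str
    role: str


@dataclass(frozen=True)
class RegulatorRegistry:
    """The m6A regulator panel with writer/eraser/reader roles.

    The default registry holds exactly 24 genes (10 writers, 2 erasers,
    12 readers).  User-supplied registries may be smaller; they are flagged
    ``canonical=False`` and the strict partition invariant is relaxed.
    """

    entries: tuple[Regulator, ...]
    canonical: bool = True

    def __post_init__(self) -> None:
        symbols = [e.symbol for e in self.entries]
        if len(symbols) != len(set(symbols)):
            dupes = sorted({s for s in symbols if symbols.count(s) > 1})
            raise FormatError(f"duplicate regulator symbols: {dupes}")
        for e in self.entries:
            if not e.symbol or e.symbol != e.symbol.upper():
                raise FormatError(f"invalid gene symbol {e.symbol!r}")
            if e.role not in ROLES:
                raise SchemaError(f"unknown regulator role {e.role!r}")
        if self.canonical:
            counts = self.role_counts()
            if len(self.entries) != 24 or counts != {"writer": 10, "eraser": 2, "reader": 12}:
                raise FormatError(
                    "canonical registry must hold 24 genes "
                    f"(10 writers, 2 erasers, 12 readers); got {counts}"
                )

    @property
    def symbols(self) -> list[str]:
        return [e.symbol for e in self.entries]

    def role_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for e in self.entries:
            counts[e.role] = counts.get(e.role, 0) + 1
        return counts

    def by_role(self, role: str) -> list[str]:
        return [e.symbol for e in self.entries if e.role == role]

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)


def load_registry(path: str | Path | None = None) -> RegulatorRegistry:
    """Load a regulator registry.

    Without a path, returns the built-in 24-gene panel.  With a path, reads a
    two-column table (symbol, role), normalises known symbol aliases
    (``WTA`` -> ``WTAP``, logged) and relaxes the 24-gene partition invariant
    (the registry is flagged non-canonical).
    """
    if path is None:
        return RegulatorRegistry(tuple(Regulator(s, r) for s, r in _DEFAULT_PANEL))
    rows: list[Regulator] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.replace(",", "\t").split("\t")
            if len(fields) < 2:
                raise FormatError(f"{path}:{lineno}: expected 'symbol<TAB>role'")
            symbol, role = fields[0].strip().upper(), fields[1].strip().lower()
            if symbol in _SYMBOL_ALIASES:
                logger.info("registry: normalising alias %s -> %s", symbol, _SYMBOL_ALIASES[symbol])
                symbol = _SYMBOL_ALIASES[symbol]
            rows.append(Regulator(symbol, role))
    if not rows:
        raise FormatError(f"{path}: empty registry file")
    registry = RegulatorRegistry(tuple(rows), canonical=False)
    if len(registry) != 24:
        logger.warning("registry: %d entries, flagged non-canonical", len(registry))
    return registry


# ---------------------------------------------------------------------------
# Expression matrices
# ---------------------------------------------------------------------------

UNITS = ("fpkm", "tpm", "log2tpm", "log2intensity")


@dataclass
class ExpressionMatrix:
    """Genes x samples numeric matrix with unit metadata.

    ``values`` is a DataFrame indexed by gene symbol with sample ids as
    columns.  Invariants: unique ids, finite values, no missing entries,
    non-negative values for linear (fpkm/tpm) units.
    """

    values: pd.DataFrame
    unit: str

    def __post_init__(self) -> None:
        if self.unit not in UNITS:
            raise SchemaError(f"unknown expression unit {self.unit!r} (choose from {UNITS})")
        if self.values.size == 0:
            raise FormatError("empty expression matrix")
        if self.values.index.duplicated().any():
            dupes = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate gene ids: {dupes[:5]}")
        if self.values.columns.duplicated().any():
            dupes = self.values.columns[self.values.columns.duplicated()].unique().tolist()
            raise FormatError(f"duplicate sample ids: {dupes[:5]}")
        arr = self.values.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise FormatError("expression matrix contains non-numeric values")
        if np.isnan(arr).any():
            r, c = np.argwhere(np.isnan(arr))[0]
            raise FormatError(
                f"missing value at gene {self.values.index[r]!r}, "
                f"sample {self.values.columns[c]!r} (default policy: reject)"
            )
        if not np.isfinite(arr).all():
            raise FormatError("expression matrix contains non-finite values")
        if self.unit in ("fpkm", "tpm") and (arr < 0).any():
            raise FormatError(f"negative values not allowed for unit {self.unit!r}")

    @property
    def genes(self) -> list[str]:
        return self.values.index.tolist()

    @property
    def samples(self) -> list[str]:
        return self.values.columns.tolist()

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset_genes(self, genes: Iterable[str]) -> "ExpressionMatrix":
        genes = [g for g in genes if g in self.values.index]
        if not genes:
            raise KeyError("none of the requested genes are present")
        return ExpressionMatrix(self.values.loc[genes], self.unit)


def _read_table(path: str | Path) -> pd.DataFrame:
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else None
    return pd.read_csv(path, sep=sep, engine="python" if sep is None else "c",
                       index_col=0, comment="#")


def read_expression(
    path: str | Path,
    unit: str,
    impute_median: bool = False,
) -> ExpressionMatrix:
    """Read a TSV/CSV expression matrix (first column gene ids, header = samples).

    Duplicate gene rows are collapsed by the per-sample maximum (the usual
    probe-collapse convention).  Missing values are rejected by default;
    ``impute_median=True`` replaces them with the per-gene median instead.
    """
    df = _read_table(path)
    if df.size == 0:
        raise FormatError(f"{path}: empty matrix")
    for col in df.columns:
        bad = pd.to_numeric(df[col], errors="coerce")
        raw_na = df[col].isna()
        non_numeric = bad.isna() & ~raw_na
        if non_numeric.any():
            gene = df.index[non_numeric.to_numpy().argmax()]
            raise FormatError(f"{path}: non-numeric cell at gene {gene!r}, sample {col!r}")
        df[col] = bad
    if df.index.duplicated().any():
        n = int(df.index.duplicated().sum())
        logger.info("read_expression: collapsing %d duplicate gene rows by max", n)
        df = df.groupby(level=0, sort=False).max()
    if impute_median and df.isna().any().any():
        med = df.median(axis=1)
        df = df.apply(lambda col: col.fillna(med))
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return ExpressionMatrix(df.astype(float), unit)


def write_expression(x: ExpressionMatrix, path: str | Path) -> None:
    """Write a TSV with a header comment carrying the pipeline version and unit."""
    with open(path, "w") as fh:
        fh.write(f"# {PIPELINE_VERSION} unit={x.unit}\n")
        x.values.to_csv(fh, sep="\t", index_label="gene")


# ---------------------------------------------------------------------------
# Gene sets (GMT)
# ---------------------------------------------------------------------------

@dataclass
class GeneSetCollection:
    """Named gene sets; set names unique, members unique within a set."""

    sets: dict[str, list[str]]

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes:
                raise FormatError(f"gene set {name!r} is empty")
            if len(genes) != len(set(genes)):
                raise FormatError(f"gene set {name!r} has duplicate members")

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def names(self) -> list[str]:
        return list(self.sets)


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file: ``name TAB description TAB gene ...`` per line.

    The description column is discarded; repeated genes within a set are
    deduplicated (logged).
    """
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line needs >=3 tab-separated fields")
            name, genes = fields[0], [g for g in fields[2:] if g]
            if name in sets:
                raise FormatError(f"{path}:{lineno}: duplicate set name {name!r}")
            deduped = list(dict.fromkeys(genes))
            if len(deduped) != len(genes):
                logger.info("read_gmt: set %s had %d duplicate genes", name, len(genes) - len(deduped))
            sets[name] = deduped
    if not sets:
        raise FormatError(f"{path}: empty GMT file")
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, genes in collection.sets.items():
            fh.write("\t".join([name, "na", *genes]) + "\n")


# ---------------------------------------------------------------------------
# Mutations (MAF-lite)
# ---------------------------------------------------------------------------

VARIANT_CLASSES = ("missense", "nonsense", "frameshift", "splice", "in_frame", "silent", "other")

#: MAF Variant_Classification tokens -> simplified class.
_MAF_CLASS_MAP = {
    "missense_mutation": "missense",
    "missense": "missense",
    "nonsense_mutation": "nonsense",
    "nonsense": "nonsense",
    "frame_shift_del": "frameshift",
    "frame_shift_ins": "frameshift",
    "frameshift": "frameshift",
    "splice_site": "splice",
    "splice": "splice",
    "in_frame_del": "in_frame",
    "in_frame_ins": "in_frame",
    "in_frame": "in_frame",
    "silent": "silent",
    "synonymous": "silent",
}

_MAF_COLUMNS = ("Tumor_Sample_Barcode", "Hugo_Symbol", "Variant_Classification")


@dataclass
class MutationTable:
    """Long-format somatic mutation records (sample, gene, variant class).

    Duplicate (sample, gene, class) records are allowed: they are multiple hits.
    """

    records: pd.DataFrame  # columns: sample_id, gene_symbol, variant_class

    def __post_init__(self) -> None:
        needed = {"sample_id", "gene_symbol", "variant_class"}
        if not needed.issubset(self.records.columns):
            raise SchemaError(f"mutation table needs columns {sorted(needed)}")
        if len(self.records):
            if self.records[["sample_id", "gene_symbol"]].isin(["", None]).any().any():
                raise FormatError("empty sample or gene identifiers in mutation table")
            bad = set(self.records["variant_class"]) - set(VARIANT_CLASSES)
            if bad:
                raise SchemaError(f"unknown variant classes: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def samples(self) -> list[str]:
        return self.records["sample_id"].unique().tolist()


def read_mutations(path: str | Path) -> MutationTable:
    """Read a MAF-lite TSV (Tumor_Sample_Barcode, Hugo_Symbol, Variant_Classification)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    missing = [c for c in _MAF_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing mandatory MAF columns {missing}")
    classes = (
        df["Variant_Classification"].str.strip().str.lower().map(lambda v: _MAF_CLASS_MAP.get(v, "other"))
    )
    records = pd.DataFrame(
        {
            "sample_id": df["Tumor_Sample_Barcode"].str.strip(),
            "gene_symbol": df["Hugo_Symbol"].str.strip(),
            "variant_class": classes,
        }
    )
    return MutationTable(records)


# ---------------------------------------------------------------------------
# Copy-number calls
# ---------------------------------------------------------------------------

@dataclass
class CopyNumberCalls:
    """Gene x sample integer call matrix restricted to {-2,-1,0,1,2}."""

    calls: pd.DataFrame

    def __post_init__(self) -> None:
        arr = self.calls.to_numpy()
        if not np.isin(arr, (-2, -1, 0, 1, 2)).all():
            bad = arr[~np.isin(arr, (-2, -1, 0, 1, 2))][0]
            raise FormatError(f"CNV call {bad!r} outside {{-2..2}}")


def read_cnv(path: str | Path) -> CopyNumberCalls:
    df = _read_table(path)
    try:
        df = df.astype(int)
    except ValueError as exc:
        raise FormatError(f"{path}: non-integer CNV call ({exc})") from exc
    return CopyNumberCalls(df)


# ---------------------------------------------------------------------------
# Clinical tables
# ---------------------------------------------------------------------------

STAGES = ("I", "II", "III", "IV", "unknown")

_CLINICAL_DEFAULT_MAP = {
    "sample_id": "sample_id",
    "time": "time",
    "event": "event",
    "stage": "stage",
    "t_cat": "t_cat",
    "n_cat": "n_cat",
    "m_cat": "m_cat",
    "age": "age",
    "sex": "sex",
    "radiotherapy": "radiotherapy",
}


@dataclass
class ClinicalTable:
    """Per-sample survival and clinicopathological covariates.

    ``time`` is strictly positive in the declared unit; ``event`` is 0/1.
    Rows missing time or event are dropped at load and counted in
    ``n_excluded`` (mirroring the usual exclusion of patients without
    survival information).
    """

    data: pd.DataFrame  # indexed by sample_id
    time_unit: str = "months"
    n_excluded: int = 0

    def __post_init__(self) -> None:
        if "time" not in self.data.columns or "event" not in self.data.columns:
            raise SchemaError("clinical table needs 'time' and 'event' columns")
        if (self.data["time"] <= 0).any():
            raise FormatError("clinical times must be > 0 after exclusion")
        if not self.data["event"].isin((0, 1)).all():
            raise FormatError("clinical event indicator must be 0/1")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def samples(self) -> list[str]:
        return self.data.index.tolist()

    @property
    def time(self) -> pd.Series:
        return self.data["time"]

    @property
    def event(self) -> pd.Series:
        return self.data["event"]


def read_clinical(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    time_unit: str = "months",
) -> ClinicalTable:
    """Read a clinical TSV/CSV.

    ``column_map`` maps canonical field names (sample_id, time, event, stage,
    t_cat, n_cat, m_cat, age, sex, radiotherapy) to the file's column names;
    unmapped optional fields are filled with 'unknown'.  Time units are
    declared, never inferred.
    """
    cmap = dict(_CLINICAL_DEFAULT_MAP)
    if column_map:
        cmap.update(column_map)
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep, comment="#")
    for canon in ("sample_id", "time", "event"):
        if cmap[canon] not in df.columns:
            raise SchemaError(f"{path}: missing mandatory clinical column {cmap[canon]!r}")
    out = pd.DataFrame({"sample_id": df[cmap["sample_id"]].astype(str)})
    out["time"] = pd.to_numeric(df[cmap["time"]], errors="coerce")
    out["event"] = pd.to_numeric(df[cmap["event"]], errors="coerce")
    for canon in ("stage", "t_cat", "n_cat", "m_cat", "sex", "radiotherapy"):
        col = cmap[canon]
        out[canon] = df[col].astype(str) if col in df.columns else "unknown"
    out["age"] = pd.to_numeric(df[cmap["age"]], errors="coerce") if cmap["age"] in df.columns else np.nan
    keep = out["time"].notna() & out["event"].notna() & (out["time"] > 0) & out["event"].isin((0, 1))
    n_excluded = int((~keep).sum())
    if n_excluded:
        logger.info("read_clinical: dropped %d rows without usable survival information", n_excluded)
    out = out[keep].set_index("sample_id")
    return ClinicalTable(out, time_unit=time_unit, n_excluded=n_excluded)
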