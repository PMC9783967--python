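"""Readers and writers for the external formats the pipeline touches.

All downstream modules operate on the in-memory types defined here:
:class:`MutationRecord` rows parsed from MAF-like tables, :class:`GeneSet`
collections parsed from GMT, and :class:`ClinicalCohort` tables parsed from
TSV/CSV. Parsing is strict — a missing required column or a malformed line is
an error, not a silent drop — because every downstream statistic inherits
whatever slips through here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "VARIANT_CLASSES",
    "TCGA_MAF_DIALECT",
    "RESPONSE_VOCAB",
    "DCB_VOCAB",
    "MSI_VOCAB",
    "FormatError",
    "MutationRecord",
    "GeneSet",
    "ClinicalCohort",
    "read_maf",
    "write_maf",
    "read_gmt",
    "write_gmt",
    "read_clinical",
    "write_table",
]

#: Closed vocabulary of normalized variant classes. "silent" and "other" are
#: excluded from every non-silent computation downstream.
VARIANT_CLASSES = frozenset(
    {
        "missense",
        "nonsense",
        "frameshift_insertion",
        "frameshift_deletion",
        "in_frame_insertion",
        "in_frame_deletion",
        "splice_site",
        "silent",
        "other",
    }
)

#: Default dialect map translating TCGA MAF ``Variant_Classification`` labels
#: to the normalized vocabulary. Editable: pass your own map to
#: :func:`read_maf` for panels with a different vocabulary. Labels absent
#: from the map normalize to "other".
TCGA_MAF_DIALECT: dict[str, str] = {
    "Missense_Mutation": "missense",
    "Nonsense_Mutation": "nonsense",
    "Nonstop_Mutation": "nonsense",
    "Frame_Shift_Ins": "frameshift_insertion",
    "Frame_Shift_Del": "frameshift_deletion",
    "In_Frame_Ins": "in_frame_insertion",
    "In_Frame_Del": "in_frame_deletion",
    "Splice_Site": "splice_site",
    "Splice_Region": "splice_site",
    "Silent": "silent",
}

#: Non-silent classes: everything except silent/other counts toward the
#: mutation matrix and TMB.
NONSILENT_CLASSES = frozenset(VARIANT_CLASSES - {"silent", "other"})

RESPONSE_VOCAB = frozenset({"CR", "PR", "SD", "PD", "NA"})
DCB_VOCAB = frozenset({"DCB", "NDB", "NA"})
MSI_VOCAB = frozenset({"MSI-H", "MSS", "NA"})


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass(frozen=True)
class MutationRecord:
    """One somatic mutation call: sample, gene symbol, normalized class."""

    sample_id: str
    gene: str
    variant_class: str

    def __post_init__(self) -> None:
        if not self.sample_id:
            raise ValueError("sample_id must be non-empty")
        if not self.gene:
            raise ValueError("gene must be non-empty")
        if self.variant_class not in VARIANT_CLASSES:
            raise ValueError(
                f"variant_class {self.variant_class!r} not in {sorted(VARIANT_CLASSES)}"
            )

    @property
    def is_nonsilent(self) -> bool:
        return self.variant_class in NONSILENT_CLASSES


@dataclass(frozen=True)
class GeneSet:
    """A named gene set (e.g. one KEGG signaling pathway)."""

    name: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("gene set name must be non-empty")
        if not self.genes:
            raise ValueError(f"gene set {self.name!r} is empty")


# Columns of the normalized clinical table. ``time`` is in months throughout
# the package; ``event`` is 1 = death/progression, 0 = censored.
_CLINICAL_CORE = ["id", "time", "event", "age", "sex", "cancer_type"]
_CLINICAL_OPTIONAL = ["response", "dcb", "tmb", "nal", "pdl1", "msi"]


@dataclass
class ClinicalCohort:
    """Per-patient clinical table with closed-vocabulary categorical columns.

    ``data`` is indexed by patient id and carries the core columns
    (time, event, age, sex, cancer_type) plus any of the optional biomarker
    columns (response, dcb, tmb, nal, pdl1, msi).
    """

    data: pd.DataFrame
    name: str = "cohort"

    def __post_init__(self) -> None:
        df = self.data
        if df.index.has_duplicates:
            dupes = df.index[df.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate patient ids: {dupes}")
        for col in ("time", "event"):
            if col not in df.columns:
                raise FormatError(f"clinical table missing column {col!r}")
        if (df["time"] < 0).any():
            raise FormatError("negative survival time")
        if not df["event"].isin([0, 1]).all():
            raise FormatError("event must be 0/1")
        for col, vocab in (("response", RESPONSE_VOCAB), ("dcb", DCB_VOCAB), ("msi", MSI_VOCAB)):
            if col in df.columns and not df[col].isin(vocab).all():
                bad = sorted(set(df[col]) - vocab)
                raise FormatError(f"{col} values outside vocabulary: {bad}")

    @property
    def ids(self) -> list[str]:
        return list(self.data.index)

    def __len__(self) -> int:
        return len(self.data)

    def subset(self, ids: Sequence[str]) -> "ClinicalCohort":
        return ClinicalCohort(self.data.loc[list(ids)].copy(), name=self.name)


# ---------------------------------------------------------------------------
# MAF-like mutation tables


def _resolve_column(columns: Sequence[str], candidates: Sequence[str], what: str) -> str:
    lower = {c.lower(): c for c in columns}
    for cand in candidates:
        if cand.lower() in lower:
            return lower[cand.lower()]
    raise FormatError(f"no column for {what}; looked for any of {list(candidates)}")


_SAMPLE_COLS = ("Tumor_Sample_Barcode", "sample", "sample_id", "patient_id")
_GENE_COLS = ("Hugo_Symbol", "gene", "gene_symbol")
_CLASS_COLS = ("Variant_Classification", "variant_class", "variant_classification")


def read_maf(
    path: str | Path,
    dialect_map: Mapping[str, str] | None = None,
) -> list[MutationRecord]:
    """Read a MAF-like tab-separated mutation table.

    ``dialect_map`` translates source variant-classification labels to the
    normalized vocabulary (defaults to the TCGA MAF table). Labels absent
    from the map map to "other". Row order is preserved.
    """
    dialect = dict(TCGA_MAF_DIALECT if dialect_map is None else dialect_map)
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    if df.empty:
        if len(df.columns) == 0:
            warnings.warn(f"{path}: empty mutation file", stacklevel=2)
            return []
        # header-only file still validates its columns below
    sample_col = _resolve_column(df.columns, _SAMPLE_COLS, "sample id")
    gene_col = _resolve_column(df.columns, _GENE_COLS, "gene symbol")
    class_col = _resolve_column(df.columns, _CLASS_COLS, "variant classification")
    if df.empty:
        warnings.warn(f"{path}: empty mutation file", stacklevel=2)
        return []
    records = []
    for sample, gene, vclass in zip(df[sample_col], df[gene_col], df[class_col]):
        norm = dialect.get(str(vclass).strip())
        if norm is None:
            norm = str(vclass).strip().lower()
            if norm not in VARIANT_CLASSES:
                norm = "other"
        records.append(
            MutationRecord(str(sample).strip(), str(gene).strip(), norm)
        )
    return records


def write_maf(records: Iterable[MutationRecord], path: str | Path) -> None:
    """Write records as a minimal MAF-like TSV using normalized class labels.

    ``read_maf`` on the output is the identity on
    (sample, gene, normalized class).
    """
    df = pd.DataFrame(
        [(r.sample_id, r.gene, r.variant_class) for r in records],
        columns=["sample_id", "gene", "variant_class"],
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# GMT gene sets


def read_gmt(path: str | Path) -> list[GeneSet]:
    """Read gene sets from standard GMT (name TAB description TAB genes...).

    The description field is discarded; duplicate genes within a line are
    deduplicated; duplicate set names and empty sets are format errors.
    """
    sets: list[GeneSet] = []
    seen: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line has <3 fields")
            name = fields[0].strip()
            if name in seen:
                raise FormatError(f"{path}:{lineno}: duplicate gene set name {name!r}")
            seen.add(name)
            genes = frozenset(g.strip() for g in fields[2:] if g.strip())
            if not genes:
                raise FormatError(f"{path}:{lineno}: gene set {name!r} is empty")
            sets.append(GeneSet(name, genes))
    return sets


def write_gmt(sets: Iterable[GeneSet], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for s in sets:
            fh.write("\t".join([s.name, "na", *sorted(s.genes)]) + "\n")


# ---------------------------------------------------------------------------
# Clinical tables


def _normalize_vocab(series: pd.Series, vocab: frozenset[str], col: str) -> pd.Series:
    canon = {v.upper(): v for v in vocab}
    out = []
    for raw in series:
        if pd.isna(raw) or str(raw).strip() == "":
            out.append("NA")
            continue
        key = str(raw).strip().upper()
        if key in canon:
            out.append(canon[key])
        else:
            warnings.warn(f"unknown {col} value {raw!r} -> NA", stacklevel=3)
            out.append("NA")
    return pd.Series(out, index=series.index)


def read_clinical(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    name: str = "cohort",
) -> ClinicalCohort:
    """Read a clinical TSV/CSV into a :class:`ClinicalCohort`.

    ``column_map`` maps normalized column names (id, time, event, age, sex,
    cancer_type, response, dcb, tmb, nal, pdl1, msi) to source column names;
    identity is assumed for unmapped names present in the file.
    """
    sep = "," if str(path).endswith(".csv") else "\t"
    raw = pd.read_csv(path, sep=sep)
    cmap = dict(column_map or {})
    df = pd.DataFrame()
    for norm in _CLINICAL_CORE + _CLINICAL_OPTIONAL:
        src = cmap.get(norm, norm)
        if src in raw.columns:
            df[norm] = raw[src]
        elif norm in ("id", "time", "event"):
            raise FormatError(f"clinical table missing required column {src!r}")
    df["id"] = df["id"].astype(str)
    df = df.set_index("id")
    df["time"] = pd.to_numeric(df["time"], errors="raise").astype(float)
    df["event"] = pd.to_numeric(df["event"], errors="raise").astype(int)
    for col, vocab in (("response", RESPONSE_VOCAB), ("dcb", DCB_VOCAB), ("msi", MSI_VOCAB)):
        if col in df.columns:
            df[col] = _normalize_vocab(df[col], vocab, col)
    for col in ("tmb", "nal", "pdl1", "age"):
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="coerce")
    if "sex" in df.columns:
        df["sex"] = df["sex"].astype(str)
    if "cancer_type" in df.columns:
        df["cancer_type"] = df["cancer_type"].astype(str)
    return ClinicalCohort(df, name=name)


def write_table(obj, path: str | Path) -> None:
    """Write a ClinicalCohort or DataFrame as TSV (lossless round-trip)."""
    if isinstance(obj, ClinicalCohort):
        obj.data.to_csv(path, sep="\t", index=True, index_label="id")
    elif isinstance(obj, pd.DataFrame):
        obj.to_csv(path, sep="\t")
    else:
        raise TypeError(f"cannot write {type(obj).__name__}")
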