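"""Binary mutation matrix, TMB, pathway mapping and comutation calls.

The analysis starts from somatic mutation calls and reduces them to a
genes × samples 0/1 matrix of non-silent mutation (a gene is "mutated in a
sample" if it carries at least one non-silent call there). Genes mutated in
more than ``min_gene_freq`` of samples are retained; gene sets are then
collapsed to a pathways × samples 0/1 matrix by an OR over each set's
retained genes, and pathways mutated in at least ``min_pathway_freq`` of
samples are kept. A sample is "comut+" for a designated pathway pair when
both pathways of the pair are mutated in it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io_formats import GeneSet, MutationRecord

__all__ = [
    "BinaryMutationMatrix",
    "PathwayMutationProfile",
    "TmbTable",
    "build_binary_matrix",
    "compute_tmb",
    "map_to_pathways",
    "comutation_status",
    "waterfall_export",
]

#: Default coding-exome size (Mb) used as the TMB denominator.
DEFAULT_CODING_MB = 38.0


@dataclass
class BinaryMutationMatrix:
    """Genes × samples 0/1 indicator of non-silent mutation.

    ``values`` is a DataFrame with gene rows and sample columns, both in
    lexicographic order. ``gene_freq`` is the fraction of samples mutated
    per retained gene.
    """

    values: pd.DataFrame
    gene_freq: pd.Series

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def write(self, path: str | Path) -> None:
        self.values.to_csv(path, sep="\t", index_label="gene")


@dataclass
class PathwayMutationProfile:
    """Pathways × samples 0/1 mutation status with comutation annotations.

    ``comut_count`` (per-sample count of mutated pathways within a selected
    subset) and ``comut_label`` (both pathways of a designated pair mutated)
    are filled in by :func:`comutation_status`.
    """

    status: pd.DataFrame
    pathway_freq: pd.Series
    selected_pathways: list[str] = field(default_factory=list)
    pair: tuple[str, str] | None = None
    comut_count: pd.Series | None = None
    comut_label: pd.Series | None = None

    @property
    def pathways(self) -> list[str]:
        return list(self.status.index)

    @property
    def samples(self) -> list[str]:
        return list(self.status.columns)

    def write(self, path: str | Path) -> None:
        self.status.to_csv(path, sep="\t", index_label="pathway")


@dataclass
class TmbTable:
    """Per-sample tumour mutational burden (mutations/Mb) and optional NAL."""

    tmb: pd.Series
    nal: pd.Series | None = None
    coding_mb: float = DEFAULT_CODING_MB

    @property
    def samples(self) -> list[str]:
        return list(self.tmb.index)


def _nonsilent(records: Iterable[MutationRecord]) -> list[MutationRecord]:
    return [r for r in records if r.is_nonsilent]


def build_binary_matrix(
    records: Iterable[MutationRecord],
    samples: Sequence[str],
    min_gene_freq: float = 0.01,
) -> BinaryMutationMatrix:
    """Build the non-silent gene binary mutation matrix.

    Silent/other calls are excluded; multiple hits of a gene in one sample
    collapse to a single 1. Genes whose mutated-sample fraction is
    <= ``min_gene_freq`` are dropped (strict "greater than" filter). Samples
    with no mutations appear as all-zero columns.
    """
    samples = sorted(dict.fromkeys(samples))
    sample_index = {s: i for i, s in enumerate(samples)}
    hits: dict[str, set[int]] = {}
    for rec in _nonsilent(records):
        if rec.sample_id not in sample_index:
            raise ValueError(f"record references unknown sample {rec.sample_id!r}")
        hits.setdefault(rec.gene, set()).add(sample_index[rec.sample_id])
    n = len(samples)
    genes = sorted(g for g, s in hits.items() if len(s) / n > min_gene_freq)
    if not genes:
        warnings.warn("no gene passes the frequency filter; matrix is empty", stacklevel=2)
    mat = np.zeros((len(genes), n), dtype=np.int8)
    for i, g in enumerate(genes):
        mat[i, sorted(hits[g])] = 1
    values = pd.DataFrame(mat, index=genes, columns=samples)
    gene_freq = pd.Series(mat.sum(axis=1) / n if n else [], index=genes, dtype=float)
    return BinaryMutationMatrix(values=values, gene_freq=gene_freq)


def compute_tmb(
    records: Iterable[MutationRecord],
    samples: Sequence[str],
    coding_mb: float = DEFAULT_CODING_MB,
) -> TmbTable:
    """TMB = non-silent mutation count / coding megabases, per sample.

    Counts every non-silent call (before any gene-frequency filtering);
    samples without records get TMB 0.
    """
    if coding_mb <= 0:
        raise ValueError("coding_mb must be positive")
    samples = sorted(dict.fromkeys(samples))
    counts = dict.fromkeys(samples, 0)
    for rec in _nonsilent(records):
        if rec.sample_id not in counts:
            raise ValueError(f"record references unknown sample {rec.sample_id!r}")
        counts[rec.sample_id] += 1
    tmb = pd.Series({s: counts[s] / coding_mb for s in samples}, dtype=float)
    return TmbTable(tmb=tmb, coding_mb=coding_mb)


def map_to_pathways(
    matrix: BinaryMutationMatrix,
    sets: Sequence[GeneSet],
    min_pathway_freq: float = 0.01,
) -> PathwayMutationProfile:
    """Collapse the gene matrix to pathway mutation status.

    A pathway is mutated in a sample iff at least one of its retained genes
    is (OR over the set). Pathways mutated in < ``min_pathway_freq`` of
    samples are dropped (inclusive "at least" filter).
    """
    n = len(matrix.samples)
    rows = {}
    for s in sorted(sets, key=lambda g: g.name):
        present = [g for g in s.genes if g in matrix.values.index]
        if present:
            status = (matrix.values.loc[present].sum(axis=0) > 0).astype(np.int8)
        else:
            status = pd.Series(np.zeros(n, dtype=np.int8), index=matrix.samples)
        if n and status.sum() / n >= min_pathway_freq:
            rows[s.name] = status
    if not rows:
        warnings.warn("no pathway passes the frequency filter; profile is empty", stacklevel=2)
        status_df = pd.DataFrame(
            np.zeros((0, n), dtype=np.int8), columns=matrix.samples
        )
    else:
        status_df = pd.DataFrame(rows).T.astype(np.int8)
        status_df = status_df.sort_index()
    freq = status_df.sum(axis=1) / n if n else pd.Series(dtype=float)
    return PathwayMutationProfile(status=status_df, pathway_freq=freq)


def comutation_status(
    profile: PathwayMutationProfile,
    selected_pathways: Sequence[str],
    pair: tuple[str, str],
) -> PathwayMutationProfile:
    """Annotate per-sample comutation count and the pair comut+/− label.

    ``comut_count`` counts mutated pathways among ``selected_pathways``;
    ``comut_label`` is True iff both pathways of ``pair`` are mutated
    (the comut+ definition).
    """
    available = set(profile.pathways)
    missing = [p for p in [*selected_pathways, *pair] if p not in available]
    if missing:
        raise KeyError(
            f"unknown pathway(s) {missing}; available: {sorted(available)}"
        )
    if not set(pair) <= set(selected_pathways):
        raise ValueError("pair must be contained in selected_pathways")
    sel = list(dict.fromkeys(selected_pathways))
    count = profile.status.loc[sel].sum(axis=0).astype(int)
    label = (profile.status.loc[pair[0]] == 1) & (profile.status.loc[pair[1]] == 1)
    return PathwayMutationProfile(
        status=profile.status,
        pathway_freq=profile.pathway_freq,
        selected_pathways=sel,
        pair=(pair[0], pair[1]),
        comut_count=count,
        comut_label=label,
    )


def waterfall_export(
    profile: PathwayMutationProfile,
    matrix: BinaryMutationMatrix,
    sets: Sequence[GeneSet],
    tmb: TmbTable | None = None,
    clinical: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-sample table backing a waterfall plot of the designated pair.

    Columns: comut label, comut count, TMB/NAL if supplied, MSI if present in
    the clinical table, and the mutated-gene list per pair pathway.
    """
    if profile.pair is None or profile.comut_label is None:
        raise ValueError("profile has no designated pair; run comutation_status first")
    out = pd.DataFrame(index=profile.samples)
    out["comut_label"] = profile.comut_label.reindex(out.index)
    out["comut_count"] = profile.comut_count.reindex(out.index)
    if tmb is not None:
        out["tmb"] = tmb.tmb.reindex(out.index)
        if tmb.nal is not None:
            out["nal"] = tmb.nal.reindex(out.index)
    if clinical is not None and "msi" in clinical.columns:
        out["msi"] = clinical["msi"].reindex(out.index)
    by_name = {s.name: s for s in sets}
    for pw in profile.pair:
        genes = [g for g in sorted(by_name[pw].genes) if g in matrix.values.index]
        sub = matrix.values.loc[genes]
        out[f"{pw}_mutated_genes"] = [
            ",".join(sub.index[sub[s] == 1]) for s in out.index
        ]
    return out
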