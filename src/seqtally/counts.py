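"""Gene and isoform count matrices from best-stratum alignments.

A unique read is *unambiguous and usable* when all of its best-stratum
alignments fall within annotated features of exactly one gene locus; reads
touching two loci are ambiguous and excluded, reads landing outside any
annotated feature are intergenic and excluded. An unambiguous read with
occurrence ``o`` in a replicate adds ``o`` to its gene and ``o/m`` to each of
the ``m`` isoforms it maps to; isoform counts stay exact rationals until
export. A read with several best hits inside one gene still counts once per
occurrence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
import pandas as pd

from .aligner import AlignmentHit
from .readstore import ExperimentDesign, ReadStore
from .refdb import FeatureCatalog


@dataclass
class CountMatrix:
    """Genes x replicates counts with the treatment design attached.

    ``library_sizes`` are the column sums of the unfiltered matrix (the
    usable-read totals); they are preserved by :func:`expression_filter` so
    downstream normalization sees the original sequencing depths.
    """

    counts: pd.DataFrame  # index: gene_id, columns: replicate_id
    treatments: dict[str, str]  # replicate_id -> treatment label
    library_sizes: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.counts.index.name = "gene_id"
        if (self.counts.values < 0).any():
            raise ValueError("counts must be non-negative")
        if set(self.counts.columns) - set(self.treatments):
            raise ValueError("every replicate needs a treatment label")
        if not self.library_sizes:
            self.library_sizes = {
                r: float(self.counts[r].sum()) for r in self.counts.columns
            }

    @property
    def genes(self) -> list[str]:
        return list(self.counts.index)

    @property
    def replicates(self) -> list[str]:
        return list(self.counts.columns)

    def replicates_of(self, treatment: str) -> list[str]:
        return [r for r in self.replicates if self.treatments[r] == treatment]

    def treatment_labels(self) -> list[str]:
        seen: list[str] = []
        for r in self.replicates:
            if self.treatments[r] not in seen:
                seen.append(self.treatments[r])
        return seen

    # -- TSV dialect: header column "replicate:treatment" --------------------

    def to_tsv(self, path) -> None:
        df = self.counts.copy()
        df.columns = [f"{r}:{self.treatments[r]}" for r in df.columns]
        df.index.name = "gene_id"
        df.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path) -> "CountMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        df.index.name = "gene_id"
        treatments = {}
        cols = []
        for c in df.columns:
            rid, _, trt = c.partition(":")
            treatments[rid] = trt
            cols.append(rid)
        df.columns = cols
        return cls(counts=df, treatments=treatments)


@dataclass(frozen=True)
class Classification:
    status: str  # unambiguous | ambiguous | intergenic | unmapped
    gene_id: str | None = None
    isoform_ids: frozenset[str] = frozenset()


def classify_read(
    hits: list[AlignmentHit], catalog: FeatureCatalog, read_length: int
) -> Classification:
    """Classify one read's best-stratum hits against the feature catalog.

    A genome hit is attributed to every gene with an annotated feature
    overlapping the aligned window; a hit on a junction sequence is
    attributed to the junction's gene. The read is unambiguous iff the union
    of attributed genes over all hits has size one.
    """
    if not hits:
        return Classification("unmapped")
    trees = catalog.overlap_tree()
    genes: set[str] = set()
    isoforms: set[str] = set()
    for h in hits:
        if h.seq_id in catalog.junctions or h.target_kind == "junction":
            j = catalog.junctions[h.seq_id]
            genes.add(j.gene_id)
            isoforms |= j.isoform_ids
            continue
        tree = trees.get(h.seq_id)
        if tree is None:
            continue
        for node in tree.overlap(h.pos, h.pos + read_length):
            iv = node.data
            genes.add(iv.gene_id)
            isoforms |= set(iv.isoform_ids)
    if not genes:
        return Classification("intergenic")
    if len(genes) > 1:
        return Classification("ambiguous")
    gene = genes.pop()
    isoforms = {
        i for i in isoforms
        if i in catalog.genes[gene].isoforms
    }
    return Classification("unambiguous", gene_id=gene, isoform_ids=frozenset(isoforms))


def accumulate_counts(
    classifications: dict[int, Classification],
    store: ReadStore,
    design: ExperimentDesign,
    catalog: FeatureCatalog,
) -> tuple[CountMatrix, pd.DataFrame]:
    """Turn per-read classifications and occurrences into count matrices.

    Returns the integral gene-level :class:`CountMatrix` (genes x replicates,
    every annotated gene present, zero rows kept) and the isoform-level
    DataFrame of :class:`fractions.Fraction` counts (``o/m`` per isoform).
    """
    reps = [r.replicate_id for r in design.replicates]
    gene_ids = sorted(catalog.genes)
    gidx = {g: i for i, g in enumerate(gene_ids)}
    gene_counts = np.zeros((len(gene_ids), len(reps)), dtype=np.int64)
    iso_rows: dict[str, dict[str, Fraction]] = {}
    for rid, cls in classifications.items():
        if cls.status != "unambiguous":
            continue
        occ = store.reads[rid].occurrences
        gi = gidx[cls.gene_id]
        m = len(cls.isoform_ids)
        for j, rep in enumerate(reps):
            o = occ.get(rep, 0)
            if not o:
                continue
            gene_counts[gi, j] += o
            if m:
                for iso in cls.isoform_ids:
                    row = iso_rows.setdefault(iso, {})
                    row[rep] = row.get(rep, Fraction(0)) + Fraction(o, m)
    gene_df = pd.DataFrame(gene_counts, index=gene_ids, columns=reps)
    iso_df = pd.DataFrame(
        {
            iso: {rep: iso_rows[iso].get(rep, Fraction(0)) for rep in reps}
            for iso in sorted(iso_rows)
        }
    ).T
    if not iso_df.empty:
        iso_df = iso_df[reps]
    matrix = CountMatrix(
        counts=gene_df,
        treatments={r.replicate_id: r.treatment for r in design.replicates},
    )
    return matrix, iso_df


def expression_filter(matrix: CountMatrix, design: ExperimentDesign | None = None) -> CountMatrix:
    """Keep genes with counts in *all* replicates of at least one treatment.

    Library sizes are carried over unchanged from the input matrix.
    """
    treatments = matrix.treatment_labels()
    keep = np.zeros(len(matrix.genes), dtype=bool)
    for trt in treatments:
        reps = matrix.replicates_of(trt)
        keep |= (matrix.counts[reps].values > 0).all(axis=1)
    return CountMatrix(
        counts=matrix.counts.loc[keep].copy(),
        treatments=dict(matrix.treatments),
        library_sizes=dict(matrix.library_sizes),
    )
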