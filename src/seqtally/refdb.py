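"""Reference feature catalog: FASTA + GFF3 ingestion and splice-junction synthesis.

The catalog is the single queryable description of the reference used by the
aligner and the counting rules: residue sequences, gene loci with their
classifications, transcript isoforms, typed feature intervals (exons, UTRs,
CDS, retained introns), and synthetic splice-junction sequences built from
adjacent exon pairs so that junction-crossing reads can be aligned without a
spliced aligner.

Coordinates are 0-based half-open internally; GFF3 I/O converts from/to the
1-based inclusive convention on disk.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq
from intervaltree import IntervalTree

#: GFF3 feature types treated as countable gene features.
FEATURE_TYPES = {
    "exon",
    "five_prime_UTR",
    "three_prime_UTR",
    "CDS",
    "retained_intron",
}

#: GFF3 types treated as gene loci (open set; unknown gene-like parents kept).
GENE_TYPES = {"gene", "pseudogene", "transposable_element_gene"}


@dataclass(frozen=True)
class FeatureInterval:
    """One typed feature interval of a gene locus.

    ``start``/``end`` are 0-based half-open genome coordinates. An interval
    shared by several isoforms of the gene carries all of their ids.
    """

    seq_id: str
    start: int
    end: int
    strand: str
    ftype: str
    gene_id: str
    isoform_ids: frozenset[str]

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"bad interval [{self.start}, {self.end})")
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")


@dataclass(frozen=True)
class Junction:
    """A synthetic splice-junction sequence for one adjacent exon pair.

    The sequence is the last ``flank`` nt of the transcriptionally upstream
    exon joined to the first ``flank`` nt of the downstream exon, in
    transcript orientation (reverse-complemented for minus-strand isoforms).
    ``donor``/``acceptor`` are genome coordinates of the joined exon edges.
    """

    junction_id: str
    gene_id: str
    sequence: str
    seq_id: str
    donor: int
    acceptor: int
    strand: str
    isoform_ids: frozenset[str]
    short: bool = False  # an exon shorter than the flank truncated this side


@dataclass
class GeneModel:
    gene_id: str
    seq_id: str
    start: int
    end: int
    strand: str
    gene_class: str
    isoforms: dict[str, str] = field(default_factory=dict)  # id -> type


@dataclass
class Reject:
    """A GFF3 record that could not be placed in the catalog."""

    line_number: int
    reason: str
    line: str


class FeatureCatalog:
    """Sequences, gene models, typed intervals and junction sequences."""

    def __init__(self) -> None:
        self.sequences: dict[str, str] = {}
        self.genes: dict[str, GeneModel] = {}
        self.intervals: list[FeatureInterval] = []
        self.junctions: dict[str, Junction] = {}
        self.rejects: list[Reject] = []
        self._trees: dict[str, IntervalTree] | None = None

    # -- queries -------------------------------------------------------------

    def intervals_of_gene(self, gene_id: str) -> list[FeatureInterval]:
        return [iv for iv in self.intervals if iv.gene_id == gene_id]

    def exons_of_isoform(self, isoform_id: str) -> list[FeatureInterval]:
        """Exon intervals of one isoform in genome coordinate order."""
        exs = [
            iv
            for iv in self.intervals
            if iv.ftype == "exon" and isoform_id in iv.isoform_ids
        ]
        return sorted(exs, key=lambda iv: iv.start)

    def overlap_tree(self) -> dict[str, IntervalTree]:
        """Per-sequence interval trees over all feature intervals (cached)."""
        if self._trees is None:
            trees: dict[str, IntervalTree] = {}
            for iv in self.intervals:
                trees.setdefault(iv.seq_id, IntervalTree()).addi(
                    iv.start, iv.end, iv
                )
            self._trees = trees
        return self._trees

    def invalidate_cache(self) -> None:
        self._trees = None

    # -- GFF3 round trip -----------------------------------------------------

    def to_gff3(self) -> str:
        """Serialize gene models and intervals as deterministic GFF3."""
        out = ["##gff-version 3"]
        for gid in sorted(self.genes):
            g = self.genes[gid]
            out.append(
                f"{g.seq_id}\tseqtally\t{g.gene_class}\t{g.start + 1}\t{g.end}\t."
                f"\t{g.strand}\t.\tID={gid}"
            )
            for iso in sorted(g.isoforms):
                ivs = [iv for iv in self.intervals if iso in iv.isoform_ids]
                lo = min(iv.start for iv in ivs)
                hi = max(iv.end for iv in ivs)
                out.append(
                    f"{g.seq_id}\tseqtally\t{g.isoforms[iso]}\t{lo + 1}\t{hi}\t."
                    f"\t{g.strand}\t.\tID={iso};Parent={gid}"
                )
            seen: set[tuple] = set()
            for iv in sorted(
                self.intervals, key=lambda iv: (iv.start, iv.end, iv.ftype)
            ):
                if iv.gene_id != gid:
                    continue
                key = (iv.start, iv.end, iv.ftype)
                if key in seen:
                    continue
                seen.add(key)
                parents = ",".join(sorted(iv.isoform_ids))
                out.append(
                    f"{iv.seq_id}\tseqtally\t{iv.ftype}\t{iv.start + 1}\t{iv.end}"
                    f"\t.\t{iv.strand}\t.\tParent={parents}"
                )
        return "\n".join(out) + "\n"


def _read_fasta(source) -> dict[str, str]:
    if hasattr(source, "read"):
        handle = source
    else:
        handle = open(source)
    try:
        return {
            rec.id: str(rec.seq).upper() for rec in SeqIO.parse(handle, "fasta")
        }
    finally:
        if handle is not source:
            handle.close()


def _prescan_gff3(text: str) -> tuple[list[str], list[Reject]]:
    """Split GFF3 text into structurally sound lines and record-level rejects."""
    good: list[str] = []
    rejects: list[Reject] = []
    for n, line in enumerate(text.splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            good.append(line)
            continue
        cols = line.split("\t")
        if len(cols) != 9:
            rejects.append(Reject(n, "not 9 tab-separated columns", line))
            continue
        try:
            start, end = int(cols[3]), int(cols[4])
        except ValueError:
            rejects.append(Reject(n, "non-integer coordinates", line))
            continue
        if start < 1 or end < start:
            rejects.append(Reject(n, "invalid coordinate range", line))
            continue
        if cols[6] not in {"+", "-", ".", "?"}:
            rejects.append(Reject(n, "invalid strand", line))
            continue
        good.append(line)
    return good, rejects


def load_reference(fasta_source, gff3_source) -> FeatureCatalog:
    """Ingest reference FASTA + GFF3 annotation into a :class:`FeatureCatalog`.

    Malformed GFF3 lines and features whose ``Parent`` cannot be resolved are
    collected in ``catalog.rejects`` rather than silently dropped. A feature
    placed on a sequence absent from the FASTA is a hard error.
    """
    catalog = FeatureCatalog()
    catalog.sequences = _read_fasta(fasta_source)

    if hasattr(gff3_source, "read"):
        text = gff3_source.read()
    else:
        with open(gff3_source) as fh:
            text = fh.read()
    good_lines, rejects = _prescan_gff3(text)
    catalog.rejects.extend(rejects)

    db = gffutils.create_db(
        "\n".join(good_lines),
        dbfn=":memory:",
        from_string=True,
        merge_strategy="create_unique",
        keep_order=True,
    )

    # Gene loci: top-level records of gene-like type (no Parent attribute).
    iso2gene: dict[str, str] = {}
    for feat in db.all_features():
        if "Parent" in feat.attributes:
            continue
        if feat.featuretype in FEATURE_TYPES:
            continue  # orphan feature record handled below
        if feat.seqid not in catalog.sequences:
            raise ValueError(
                f"GFF3 references sequence {feat.seqid!r} missing from FASTA"
            )
        gid = feat.id
        catalog.genes[gid] = GeneModel(
            gene_id=gid,
            seq_id=feat.seqid,
            start=feat.start - 1,
            end=feat.end,
            strand=feat.strand if feat.strand in "+-" else "+",
            gene_class=feat.featuretype,
        )

    # Transcript isoforms: children of genes that are not leaf feature types.
    for feat in db.all_features():
        parents = feat.attributes.get("Parent", [])
        if not parents or feat.featuretype in FEATURE_TYPES:
            continue
        for pid in parents:
            if pid in catalog.genes:
                catalog.genes[pid].isoforms[feat.id] = feat.featuretype
                iso2gene[feat.id] = pid
            else:
                catalog.rejects.append(
                    Reject(0, f"transcript Parent {pid!r} not a known gene",
                           str(feat))
                )

    # Leaf features: exon/UTR/CDS/retained_intron records linked to isoforms.
    for feat in db.all_features():
        if feat.featuretype not in FEATURE_TYPES:
            continue
        parents = feat.attributes.get("Parent", [])
        if not parents:
            catalog.rejects.append(Reject(0, "feature without Parent", str(feat)))
            continue
        isos = [p for p in parents if p in iso2gene]
        if not isos:
            catalog.rejects.append(
                Reject(0, f"feature Parent(s) {parents} unresolvable", str(feat))
            )
            continue
        genes = {iso2gene[p] for p in isos}
        if len(genes) != 1:
            catalog.rejects.append(
                Reject(0, f"feature spans gene loci {sorted(genes)}", str(feat))
            )
            continue
        gene_id = genes.pop()
        if feat.seqid not in catalog.sequences:
            raise ValueError(
                f"GFF3 references sequence {feat.seqid!r} missing from FASTA"
            )
        if feat.end > len(catalog.sequences[feat.seqid]):
            catalog.rejects.append(
                Reject(0, "feature beyond sequence end", str(feat))
            )
            continue
        catalog.intervals.append(
            FeatureInterval(
                seq_id=feat.seqid,
                start=feat.start - 1,
                end=feat.end,
                strand=feat.strand if feat.strand in "+-" else "+",
                ftype=feat.featuretype,
                gene_id=gene_id,
                isoform_ids=frozenset(isos),
            )
        )

    # Merge duplicate interval records (same span/type/gene) into one carrying
    # the union of isoform ids; forced by shared exons listed once per isoform.
    merged: dict[tuple, set[str]] = {}
    meta: dict[tuple, FeatureInterval] = {}
    for iv in catalog.intervals:
        key = (iv.seq_id, iv.start, iv.end, iv.ftype, iv.gene_id)
        merged.setdefault(key, set()).update(iv.isoform_ids)
        meta[key] = iv
    catalog.intervals = [
        FeatureInterval(
            seq_id=k[0], start=k[1], end=k[2], strand=meta[k].strand,
            ftype=k[3], gene_id=k[4], isoform_ids=frozenset(v),
        )
        for k, v in merged.items()
    ]
    catalog.intervals.sort(key=lambda iv: (iv.seq_id, iv.start, iv.end, iv.ftype))
    catalog.invalidate_cache()
    return catalog


def load_reference_strings(fasta_text: str, gff3_text: str) -> FeatureCatalog:
    """Convenience wrapper accepting in-memory FASTA/GFF3 text."""
    return load_reference(io.StringIO(fasta_text), io.StringIO(gff3_text))


def revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def build_junctions(catalog: FeatureCatalog, flank: int) -> FeatureCatalog:
    """Add splice-junction sequences for every adjacent exon pair in place.

    For each isoform with >= 2 exons, each adjacent pair contributes one
    junction of (up to) ``2*flank`` nt: the last ``flank`` nt of the upstream
    exon followed by the first ``flank`` nt of the downstream exon, oriented
    along the transcript (minus-strand junctions are reverse-complemented).
    An exon shorter than the flank contributes its full length and the
    junction is flagged ``short``. Junctions with identical sequence within
    the same gene are collapsed.
    """
    if flank < 1:
        raise ValueError("flank must be >= 1")
    seen: dict[tuple[str, str], str] = {}  # (gene_id, sequence) -> junction_id
    new: dict[str, Junction] = {}
    n = 0
    for gid in sorted(catalog.genes):
        gene = catalog.genes[gid]
        for iso in sorted(gene.isoforms):
            exons = catalog.exons_of_isoform(iso)
            if len(exons) < 2:
                continue
            for left, right in zip(exons, exons[1:]):
                seq = catalog.sequences[left.seq_id]
                a = seq[max(left.start, left.end - flank): left.end]
                b = seq[right.start: min(right.end, right.start + flank)]
                short = len(a) < flank or len(b) < flank
                genomic = a + b
                if gene.strand == "-":
                    jseq = revcomp(genomic)
                else:
                    jseq = genomic
                key = (gid, jseq)
                if key in seen:
                    jid = seen[key]
                    old = new[jid]
                    new[jid] = Junction(
                        junction_id=jid, gene_id=gid, sequence=jseq,
                        seq_id=left.seq_id, donor=old.donor,
                        acceptor=old.acceptor, strand=gene.strand,
                        isoform_ids=old.isoform_ids | {iso}, short=old.short,
                    )
                    continue
                jid = f"{gid}.jct{n}"
                n += 1
                seen[key] = jid
                new[jid] = Junction(
                    junction_id=jid, gene_id=gid, sequence=jseq,
                    seq_id=left.seq_id, donor=left.end, acceptor=right.start,
                    strand=gene.strand, isoform_ids=frozenset({iso}),
                    short=short,
                )
    catalog.junctions = new
    return catalog
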