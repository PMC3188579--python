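"""Synthetic fixtures with known ground truth.

Generates uniform-random genomes with non-overlapping multi-exon gene
models (a configurable fraction carrying two isoforms that share exons),
valid GFF3, negative-binomially distributed per-gene counts with the
mean-dependent variance Var = mu + phi * mu**alpha, and reads sampled
uniformly along transcripts — crossing splice junctions when the position
spans an exon boundary — with per-base mismatch injection capped at two per
read. Every read's provenance (source gene, isoform, transcript and genome
position, injected mismatches) is recorded so counting and alignment can be
checked by identity.

Per-gene counts are drawn by a Gamma-Poisson mixture and the number of
emitted reads equals the drawn count exactly (no multinomial resampling).

The generator emulates overdispersed bulk RNA-Seq at desk scale. It does
not model sequencing-quality profiles, GC or positional bias, adapter
contamination, or genes sharing sequence (paralogs); ambiguity in the
synthetic data arises only from chance k-mer collisions in the random
genome.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .readstore import ExperimentDesign
from .refdb import revcomp

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class SynthGene:
    gene_id: str
    seq_id: str
    strand: str
    exons: list[tuple[int, int]]               # genome order, 0-based half-open
    isoforms: dict[str, list[int]]             # isoform id -> exon indices


@dataclass
class SynthTruth:
    seed: int
    fasta_text: str
    gff3_text: str
    sequences: dict[str, str]
    genes: dict[str, SynthGene]
    mu: pd.Series | None = None                # per-gene expression mean
    de_genes: dict[str, float] = field(default_factory=dict)  # gene -> fold
    counts: pd.DataFrame | None = None         # drawn gene x replicate counts
    provenance: pd.DataFrame | None = None     # one row per emitted read

    def transcript(self, gene_id: str, isoform_id: str) -> str:
        g = self.genes[gene_id]
        seq = self.sequences[g.seq_id]
        parts = [seq[s:e] for s, e in (g.exons[i] for i in g.isoforms[isoform_id])]
        tx = "".join(parts)
        return revcomp(tx) if g.strand == "-" else tx


def make_genome(
    n_contigs: int = 1,
    length: int = 100_000,
    n_genes: int = 50,
    isoform_rate: float = 0.3,
    seed: int = 0,
    exon_length: tuple[int, int] = (80, 220),
    intron_length: tuple[int, int] = (40, 120),
    gap_length: tuple[int, int] = (120, 300),
    exons_per_gene: tuple[int, int] = (2, 4),
) -> SynthTruth:
    """Random genome + non-overlapping gene models + GFF3, seed-determined.

    Genes are laid left to right with random intergenic gaps; a gene chosen
    for a second isoform (it must have >= 3 exons) skips one internal exon,
    so the isoforms share the flanking exons. Raises if the requested genes
    do not fit the contigs.
    """
    if length < 1000:
        raise ValueError("contig length must be >= 1 kb")
    rng = np.random.default_rng(seed)
    sequences = {
        f"ctg{c + 1}": "".join(
            chr(b) for b in rng.choice(BASES, size=length)
        )
        for c in range(n_contigs)
    }
    genes: dict[str, SynthGene] = {}
    contig_ids = sorted(sequences)
    per_contig = [n_genes // n_contigs] * n_contigs
    for i in range(n_genes % n_contigs):
        per_contig[i] += 1
    gi = 0
    for cid, want in zip(contig_ids, per_contig):
        cursor = int(rng.integers(*gap_length))
        placed = 0
        while placed < want:
            n_ex = int(rng.integers(exons_per_gene[0], exons_per_gene[1] + 1))
            exons = []
            pos = cursor
            for e in range(n_ex):
                ln = int(rng.integers(*exon_length))
                exons.append((pos, pos + ln))
                pos += ln
                if e < n_ex - 1:
                    pos += int(rng.integers(*intron_length))
            if pos > length:
                break
            gi += 1
            gid = f"g{gi:04d}"
            strand = "+" if rng.random() < 0.5 else "-"
            isoforms = {f"{gid}.1": list(range(n_ex))}
            if n_ex >= 3 and rng.random() < isoform_rate:
                skip = int(rng.integers(1, n_ex - 1))
                isoforms[f"{gid}.2"] = [i for i in range(n_ex) if i != skip]
            genes[gid] = SynthGene(gid, cid, strand, exons, isoforms)
            cursor = pos + int(rng.integers(*gap_length))
            placed += 1
        if placed < want:
            raise ValueError(
                f"could not place {want} genes on a {length} nt contig"
            )
    fasta = "".join(
        f">{cid}\n" + "\n".join(
            sequences[cid][i: i + 70] for i in range(0, len(sequences[cid]), 70)
        ) + "\n"
        for cid in contig_ids
    )
    lines = ["##gff-version 3"]
    for gid in sorted(genes):
        g = genes[gid]
        lines.append(
            f"{g.seq_id}\tsynth\tgene\t{g.exons[0][0] + 1}\t{g.exons[-1][1]}\t."
            f"\t{g.strand}\t.\tID={gid}"
        )
        for iso in sorted(g.isoforms):
            idx = g.isoforms[iso]
            lo = g.exons[idx[0]][0]
            hi = g.exons[idx[-1]][1]
            lines.append(
                f"{g.seq_id}\tsynth\tmRNA\t{lo + 1}\t{hi}\t.\t{g.strand}\t."
                f"\tID={iso};Parent={gid}"
            )
            for i in idx:
                s, e = g.exons[i]
                lines.append(
                    f"{g.seq_id}\tsynth\texon\t{s + 1}\t{e}\t.\t{g.strand}\t."
                    f"\tParent={iso}"
                )
    gff3 = "\n".join(lines) + "\n"
    return SynthTruth(
        seed=seed, fasta_text=fasta, gff3_text=gff3,
        sequences=sequences, genes=genes,
    )


def nb_counts(
    mu: np.ndarray, phi: float, alpha: float, rng: np.random.Generator,
    size: tuple | None = None,
) -> np.ndarray:
    """Gamma-Poisson draws with Var = mu + phi * mu**alpha (phi=0 -> Poisson)."""
    mu = np.asarray(mu, dtype=float)
    if size is not None:
        mu = np.broadcast_to(mu, size)
    if phi <= 0:
        return rng.poisson(mu)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(mu > 0, mu ** (2.0 - alpha) / phi, 1.0)
        lam = np.where(mu > 0, rng.gamma(shape=r, scale=mu / r), 0.0)
    return rng.poisson(lam)


def make_counts(
    n_genes: int = 2000,
    n_per_group: tuple[int, int] = (3, 3),
    mu_low: float = 10.0,
    mu_high: float = 1000.0,
    phi: float = 0.1,
    alpha: float = 2.0,
    fold: float = 1.0,
    de_fraction: float = 0.0,
    lib_factors: list[float] | None = None,
    seed: int = 0,
    treatments: tuple[str, str] = ("control", "treated"),
):
    """Count-level fixture: genes x replicates NB counts with planted DE.

    Per-gene means are drawn log-uniform on [mu_low, mu_high] — a realistic
    grid of expression levels. A ``de_fraction`` of genes has its mean
    multiplied by ``fold`` in the second treatment. ``lib_factors`` scale
    every gene's mean per replicate to emulate unequal sequencing depth
    (default: unequal factors drawn in [0.7, 1.3]).

    Returns ``(CountMatrix, de_genes: dict gene -> fold)``.
    """
    from .counts import CountMatrix

    rng = np.random.default_rng(seed)
    na, nb = n_per_group
    reps = [f"{treatments[0]}_{i + 1}" for i in range(na)] + [
        f"{treatments[1]}_{i + 1}" for i in range(nb)
    ]
    trt = {r: treatments[0] if i < na else treatments[1]
           for i, r in enumerate(reps)}
    if lib_factors is None:
        lib_factors = list(np.round(rng.uniform(0.7, 1.3, size=na + nb), 3))
    mu = np.exp(rng.uniform(np.log(mu_low), np.log(mu_high), size=n_genes))
    genes = [f"g{i + 1:04d}" for i in range(n_genes)]
    n_de = int(round(de_fraction * n_genes))
    de_idx = (
        np.sort(rng.choice(n_genes, size=n_de, replace=False))
        if n_de else np.array([], dtype=int)
    )
    # Balanced directions: half induced by `fold`, half repressed by 1/fold.
    # One-sided composition would violate the equal-composition premise of
    # total-count (thinning) normalization and bias every null gene.
    per_gene_fold = np.ones(n_genes)
    half = len(de_idx) // 2
    per_gene_fold[de_idx[:half]] = fold
    per_gene_fold[de_idx[half:]] = 1.0 / fold if fold else 1.0
    de_genes = {genes[i]: float(per_gene_fold[i]) for i in de_idx}
    counts = np.zeros((n_genes, na + nb), dtype=np.int64)
    for j, rep in enumerate(reps):
        m = mu * lib_factors[j]
        if trt[rep] == treatments[1] and n_de:
            m = m * per_gene_fold
        counts[:, j] = nb_counts(m, phi, alpha, rng)
    matrix = CountMatrix(
        counts=pd.DataFrame(counts, index=genes, columns=reps),
        treatments=trt,
    )
    return matrix, de_genes


def make_reads(
    truth: SynthTruth,
    design: ExperimentDesign,
    depth: int = 50_000,
    read_length: int = 25,
    mismatch_rate: float = 0.0,
    fold: float = 1.0,
    de_fraction: float = 0.0,
    phi: float = 0.1,
    alpha: float = 2.0,
    lib_factors: dict[str, float] | None = None,
    seed: int = 0,
) -> dict[str, list[str]]:
    """Emit per-replicate reads for a generated genome; updates ``truth``.

    Per-gene relative expression is lognormal, scaled so the expected read
    total of a unit-factor replicate is ``depth``. Counts per gene x
    replicate are NB with Var = mu + phi * mu**alpha; DE genes (fraction
    ``de_fraction``, chosen here) have their mean multiplied by ``fold`` in
    the second treatment. Reads are drawn uniformly along a uniformly chosen
    isoform, emitted on a random orientation, and mismatches are injected
    per base at ``mismatch_rate`` (capped at 2 per read).

    Returns replicate -> list of read sequences; ``truth.counts``,
    ``truth.mu``, ``truth.de_genes`` and ``truth.provenance`` are filled in.
    """
    rng = np.random.default_rng(seed)
    genes = sorted(truth.genes)
    tx_cache = {
        (gid, iso): truth.transcript(gid, iso)
        for gid in genes
        for iso in truth.genes[gid].isoforms
    }
    for (gid, iso), tx in tx_cache.items():
        if len(tx) < read_length:
            raise ValueError(f"transcript {iso} shorter than the read length")
    w = rng.lognormal(mean=0.0, sigma=1.0, size=len(genes))
    mu = depth * w / w.sum()
    truth.mu = pd.Series(mu, index=genes)
    n_de = int(round(de_fraction * len(genes)))
    de_idx = (
        np.sort(rng.choice(len(genes), size=n_de, replace=False))
        if n_de else np.array([], dtype=int)
    )
    # balanced directions, as in make_counts: keeps library composition
    # comparable between treatments so thinning normalization stays valid
    per_gene_fold = np.ones(len(genes))
    half = len(de_idx) // 2
    per_gene_fold[de_idx[:half]] = fold
    per_gene_fold[de_idx[half:]] = 1.0 / fold if fold else 1.0
    truth.de_genes = {genes[i]: float(per_gene_fold[i]) for i in de_idx}
    treatments = design.treatments
    if lib_factors is None:
        lib_factors = {
            r.replicate_id: float(np.round(rng.uniform(0.7, 1.3), 3))
            for r in design.replicates
        }
    counts = {}
    for rep in design.replicates:
        m = mu * lib_factors[rep.replicate_id]
        if len(treatments) > 1 and rep.treatment == treatments[1] and n_de:
            m = m * per_gene_fold
        counts[rep.replicate_id] = nb_counts(m, phi, alpha, rng)
    truth.counts = pd.DataFrame(counts, index=genes)

    reads: dict[str, list[str]] = {}
    prov_rows = []
    for rep in design.replicates:
        rid = rep.replicate_id
        out: list[str] = []
        for gi, gid in enumerate(genes):
            g = truth.genes[gid]
            isoforms = sorted(g.isoforms)
            c = int(truth.counts.loc[gid, rid])
            for _ in range(c):
                iso = isoforms[int(rng.integers(len(isoforms)))]
                tx = tx_cache[(gid, iso)]
                pos = int(rng.integers(0, len(tx) - read_length + 1))
                seq = tx[pos: pos + read_length]
                n_mm = 0
                if mismatch_rate > 0:
                    flips = np.nonzero(
                        rng.random(read_length) < mismatch_rate
                    )[0][:2]
                    if len(flips):
                        chars = list(seq)
                        for fpos in flips:
                            old = chars[fpos]
                            choices = [b for b in "ACGT" if b != old]
                            chars[fpos] = choices[int(rng.integers(3))]
                        seq = "".join(chars)
                        n_mm = len(flips)
                crosses = _crosses_junction(g, iso, pos, read_length)
                if rng.random() < 0.5:
                    emitted = revcomp(seq)
                    orient = "-"
                else:
                    emitted = seq
                    orient = "+"
                out.append(emitted)
                prov_rows.append(
                    (rid, len(out) - 1, gid, iso, pos, orient, n_mm, crosses)
                )
        reads[rid] = out
    truth.provenance = pd.DataFrame(
        prov_rows,
        columns=[
            "replicate", "read_index", "gene_id", "isoform_id",
            "tx_pos", "orientation", "mismatches", "crosses_junction",
        ],
    )
    return reads


def _crosses_junction(
    g: SynthGene, iso: str, tx_pos: int, read_length: int
) -> bool:
    """Whether a transcript window spans an exon-exon boundary."""
    lens = [g.exons[i][1] - g.exons[i][0] for i in g.isoforms[iso]]
    if g.strand == "-":
        lens = lens[::-1]
    edge = 0
    for ln in lens[:-1]:
        edge += ln
        if tx_pos < edge < tx_pos + read_length:
            return True
    return False


def write_fasta_reads(reads: list[str], path, prefix: str = "r") -> None:
    with open(path, "w") as fh:
        for i, seq in enumerate(reads):
            fh.write(f">{prefix}{i}\n{seq}\n")


def make_go_fixture(
    genes: list[str], seed: int = 0, n_terms: int = 12
):
    """Small three-level ontology + gene annotations for enrichment tests.

    Returns ``(obo_text, annotation_text)``: a root, a layer of broad terms,
    and a layer of specific terms each is_a one broad term; every gene gets
    1-3 specific terms.
    """
    rng = np.random.default_rng(seed)
    broad = [f"GO:10{i:02d}" for i in range(max(2, n_terms // 4))]
    specific = [f"GO:20{i:02d}" for i in range(n_terms)]
    stanzas = ["format-version: 1.2\n", "[Term]\nid: GO:0001\nname: root\n"]
    for t in broad:
        stanzas.append(f"[Term]\nid: {t}\nname: broad {t}\nis_a: GO:0001\n")
    for i, t in enumerate(specific):
        parent = broad[i % len(broad)]
        stanzas.append(f"[Term]\nid: {t}\nname: specific {t}\nis_a: {parent}\n")
    ann_lines = []
    for g in genes:
        k = int(rng.integers(1, 4))
        for t in rng.choice(specific, size=k, replace=False):
            ann_lines.append(f"{g}\t{t}")
    return "\n".join(stanzas), "\n".join(ann_lines) + "\n"
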