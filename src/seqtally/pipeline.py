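"""High-level pipeline steps shared by the CLI and by tests.

Wires the modules together: index the catalog (genome and/or junction
sequences), align every unique read exhaustively, keep best strata,
classify against gene loci, and accumulate count matrices.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from . import aligner, counts, dge, qc
from .readstore import ExperimentDesign, ReadStore
from .refdb import FeatureCatalog


@dataclass
class AlignmentResult:
    hits_by_read: dict[int, list[aligner.AlignmentHit]]
    classifications: dict[int, counts.Classification]


def align_store(
    store: ReadStore,
    catalog: FeatureCatalog,
    max_mismatch: int = 2,
    preamble_length: int = 12,
    target: str = "both",
) -> dict[int, list[aligner.AlignmentHit]]:
    """Align every unique read to the genome and/or junction sequences.

    ``target`` selects the reference: ``genome``, ``transcriptome`` (the
    splice-junction set) or ``both``. Hits from the two targets are pooled
    per read before best-stratum selection.
    """
    if target not in {"genome", "transcriptome", "both"}:
        raise ValueError(f"unknown target {target!r}")
    indexes = []
    if target in ("genome", "both"):
        indexes.append(
            (aligner.build_index(catalog.sequences, preamble_length), "genome")
        )
    if target in ("transcriptome", "both") and catalog.junctions:
        jseqs = {
            jid: j.sequence for jid, j in catalog.junctions.items()
        }
        indexes.append(
            (aligner.build_index(jseqs, preamble_length), "junction")
        )
    hits_by_read: dict[int, list[aligner.AlignmentHit]] = {}
    for read in store.reads:
        all_hits: list[aligner.AlignmentHit] = []
        for index, kind in indexes:
            all_hits.extend(
                aligner.align_read(
                    read.sequence, index, max_mismatch,
                    read_id=read.read_id, target_kind=kind,
                )
            )
        hits_by_read[read.read_id] = all_hits
    return hits_by_read


def classify_all(
    hits_by_read: dict[int, list[aligner.AlignmentHit]],
    store: ReadStore,
    catalog: FeatureCatalog,
) -> dict[int, counts.Classification]:
    out: dict[int, counts.Classification] = {}
    for read in store.reads:
        best = aligner.best_stratum(hits_by_read.get(read.read_id, []))
        out[read.read_id] = counts.classify_read(
            best, catalog, len(read.sequence)
        )
    return out


@dataclass
class PipelineResult:
    store: ReadStore
    hits_by_read: dict
    classifications: dict
    matrix: counts.CountMatrix           # unfiltered gene-level counts
    filtered: counts.CountMatrix
    isoform_counts: pd.DataFrame
    icc: qc.ICCReport
    summary: pd.DataFrame
    dge: dge.DGEResult


def run_pipeline(
    catalog: FeatureCatalog,
    design: ExperimentDesign,
    reads_by_replicate: dict[str, list[str]] | None = None,
    head: int = 0,
    tail: int = 0,
    max_mismatch: int = 2,
    preamble_length: int = 12,
    target: str = "both",
    seed: int = 0,
    fdr: float = 0.05,
) -> PipelineResult:
    """Run reads -> store -> align -> count -> assess -> test in one call."""
    from .readstore import collapse_reads

    store = collapse_reads(
        design, head=head, tail=tail, reads_by_replicate=reads_by_replicate
    )
    hits = align_store(
        store, catalog, max_mismatch=max_mismatch,
        preamble_length=preamble_length, target=target,
    )
    cls = classify_all(hits, store, catalog)
    matrix, iso = counts.accumulate_counts(cls, store, design, catalog)
    filtered = counts.expression_filter(matrix)
    report = qc.icc_report(matrix)
    summary = qc.summaries(store, cls, matrix)
    result = dge.nbp_test(filtered, seed=seed)
    return PipelineResult(
        store=store, hits_by_read=hits, classifications=cls,
        matrix=matrix, filtered=filtered, isoform_counts=iso,
        icc=report, summary=summary, dge=result,
    )
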