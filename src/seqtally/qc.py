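"""Replicate quality assessment: RPQM log counts, ICC, MA coordinates.

The intraclass correlation coefficient quantifies how strongly replicate
libraries of the same treatment agree across genes. Counts are first
normalized to reads per quarter million, incremented by one to handle
zeroes, and natural-log transformed; the ICC is the one-way random-effects,
single-rater coefficient ICC(1) = (MSB - MSW) / (MSB + (k - 1) MSW) with
genes as rows and replicates as raters. No pass/fail threshold is enforced:
the value is reported for the analyst to judge.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .counts import CountMatrix
from .readstore import ReadStore


def rpqm_log(counts, library_size: float) -> np.ndarray:
    """ln(count * 250000 / library_size + 1); the +1 keeps zeros finite."""
    if library_size <= 0:
        raise ValueError("library size must be positive")
    c = np.asarray(counts, dtype=float)
    return np.log(c * 250_000.0 / library_size + 1.0)


def icc(matrix: np.ndarray) -> float:
    """One-way random-effects single-rater ICC of a genes x replicates matrix.

    ICC(1) = (MSB - MSW) / (MSB + (k-1) * MSW) where MSB/MSW are the between-
    and within-row mean squares of the one-way ANOVA over rows (genes) with
    k replicate columns. Zero between-gene variance yields a value <= 0,
    which is returned as computed (callers may flag it).
    """
    x = np.asarray(matrix, dtype=float)
    n, k = x.shape
    if n < 2 or k < 2:
        raise ValueError("ICC needs >= 2 genes and >= 2 replicates")
    row_means = x.mean(axis=1)
    grand = x.mean()
    msb = k * ((row_means - grand) ** 2).sum() / (n - 1)
    msw = ((x - row_means[:, None]) ** 2).sum() / (n * (k - 1))
    denom = msb + (k - 1) * msw
    if denom == 0.0:
        return 0.0
    return float((msb - msw) / denom)


@dataclass
class ICCReport:
    values: dict[str, float]          # treatment -> ICC
    raw_totals: dict[str, float]      # replicate -> raw usable count total
    flagged: list[str]                # treatments with non-positive ICC


def icc_report(matrix: CountMatrix) -> ICCReport:
    """ICC per treatment (>= 2 replicates) on RPQM-log-transformed counts."""
    values: dict[str, float] = {}
    flagged: list[str] = []
    for trt in matrix.treatment_labels():
        reps = matrix.replicates_of(trt)
        if len(reps) < 2:
            continue
        cols = np.column_stack(
            [
                rpqm_log(matrix.counts[r].values, matrix.library_sizes[r])
                for r in reps
            ]
        )
        v = icc(cols)
        values[trt] = v
        if v <= 0:
            flagged.append(trt)
    totals = {r: float(matrix.counts[r].sum()) for r in matrix.replicates}
    return ICCReport(values=values, raw_totals=totals, flagged=flagged)


@dataclass(frozen=True)
class MAPoint:
    gene_id: str
    M: float
    A: float


def ma_points(
    matrix: CountMatrix, treatment_1: str, treatment_2: str
) -> list[MAPoint]:
    """Per-gene MA coordinates from normalized counts.

    M = log2(mean_1 + 1) - log2(mean_2 + 1);
    A = (log2(mean_1 + 1) + log2(mean_2 + 1)) / 2.
    The +1 offset keeps every point finite.
    """
    r1 = matrix.replicates_of(treatment_1)
    r2 = matrix.replicates_of(treatment_2)
    if not r1 or not r2:
        raise ValueError("both treatments need at least one replicate")
    m1 = matrix.counts[r1].mean(axis=1).values
    m2 = matrix.counts[r2].mean(axis=1).values
    l1 = np.log2(m1 + 1.0)
    l2 = np.log2(m2 + 1.0)
    return [
        MAPoint(gene_id=g, M=float(a - b), A=float((a + b) / 2.0))
        for g, a, b in zip(matrix.genes, l1, l2)
    ]


def ma_to_tsv(points: list[MAPoint], path) -> None:
    pd.DataFrame(
        [(p.gene_id, p.M, p.A) for p in points], columns=["gene_id", "M", "A"]
    ).to_csv(path, sep="\t", index=False)


def feature_type_counts(catalog) -> pd.Series:
    """Tally of annotated feature intervals per type (exon, UTR, ...)."""
    counts: dict[str, int] = {}
    for iv in catalog.intervals:
        counts[iv.ftype] = counts.get(iv.ftype, 0) + 1
    counts["splice_junction"] = len(catalog.junctions)
    return pd.Series(counts).sort_index()


def summaries(
    store: ReadStore,
    classifications: dict[int, "object"],
    matrix: CountMatrix | None = None,
) -> pd.DataFrame:
    """Per-replicate processing summary.

    Columns: raw reads, kept after trim/ambiguity filtering, aligned,
    unambiguous-and-usable, and the corresponding percentages of raw.
    Empty replicates report zeros, not absent rows.
    """
    rows = []
    for rep in store.design.replicates:
        rid = rep.replicate_id
        st = store.stats[rid]
        aligned = 0
        usable = 0
        for read in store.reads:
            o = read.occurrences.get(rid, 0)
            if not o:
                continue
            cls = classifications.get(read.read_id)
            if cls is None:
                continue
            if cls.status != "unmapped":
                aligned += o
            if cls.status == "unambiguous":
                usable += o
        rows.append(
            {
                "replicate": rid,
                "treatment": rep.treatment,
                "raw": st.raw,
                "kept": st.kept,
                "dropped": st.dropped,
                "ambiguous_bases": st.ambiguous,
                "aligned": aligned,
                "usable": usable,
                "pct_aligned": 100.0 * aligned / st.raw if st.raw else 0.0,
                "pct_usable": 100.0 * usable / st.raw if st.raw else 0.0,
            }
        )
    return pd.DataFrame(rows).set_index("replicate")
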