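"""Single-file relational store shared by all pipeline stages.

An embedded sqlite database replaces a client-server RDBMS while keeping the
same relational shape: reference sequences and features, unique reads and
occurrences, alignments, gene counts, test results, and a stage journal that
records each run's configuration. Exports are ordered deterministically so a
given store always serializes byte-identically.
"""

from __future__ import annotations

import json
import sqlite3
from pathlib import Path

STAGE_ORDER = [
    "build-ref",
    "load-reads",
    "align",
    "count",
    "assess",
    "dge",
    "go",
]

_SCHEMA = """
CREATE TABLE IF NOT EXISTS stages (
    name TEXT PRIMARY KEY, config TEXT NOT NULL);
CREATE TABLE IF NOT EXISTS sequences (
    seq_id TEXT PRIMARY KEY, length INTEGER NOT NULL, residues TEXT NOT NULL);
CREATE TABLE IF NOT EXISTS genes (
    gene_id TEXT PRIMARY KEY, seq_id TEXT NOT NULL, start INTEGER, end INTEGER,
    strand TEXT, class TEXT);
CREATE TABLE IF NOT EXISTS isoforms (
    isoform_id TEXT PRIMARY KEY, gene_id TEXT NOT NULL REFERENCES genes,
    type TEXT);
CREATE TABLE IF NOT EXISTS intervals (
    seq_id TEXT, start INTEGER, end INTEGER, strand TEXT, ftype TEXT,
    gene_id TEXT REFERENCES genes, isoform_ids TEXT);
CREATE TABLE IF NOT EXISTS junctions (
    junction_id TEXT PRIMARY KEY, gene_id TEXT REFERENCES genes,
    sequence TEXT, seq_id TEXT, donor INTEGER, acceptor INTEGER, strand TEXT,
    isoform_ids TEXT, short INTEGER);
CREATE TABLE IF NOT EXISTS replicates (
    replicate_id TEXT PRIMARY KEY, treatment TEXT NOT NULL, path TEXT);
CREATE TABLE IF NOT EXISTS unique_reads (
    read_id INTEGER PRIMARY KEY, sequence TEXT NOT NULL UNIQUE);
CREATE TABLE IF NOT EXISTS occurrences (
    read_id INTEGER REFERENCES unique_reads,
    replicate_id TEXT REFERENCES replicates, count INTEGER NOT NULL,
    PRIMARY KEY (read_id, replicate_id));
CREATE TABLE IF NOT EXISTS read_stats (
    replicate_id TEXT PRIMARY KEY, raw INTEGER, kept INTEGER,
    dropped INTEGER, ambiguous INTEGER);
CREATE TABLE IF NOT EXISTS alignments (
    read_id INTEGER REFERENCES unique_reads, seq_id TEXT, pos INTEGER,
    strand TEXT, mismatches INTEGER, target_kind TEXT);
CREATE TABLE IF NOT EXISTS classifications (
    read_id INTEGER PRIMARY KEY REFERENCES unique_reads, status TEXT,
    gene_id TEXT, isoform_ids TEXT);
CREATE TABLE IF NOT EXISTS gene_counts (
    gene_id TEXT REFERENCES genes, replicate_id TEXT REFERENCES replicates,
    count INTEGER NOT NULL, PRIMARY KEY (gene_id, replicate_id));
CREATE TABLE IF NOT EXISTS dge_results (
    gene_id TEXT PRIMARY KEY, mean_1 REAL, mean_2 REAL, fold_change REAL,
    p_value REAL, q_value REAL, direction TEXT);
CREATE TABLE IF NOT EXISTS go_results (
    term TEXT, method TEXT, study_hits INTEGER, study_size INTEGER,
    population_hits INTEGER, population_size INTEGER, p_value REAL,
    PRIMARY KEY (term, method));
"""


class PipelineStore:
    """Thin wrapper over the sqlite database used by every stage."""

    def __init__(self, path) -> None:
        self.path = Path(path)
        self.conn = sqlite3.connect(str(self.path))
        self.conn.executescript(_SCHEMA)
        self.conn.commit()

    def close(self) -> None:
        self.conn.close()

    def __enter__(self) -> "PipelineStore":
        return self

    def __exit__(self, *exc) -> None:
        self.close()

    # -- stage journal -------------------------------------------------------

    def mark_stage(self, name: str, config: dict) -> None:
        self.conn.execute(
            "INSERT OR REPLACE INTO stages (name, config) VALUES (?, ?)",
            (name, json.dumps(config, sort_keys=True)),
        )
        self.conn.commit()

    def stage_done(self, name: str) -> bool:
        cur = self.conn.execute("SELECT 1 FROM stages WHERE name = ?", (name,))
        return cur.fetchone() is not None

    def require_stage(self, name: str) -> None:
        if not self.stage_done(name):
            raise RuntimeError(
                f"stage {name!r} has not been run yet; run it first "
                f"(order: {' -> '.join(STAGE_ORDER)})"
            )

    def clear(self, *tables: str) -> None:
        for t in tables:
            self.conn.execute(f"DELETE FROM {t}")
        self.conn.commit()

    # -- referential integrity ----------------------------------------------

    def integrity_violations(self) -> list[str]:
        """Cross-table referential checks; empty list means consistent."""
        probes = {
            "alignments -> unique_reads": (
                "SELECT COUNT(*) FROM alignments a LEFT JOIN unique_reads u "
                "ON a.read_id = u.read_id WHERE u.read_id IS NULL"
            ),
            "gene_counts -> genes": (
                "SELECT COUNT(*) FROM gene_counts c LEFT JOIN genes g "
                "ON c.gene_id = g.gene_id WHERE g.gene_id IS NULL"
            ),
            "occurrences -> unique_reads": (
                "SELECT COUNT(*) FROM occurrences o LEFT JOIN unique_reads u "
                "ON o.read_id = u.read_id WHERE u.read_id IS NULL"
            ),
            "intervals -> genes": (
                "SELECT COUNT(*) FROM intervals i LEFT JOIN genes g "
                "ON i.gene_id = g.gene_id WHERE g.gene_id IS NULL"
            ),
            "genome alignments -> sequences": (
                "SELECT COUNT(*) FROM alignments a LEFT JOIN sequences s "
                "ON a.seq_id = s.seq_id WHERE a.target_kind = 'genome' "
                "AND s.seq_id IS NULL"
            ),
        }
        bad = []
        for label, sql in probes.items():
            if self.conn.execute(sql).fetchone()[0]:
                bad.append(label)
        return bad
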