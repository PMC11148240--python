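"""Portable single-file store and the two query modes.

Candidates, scores, provenance and annotations are persisted in a SQLite
file (replacing a client/server database for desk-scale reproducibility)
and served through two queries:

* ``search`` -- conjunction of filters (gene, epitope substring or exact
  peptide, alleles, MHC class, affinity statistic < cutoff), deterministic
  (gene, peptide, allele) ordering;
* ``best`` -- per-allele ranked lists below an affinity cutoff on a chosen
  statistic (median by default, mirroring the worked median-30 nM query),
  optionally intersected with the top expression fraction of a cohort.
"""

from __future__ import annotations

import json
import logging
import sqlite3
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import annotate as _annotate
from .annotate import CoverageResult, EvidenceRecord, ExpressionMatrix
from .epitope_enum import EpitopeCandidate
from .frameshift_gen import FrameshiftPeptide, FrameshiftVariant

logger = logging.getLogger("msneoforge")

_SCHEMA = """
CREATE TABLE peptides (
    peptide_id TEXT PRIMARY KEY,
    peptide TEXT NOT NULL UNIQUE,
    non_stop INTEGER NOT NULL
);
CREATE TABLE sources (
    peptide_id TEXT NOT NULL REFERENCES peptides(peptide_id),
    gene TEXT NOT NULL,
    transcript_id TEXT NOT NULL,
    locus TEXT NOT NULL,
    frame_class INTEGER NOT NULL,
    variant_key TEXT
);
CREATE TABLE epitopes (
    epitope TEXT NOT NULL,
    allele TEXT NOT NULL,
    mhc_class TEXT NOT NULL,
    best REAL NOT NULL,
    median REAL NOT NULL,
    mean REAL NOT NULL,
    n_algorithms INTEGER NOT NULL,
    gravy REAL NOT NULL,
    n_terminal TEXT NOT NULL,
    c_terminal TEXT NOT NULL,
    PRIMARY KEY (epitope, allele)
);
CREATE TABLE epitope_sources (
    epitope TEXT NOT NULL,
    peptide_id TEXT NOT NULL,
    offset INTEGER NOT NULL
);
CREATE TABLE scores (
    epitope TEXT NOT NULL,
    allele TEXT NOT NULL,
    algorithm TEXT NOT NULL,
    ic50 REAL NOT NULL
);
CREATE TABLE evidence (
    key_type TEXT NOT NULL,
    key TEXT NOT NULL,
    source TEXT NOT NULL,
    payload TEXT NOT NULL
);
CREATE TABLE expression (
    gene TEXT NOT NULL,
    sample TEXT NOT NULL,
    value REAL NOT NULL
);
CREATE TABLE samples (
    sample TEXT PRIMARY KEY,
    cohort TEXT,
    grp TEXT,
    msi_status TEXT
);
CREATE INDEX ix_epitopes_allele ON epitopes(allele);
CREATE INDEX ix_epitope_sources ON epitope_sources(epitope);
CREATE INDEX ix_sources_gene ON sources(gene);
CREATE INDEX ix_evidence_key ON evidence(key_type, key);
"""


@dataclass
class QueryFilter:
    """Filters for ``search``; at least one must be set."""

    genes: list[str] | None = None
    epitope_substring: str | None = None
    peptide_exact: str | None = None
    alleles: list[str] | None = None
    mhc_class: str | None = None
    affinity_statistic: str = "best"
    affinity_cutoff_nM: float | None = None
    limit: int | None = None
    offset: int = 0

    def any_set(self) -> bool:
        return any(
            v is not None
            for v in (self.genes, self.epitope_substring, self.peptide_exact,
                      self.alleles, self.mhc_class, self.affinity_cutoff_nM)
        )


class NeoantigenStore:
    """A built store, opened read-only for queries."""

    def __init__(self, path: str | Path) -> None:
        self.path = Path(path)
        if not self.path.exists():
            raise FileNotFoundError(path)
        self.conn = sqlite3.connect(self.path)
        self.conn.row_factory = sqlite3.Row

    def close(self) -> None:
        self.conn.close()

    def __enter__(self) -> "NeoantigenStore":
        return self

    def __exit__(self, *exc) -> None:
        self.close()

    # -- introspection -------------------------------------------------
    def row_counts(self) -> dict[str, int]:
        tables = ("peptides", "sources", "epitopes", "epitope_sources",
                  "scores", "evidence", "expression", "samples")
        return {
            t: self.conn.execute(f"SELECT COUNT(*) FROM {t}").fetchone()[0]
            for t in tables
        }

    def epitope_strings(self) -> set[str]:
        rows = self.conn.execute("SELECT DISTINCT epitope FROM epitopes")
        return {r[0] for r in rows}

    def peptide_strings(self) -> set[str]:
        rows = self.conn.execute("SELECT peptide FROM peptides")
        return {r[0] for r in rows}

    def expression_matrix(self) -> ExpressionMatrix | None:
        expr = pd.read_sql("SELECT gene, sample, value FROM expression",
                           self.conn)
        if expr.empty:
            return None
        values = expr.pivot(index="gene", columns="sample", values="value")
        md = pd.read_sql("SELECT sample, cohort, grp AS 'group', msi_status "
                         "FROM samples", self.conn).set_index("sample")
        return ExpressionMatrix(values=values, metadata=md)

    # -- queries -------------------------------------------------------
    def search(self, qf: QueryFilter) -> pd.DataFrame:
        """Conjunction of all set filters; (gene, peptide, allele) order."""
        if not qf.any_set():
            raise ValueError("search requires at least one filter "
                             "(unbounded query refused)")
        sql = """
        SELECT s.gene AS gene, e.epitope AS epitope, e.allele AS allele,
               e.mhc_class AS mhc_class, e.best AS best, e.median AS median,
               e.mean AS mean, e.n_algorithms AS n_algorithms,
               e.gravy AS gravy, p.peptide AS source_peptide,
               p.peptide_id AS peptide_id, s.locus AS locus,
               s.frame_class AS frame_class, s.variant_key AS variant_key
        FROM epitopes e
        JOIN epitope_sources es ON es.epitope = e.epitope
        JOIN peptides p ON p.peptide_id = es.peptide_id
        JOIN sources s ON s.peptide_id = p.peptide_id
        """
        clauses, args = [], []
        if qf.genes is not None:
            clauses.append(
                "s.gene IN (%s)" % ",".join("?" * len(qf.genes)))
            args.extend(qf.genes)
        if qf.epitope_substring is not None:
            clauses.append("e.epitope LIKE ?")
            args.append(f"%{qf.epitope_substring}%")
        if qf.peptide_exact is not None:
            clauses.append("e.epitope = ?")
            args.append(qf.peptide_exact)
        if qf.alleles is not None:
            clauses.append(
                "e.allele IN (%s)" % ",".join("?" * len(qf.alleles)))
            args.extend(qf.alleles)
        if qf.mhc_class is not None:
            clauses.append("e.mhc_class = ?")
            args.append(qf.mhc_class)
        if qf.affinity_cutoff_nM is not None:
            stat = {"best": "e.best", "median": "e.median"}[qf.affinity_statistic]
            clauses.append(f"{stat} < ?")
            args.append(qf.affinity_cutoff_nM)
        if clauses:
            sql += " WHERE " + " AND ".join(clauses)
        sql += """
        GROUP BY s.gene, e.epitope, e.allele
        ORDER BY s.gene, e.epitope, e.allele
        """
        if qf.limit is not None:
            sql += f" LIMIT {int(qf.limit)} OFFSET {int(qf.offset)}"
        return pd.read_sql(sql, self.conn, params=args)

    def best(self, alleles: Sequence[str], cutoff_nM: float,
             statistic: str = "median",
             expression_cohort: str | None = None,
             top_fraction: float | None = None) -> dict[str, pd.DataFrame]:
        """Per-allele ranked epitopes below the cutoff on the statistic.

        Unknown alleles yield an empty block with a warning.  When an
        expression filter is requested, only epitopes whose source genes
        rank in the cohort's top expression fraction are kept.
        """
        if not alleles:
            raise ValueError("alleles must be non-empty")
        if statistic not in {"best", "median"}:
            raise ValueError("statistic must be 'best' or 'median'")
        known = {
            r[0] for r in self.conn.execute("SELECT DISTINCT allele FROM epitopes")
        }
        keep_genes: set[str] | None = None
        if top_fraction is not None:
            expr = self.expression_matrix()
            if expr is None:
                raise ValueError("store holds no expression data")
            keep_genes = _annotate.top_expressed_genes(
                expr, expression_cohort, top_fraction)
        out: dict[str, pd.DataFrame] = {}
        for allele in alleles:
            if allele not in known:
                logger.warning("allele %s not in store; empty result", allele)
                out[allele] = pd.DataFrame(
                    columns=["epitope", "allele", "gene", "best", "median",
                             "mean", "gravy"])
                continue
            df = pd.read_sql(
                f"""
                SELECT e.epitope AS epitope, e.allele AS allele,
                       s.gene AS gene, e.best AS best, e.median AS median,
                       e.mean AS mean, e.gravy AS gravy
                FROM epitopes e
                JOIN epitope_sources es ON es.epitope = e.epitope
                JOIN peptides p ON p.peptide_id = es.peptide_id
                JOIN sources s ON s.peptide_id = p.peptide_id
                WHERE e.allele = ? AND e.{statistic} < ?
                GROUP BY e.epitope, s.gene
                ORDER BY e.{statistic} ASC, e.epitope ASC, s.gene ASC
                """,
                self.conn, params=[allele, cutoff_nM],
            )
            if keep_genes is not None:
                df = df[df["gene"].isin(keep_genes)].reset_index(drop=True)
            out[allele] = df
        return out

    def coverage_check(self, peptides: Sequence[str],
                       universe: str = "epitope") -> CoverageResult:
        """Coverage of a validated list: 'epitope', 'peptide' or 'both'."""
        known: set[str] = set()
        if universe in {"epitope", "both"}:
            known |= self.epitope_strings()
        if universe in {"peptide", "both"}:
            known |= self.peptide_strings()
        if universe not in {"epitope", "peptide", "both"}:
            raise ValueError(f"unknown universe {universe!r}")
        return _annotate.coverage_check(known, peptides)


def build_store(
    path: str | Path,
    peptides: Sequence[FrameshiftPeptide] = (),
    candidates: Sequence[EpitopeCandidate] = (),
    scores: Sequence = (),
    evidence: Sequence[EvidenceRecord] = (),
    expression: ExpressionMatrix | None = None,
    variant_keys: dict[tuple[str, str], str] | None = None,
) -> Path:
    """Build the single-file store; deterministic for identical inputs.

    ``variant_keys`` maps (transcript_id, locus key) -> normalized VCF key
    so variant-keyed evidence can be joined to peptide sources.
    """
    path = Path(path)
    if path.exists():
        path.unlink()
    conn = sqlite3.connect(path)
    try:
        conn.executescript(_SCHEMA)
        for p in sorted(peptides, key=lambda p: p.peptide):
            conn.execute(
                "INSERT INTO peptides VALUES (?,?,?)",
                (p.peptide_id, p.peptide, int(p.non_stop)),
            )
            for gene, tid, locus, fc in sorted(p.sources):
                vkey = (variant_keys or {}).get((tid, locus))
                conn.execute(
                    "INSERT INTO sources VALUES (?,?,?,?,?,?)",
                    (p.peptide_id, gene, tid, locus, fc, vkey),
                )
        for c in sorted(candidates, key=lambda c: (c.epitope, c.allele)):
            conn.execute(
                "INSERT INTO epitopes VALUES (?,?,?,?,?,?,?,?,?,?)",
                (c.epitope, c.allele, c.mhc_class, c.best, c.median,
                 c.mean, c.n_algorithms, c.gravy, c.n_terminal, c.c_terminal),
            )
        seen_src = set()
        for c in candidates:
            for pid, off in c.sources:
                if (c.epitope, pid, off) not in seen_src:
                    seen_src.add((c.epitope, pid, off))
                    conn.execute(
                        "INSERT INTO epitope_sources VALUES (?,?,?)",
                        (c.epitope, pid, off),
                    )
        for s in sorted(scores, key=lambda s: (s.epitope, s.allele, s.algorithm)):
            conn.execute("INSERT INTO scores VALUES (?,?,?,?)",
                         (s.epitope, s.allele, s.algorithm, s.ic50))
        for r in sorted(evidence, key=lambda r: (r.key_type, r.key, r.source)):
            conn.execute(
                "INSERT INTO evidence VALUES (?,?,?,?)",
                (r.key_type, r.key, r.source, json.dumps(dict(r.payload),
                                                         sort_keys=True)),
            )
        if expression is not None:
            for gene in expression.values.index:
                for sample in expression.values.columns:
                    conn.execute(
                        "INSERT INTO expression VALUES (?,?,?)",
                        (gene, sample, float(expression.values.at[gene, sample])),
                    )
            md = expression.metadata
            for sample in md.index:
                conn.execute(
                    "INSERT INTO samples VALUES (?,?,?,?)",
                    (sample,
                     md.at[sample, "cohort"] if "cohort" in md.columns else None,
                     md.at[sample, "group"] if "group" in md.columns else None,
                     md.at[sample, "msi_status"] if "msi_status" in md.columns
                     else None),
                )
        conn.commit()
    finally:
        conn.close()
    return path
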