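"""Evidence joins, differential-expression labeling and coverage checks.

Candidates are annotated by left joins against variant-, peptide- and
gene-keyed evidence tables (dbSNP-like, ClinVar-like, IEDB-like,
expression).  Differentially expressed genes between two sample groups are
flagged with a two-sided rank-sum test and Benjamini-Hochberg adjustment
at adjusted p < 0.05.  Expression filtering keeps candidates from the top
fraction of genes ranked by mean expression within a cohort, and a
coverage check counts exact string matches of a validated peptide list
against the store.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("msneoforge")

KEY_TYPES = ("variant", "peptide", "gene")


@dataclass(frozen=True)
class EvidenceRecord:
    """One evidence row keyed by variant, peptide or gene.

    Variant keys are normalized ``chrom:pos:ref:alt`` strings, left-aligned
    and anchored the same way as the pipeline's canonical variants.
    """

    key_type: str
    key: str
    source: str
    payload: tuple[tuple[str, str], ...] = ()

    def __post_init__(self) -> None:
        if self.key_type not in KEY_TYPES:
            raise ValueError(f"unknown key_type {self.key_type!r}")

    @property
    def payload_dict(self) -> dict[str, str]:
        return dict(self.payload)

    def render(self) -> str:
        body = ";".join(f"{k}={v}" for k, v in self.payload)
        return f"{self.source}[{self.key}]{{{body}}}"


def read_evidence_tsv(path: str | Path, key_type: str,
                      source: str) -> list[EvidenceRecord]:
    """Read a TSV whose first column is the key; other columns are payload.

    Malformed rows (wrong column count, empty key) are skipped with a
    warning.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    key_col = df.columns[0]
    records: list[EvidenceRecord] = []
    for _, row in df.iterrows():
        key = row[key_col]
        if not isinstance(key, str) or not key:
            logger.warning("evidence row with empty key in %s skipped", path)
            continue
        payload = tuple(
            (c, "" if pd.isna(row[c]) else str(row[c]))
            for c in df.columns[1:]
        )
        records.append(EvidenceRecord(key_type, key, source, payload))
    return records


def join_evidence(candidates: pd.DataFrame,
                  evidence: Sequence[EvidenceRecord],
                  key_columns: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Left-join evidence onto a candidate table.

    ``key_columns`` maps key_type -> candidate column holding that key
    (defaults: variant -> 'variant_key', peptide -> 'epitope',
    gene -> 'gene').  Every candidate row is retained; matches are
    concatenated into one ``annotations`` column, ordered by (source, key).
    """
    key_columns = dict(key_columns or
                       {"variant": "variant_key", "peptide": "epitope",
                        "gene": "gene"})
    by_key: dict[tuple[str, str], list[EvidenceRecord]] = {}
    for rec in evidence:
        by_key.setdefault((rec.key_type, rec.key), []).append(rec)

    def annotate_row(row) -> str:
        hits: list[EvidenceRecord] = []
        for key_type, col in key_columns.items():
            if col in row.index and isinstance(row[col], str):
                hits.extend(by_key.get((key_type, row[col]), []))
        hits.sort(key=lambda r: (r.source, r.key))
        return "|".join(r.render() for r in hits)

    out = candidates.copy()
    out["annotations"] = out.apply(annotate_row, axis=1) if len(out) else ""
    return out


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    Sort ascending, multiply p_(i) by m/i, enforce monotonicity by a
    cumulative minimum from the largest rank, cap at 1.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(m)
    out[order] = adjusted
    return out


@dataclass
class ExpressionMatrix:
    """Gene-by-sample expression with per-sample metadata.

    ``values``: DataFrame indexed by gene, columns = samples.
    ``metadata``: DataFrame indexed by sample with at least a ``group``
    column (normal/tumor) and optionally ``cohort`` and ``msi_status``.
    """

    values: pd.DataFrame
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.index.hasnans or (self.values.index == "").any():
            raise ValueError("missing gene ids in expression matrix")
        missing = set(self.values.columns) - set(self.metadata.index)
        if missing:
            raise ValueError(f"samples without metadata: {sorted(missing)}")
        if (self.values.values < 0).any():
            raise ValueError("expression values must be non-negative")

    @classmethod
    def from_tsv(cls, matrix_path: str | Path,
                 metadata_path: str | Path) -> "ExpressionMatrix":
        values = pd.read_csv(matrix_path, sep="\t", index_col=0)
        metadata = pd.read_csv(metadata_path, sep="\t", index_col=0, dtype=str)
        return cls(values=values, metadata=metadata)

    def samples_in(self, group: str | None = None,
                   cohort: str | None = None) -> list[str]:
        md = self.metadata.loc[list(self.values.columns)]
        mask = pd.Series(True, index=md.index)
        if group is not None:
            mask &= md["group"] == group
        if cohort is not None:
            if "cohort" not in md.columns or not (md["cohort"] == cohort).any():
                raise ValueError(f"unknown cohort {cohort!r}")
            mask &= md["cohort"] == cohort
        return list(md.index[mask])


def label_de_genes(expr: ExpressionMatrix, alpha: float = 0.05,
                   groups: tuple[str, str] = ("normal", "tumor")) -> pd.DataFrame:
    """Flag differentially expressed genes between two sample groups.

    Per gene, a two-sided Wilcoxon rank-sum test between the groups;
    Benjamini-Hochberg adjustment over all tested genes; flag = adjusted
    p < alpha.  Genes with zero variance across all samples are untested
    (p and adjusted NaN) and unflagged.  Each group needs >= 2 samples.
    """
    g1 = expr.samples_in(group=groups[0])
    g2 = expr.samples_in(group=groups[1])
    if len(g1) < 2 or len(g2) < 2:
        raise ValueError("each group needs at least 2 samples")
    x = expr.values[g1].to_numpy(dtype=float)
    y = expr.values[g2].to_numpy(dtype=float)
    testable = np.concatenate([x, y], axis=1).std(axis=1) > 0
    pvals = np.full(len(expr.values), np.nan)
    if testable.any():
        stat = stats.ranksums(x[testable], y[testable], axis=1)
        pvals[testable] = stat.pvalue
    adjusted = np.full_like(pvals, np.nan)
    if testable.any():
        adjusted[testable] = bh_adjust(pvals[testable])
    return pd.DataFrame(
        {
            "pvalue": pvals,
            "adjusted": adjusted,
            "de_flag": np.where(np.isnan(adjusted), False, adjusted < alpha),
        },
        index=expr.values.index,
    )


def top_expressed_genes(expr: ExpressionMatrix, cohort: str | None,
                        top_fraction: float,
                        statistic: str = "mean") -> set[str]:
    """Genes in the top fraction by within-cohort expression.

    Ranking statistic is the mean (median by option) over the cohort's
    samples; ties at the cutoff value are all retained.
    """
    if not (0 < top_fraction <= 1):
        raise ValueError("top_fraction must be in (0, 1]")
    samples = expr.samples_in(cohort=cohort)
    if not samples:
        raise ValueError(f"no samples in cohort {cohort!r}")
    sub = expr.values[samples]
    ranked = sub.mean(axis=1) if statistic == "mean" else sub.median(axis=1)
    k = int(np.ceil(top_fraction * len(ranked)))
    cutoff = ranked.sort_values(ascending=False).iloc[k - 1]
    return set(ranked.index[ranked >= cutoff])


def expression_percentile_filter(candidates: pd.DataFrame,
                                 expr: ExpressionMatrix,
                                 cohort: str | None,
                                 top_fraction: float,
                                 gene_column: str = "gene",
                                 statistic: str = "mean") -> pd.DataFrame:
    """Keep candidates whose gene ranks in the top expression fraction."""
    keep = top_expressed_genes(expr, cohort, top_fraction, statistic)
    return candidates[candidates[gene_column].isin(keep)].copy()


@dataclass
class CoverageResult:
    n_present: int
    n_missing: int
    flags: dict[str, bool] = field(default_factory=dict)

    @property
    def fraction_present(self) -> float:
        total = self.n_present + self.n_missing
        return self.n_present / total if total else float("nan")


def coverage_check(known: set[str], peptides: Sequence[str]) -> CoverageResult:
    """Exact-string coverage of a validated peptide list against a store.

    ``known`` is the set of peptide strings held by the store (epitopes,
    optionally full frameshift peptides).  No substring or MHC-restriction
    matching: a peptide differing by one residue counts as missing.
    """
    flags = {p: p in known for p in peptides}
    n_present = sum(flags.values())
    return CoverageResult(
        n_present=n_present,
        n_missing=len(peptides) - n_present,
        flags=flags,
    )
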