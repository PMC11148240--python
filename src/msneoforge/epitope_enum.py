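"""MHC epitope enumeration, binding prediction and filtering.

Fixed-length windows are enumerated from frameshift peptides (8-11-mers
for MHC Class I, 15-mers for Class II by default), scored against an HLA
allele panel through a pluggable predictor contract, aggregated across
algorithms, and retained when the best (minimum) predicted IC50 for an
allele is below 50 nM in any algorithm.  Candidates carry the terminal
residues and the GRAVY score (mean Kyte-Doolittle hydropathy) as
physicochemical annotations.

Binding predictors implement :class:`BindingPredictor`; the built-in
:class:`ToyPredictor` is fully deterministic (a stable 64-bit hash of
(epitope, allele, predictor name) mapped log-uniformly onto [1, 50000] nM)
and stands behind all desk-scale runs.  Adapters around external
prediction suites can be registered through the same contract.
"""

from __future__ import annotations

import hashlib
import logging
import statistics
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Protocol, Sequence

from Bio.SeqUtils.ProtParamData import kd as KYTE_DOOLITTLE

logger = logging.getLogger("msneoforge")

DEFAULT_THRESHOLD_NM = 50.0
DEFAULT_LENGTHS = {"I": (8, 9, 10, 11), "II": (15,)}
_TOY_MAX_NM = 50000.0


@dataclass(frozen=True)
class AllelePanel:
    """A named set of HLA alleles for one MHC class."""

    mhc_class: str  # "I" or "II"
    alleles: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.mhc_class not in {"I", "II"}:
            raise ValueError("mhc_class must be 'I' or 'II'")
        if len(set(self.alleles)) != len(self.alleles):
            raise ValueError("allele names must be unique")


def load_panel(path: str | Path, mhc_class: str) -> AllelePanel:
    """Read a plain-text panel (one allele per line, '#' comments)."""
    alleles = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            alleles.append(line)
    return AllelePanel(mhc_class=mhc_class, alleles=tuple(alleles))


def default_panel(mhc_class: str) -> AllelePanel:
    """The shipped default panel: 27 Class I or 27 Class II alleles."""
    fname = {"I": "class_i_alleles.txt", "II": "class_ii_alleles.txt"}[mhc_class]
    ref = resources.files("msneoforge.data").joinpath(fname)
    with resources.as_file(ref) as path:
        return load_panel(path, mhc_class)


@dataclass(frozen=True)
class BindingScore:
    epitope: str
    allele: str
    algorithm: str
    ic50: float  # nM, finite and positive

    def __post_init__(self) -> None:
        if not (self.ic50 > 0 and self.ic50 == self.ic50 and
                self.ic50 != float("inf")):
            raise ValueError("ic50 must be finite and positive")


@dataclass
class EpitopeCandidate:
    """One retained (epitope, allele) pair with cross-algorithm aggregates."""

    epitope: str
    allele: str
    mhc_class: str
    best: float    # minimum IC50 over algorithms
    median: float
    mean: float
    n_algorithms: int
    n_terminal: str
    c_terminal: str
    gravy: float
    sources: list[tuple[str, int]] = field(default_factory=list)
    # (source_peptide_id, 1-based offset) pairs


class BindingPredictor(Protocol):
    """Contract for MHC binding-affinity predictors."""

    name: str

    def supports(self, mhc_class: str, length: int) -> bool: ...

    def predict(self, epitope: str, allele: str) -> float:
        """Predicted IC50 in nM (finite, positive)."""
        ...


class ToyPredictor:
    """Deterministic stand-in predictor for desk-scale runs.

    IC50 = 50000**u nM where u in [0, 1) is a stable 64-bit hash of
    (epitope, allele, name) scaled to the unit interval -- log-uniform on
    [1, 50000] nM, identical across processes and platforms.
    """

    def __init__(self, name: str = "toy-a",
                 mhc_classes: tuple[str, ...] = ("I", "II"),
                 lengths: tuple[int, ...] | None = None) -> None:
        self.name = name
        self._classes = mhc_classes
        self._lengths = lengths  # None = any length

    def supports(self, mhc_class: str, length: int) -> bool:
        if mhc_class not in self._classes:
            return False
        return self._lengths is None or length in self._lengths

    def predict(self, epitope: str, allele: str) -> float:
        digest = hashlib.blake2b(
            f"{epitope}|{allele}|{self.name}".encode(), digest_size=8
        ).digest()
        u = int.from_bytes(digest, "big") / 2**64
        return _TOY_MAX_NM**u


def default_predictors() -> list[BindingPredictor]:
    """Three toy algorithms, mirroring a multi-algorithm prediction suite."""
    return [ToyPredictor("toy-a"), ToyPredictor("toy-b"), ToyPredictor("toy-c")]


def enumerate_windows(peptide: str,
                      lengths: Iterable[int]) -> list[tuple[str, int]]:
    """All (window, 1-based offset) pairs for each requested length.

    For each length L <= |peptide| there are exactly |peptide| - L + 1
    windows, emitted in ascending length then offset order.  Duplicate
    window strings across offsets are retained here and deduplicated at
    scoring time.
    """
    lengths = sorted(set(lengths))
    if not lengths:
        raise ValueError("at least one window length is required")
    out = []
    for L in lengths:
        for i in range(len(peptide) - L + 1):
            out.append((peptide[i : i + L], i + 1))
    return out


def predict_binding(
    epitopes: Sequence[str],
    panel: AllelePanel,
    predictors: Sequence[BindingPredictor],
) -> list[BindingScore]:
    """One score per (epitope, allele, predictor) the predictor supports.

    Unsupported (class, length) combinations are recorded as missing, not
    zero; a predictor raising on an input drops that predictor's scores
    for the batch with a warning and the run continues.
    """
    unique = sorted(set(epitopes))
    scores: list[BindingScore] = []
    for pred in predictors:
        supported = [e for e in unique if pred.supports(panel.mhc_class, len(e))]
        if not supported:
            logger.warning(
                "predictor %s supports no epitopes for Class %s panel",
                pred.name, panel.mhc_class,
            )
            continue
        batch: list[BindingScore] = []
        try:
            for e in supported:
                for allele in panel.alleles:
                    batch.append(
                        BindingScore(e, allele, pred.name, pred.predict(e, allele))
                    )
        except Exception as exc:  # drop this predictor's batch, keep going
            logger.warning("predictor %s failed (%s); its scores dropped",
                           pred.name, exc)
            continue
        scores.extend(batch)
    return scores


def gravy(peptide: str) -> float:
    """GRAVY: arithmetic mean of per-residue Kyte-Doolittle hydropathy."""
    if not peptide:
        raise ValueError("empty peptide")
    try:
        return sum(KYTE_DOOLITTLE[aa] for aa in peptide) / len(peptide)
    except KeyError as exc:
        raise ValueError(f"nonstandard residue {exc.args[0]!r}") from None


def terminal_residues(peptide: str) -> tuple[str, str]:
    if not peptide:
        raise ValueError("empty peptide")
    return peptide[0], peptide[-1]


def aggregate_and_filter(
    scores: Sequence[BindingScore],
    mhc_class: str,
    threshold_nM: float = DEFAULT_THRESHOLD_NM,
    sources: dict[str, list[tuple[str, int]]] | None = None,
) -> list[EpitopeCandidate]:
    """Retain (epitope, allele) pairs whose minimum IC50 over algorithms is
    below the threshold -- a strong prediction by any one algorithm
    suffices.  Aggregates (best = min, median, mean) are computed over the
    algorithms that returned scores; pairs with no scores are dropped.
    ``sources`` optionally maps epitope string -> (peptide_id, offset)
    provenance attached to each candidate.
    """
    grouped: dict[tuple[str, str], list[float]] = {}
    for s in scores:
        grouped.setdefault((s.epitope, s.allele), []).append(s.ic50)
    out: list[EpitopeCandidate] = []
    for (epitope, allele) in sorted(grouped):
        vals = grouped[(epitope, allele)]
        if min(vals) >= threshold_nM:
            continue
        out.append(
            EpitopeCandidate(
                epitope=epitope,
                allele=allele,
                mhc_class=mhc_class,
                best=min(vals),
                median=statistics.median(vals),
                mean=sum(vals) / len(vals),
                n_algorithms=len(vals),
                n_terminal=epitope[0],
                c_terminal=epitope[-1],
                gravy=gravy(epitope),
                sources=sorted((sources or {}).get(epitope, [])),
            )
        )
    return out


def candidates_to_tsv(candidates: Sequence[EpitopeCandidate],
                      path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("epitope\tallele\tmhc_class\tbest_ic50\tmedian_ic50\t"
                 "mean_ic50\tn_algorithms\tgravy\tn_terminal\tc_terminal\t"
                 "source_peptides\n")
        for c in candidates:
            src = ",".join(f"{pid}@{off}" for pid, off in c.sources)
            fh.write(
                f"{c.epitope}\t{c.allele}\t{c.mhc_class}\t{c.best:.4f}\t"
                f"{c.median:.4f}\t{c.mean:.4f}\t{c.n_algorithms}\t"
                f"{c.gravy:.4f}\t{c.n_terminal}\t{c.c_terminal}\t{src}\n"
            )


def enumerate_and_score(
    peptides,  # Sequence[FrameshiftPeptide]
    mhc_class: str,
    panel: AllelePanel | None = None,
    predictors: Sequence[BindingPredictor] | None = None,
    lengths: Iterable[int] | None = None,
    threshold_nM: float = DEFAULT_THRESHOLD_NM,
) -> tuple[list[BindingScore], list[EpitopeCandidate]]:
    """Window enumeration + prediction + filtering for one MHC class."""
    panel = panel or default_panel(mhc_class)
    predictors = predictors if predictors is not None else default_predictors()
    lengths = tuple(lengths) if lengths else DEFAULT_LENGTHS[mhc_class]
    sources: dict[str, list[tuple[str, int]]] = {}
    for pep in peptides:
        for window, offset in enumerate_windows(pep.peptide, lengths):
            sources.setdefault(window, []).append((pep.peptide_id, offset))
    scores = predict_binding(sorted(sources), panel, predictors)
    candidates = aggregate_and_filter(scores, mhc_class, threshold_nM, sources)
    return scores, candidates
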