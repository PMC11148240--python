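import numpy as np
import pytest

from msneoforge.cli import run_fixture_pipeline
from msneoforge.genome_io import GenomeSequence
from msneoforge.repeat_scan import DEFAULT_MIN_UNITS


def brute_scan(seq: str, minima: dict[int, int] | None = None):
    """Exhaustive reference scanner: per-start whole-unit counting.

    Tests every (start, motif_len) pair left to right, counts whole units
    by direct string comparison, and applies the same emission rule as the
    production scanner (leftmost anchor, resume after an emitted tract).
    Independent of the production implementation's match-run machinery.
    """
    minima = minima or DEFAULT_MIN_UNITS
    n = len(seq)
    out = []
    for k in (1, 2, 3, 4, 5):
        i = 0
        resume_at = 0
        while i + k <= n:
            if i < resume_at:
                i += 1
                continue
            motif = seq[i : i + k]
            # primitivity via the doubling trick (smallest period == k)
            if "N" in motif or (motif + motif).index(motif, 1) != k:
                i += 1
                continue
            u = 1
            while seq[i + u * k : i + (u + 1) * k] == motif:
                u += 1
            if u >= minima[k]:
                out.append((i + 1, i + u * k, motif, u))
                resume_at = i + u * k
                i = i + u * k
            else:
                i += 1
    return sorted(out, key=lambda t: (t[0], len(t[2])))


def random_dna(rng: np.random.Generator, n: int, with_n: float = 0.0) -> str:
    alphabet = "ACGTN" if with_n else "ACGT"
    probs = None
    if with_n:
        probs = [(1 - with_n) / 4] * 4 + [with_n]
    idx = rng.choice(len(alphabet), size=n, p=probs)
    return "".join(alphabet[i] for i in idx)


@pytest.fixture(scope="session")
def small_run(tmp_path_factory):
    """One full pipeline run on the small fixture preset (seed 1)."""
    outdir = tmp_path_factory.mktemp("small_run")
    result, fx = run_fixture_pipeline("small", seed=1, outdir=outdir)
    return result, fx


@pytest.fixture
def toy_genome():
    return GenomeSequence("chr1", "ATGAAACCCGGGTTTACGTAGCATGCA")
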