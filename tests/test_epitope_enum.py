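"""Window enumeration, toy prediction, IC50 filtering and annotations."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from msneoforge.epitope_enum import (
    AllelePanel,
    BindingScore,
    ToyPredictor,
    aggregate_and_filter,
    default_panel,
    default_predictors,
    enumerate_windows,
    gravy,
    predict_binding,
    terminal_residues,
)

AA = "ACDEFGHIKLMNPQRSTVWY"

# Kyte-Doolittle hydropathy, frozen independently for the lookup oracle
KD = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5, "Q": -3.5,
    "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5, "L": 3.8, "K": -3.9,
    "M": 1.9, "F": 2.8, "P": -1.6, "S": -0.8, "T": -0.7, "W": -0.9,
    "Y": -1.3, "V": 4.2,
}


def random_peptides(rng, n, length=9):
    return ["".join(AA[i] for i in rng.integers(0, 20, size=length))
            for _ in range(n)]


class TestPanels:
    def test_default_panels_have_27_alleles_each(self):
        assert len(default_panel("I").alleles) == 27
        assert len(default_panel("II").alleles) == 27

    def test_class_i_panel_contents(self):
        alleles = default_panel("I").alleles
        assert "HLA-A*02:01" in alleles and "HLA-B*07:02" in alleles
        assert all(a.startswith("HLA-") for a in alleles)

    def test_class_ii_pairs_joined(self):
        alleles = default_panel("II").alleles
        assert "DQA1*05:01-DQB1*02:01" in alleles
        assert sum("-" in a for a in alleles) == 12  # 6 DQ + 6 DP pairs

    def test_duplicate_alleles_rejected(self):
        with pytest.raises(ValueError):
            AllelePanel("I", ("HLA-A*01:01", "HLA-A*01:01"))


class TestWindows:
    @pytest.mark.parametrize("plen,lengths,expected", [
        (10, {9, 10}, 3),
        (8, {9}, 0),
        (20, {15}, 6),
        (15, {15}, 1),
    ])
    def test_window_counts(self, plen, lengths, expected):
        windows = enumerate_windows("A" * plen, lengths)
        assert len(windows) == expected

    def test_windows_are_substrings_at_offset(self):
        pep = "ACDEFGHIKLMNP"
        for w, off in enumerate_windows(pep, {8, 9}):
            assert pep[off - 1 : off - 1 + len(w)] == w

    @given(st.integers(min_value=1, max_value=60))
    @settings(derandomize=True, max_examples=60)
    def test_closed_form_count(self, plen):
        n = len(enumerate_windows("A" * plen, {15}))
        assert n == max(0, plen - 14)

    def test_empty_lengths_rejected(self):
        with pytest.raises(ValueError):
            enumerate_windows("ACDEF", set())


class TestToyPredictor:
    def test_deterministic(self):
        p = ToyPredictor("toy-a")
        a = p.predict("SIINFEKL", "HLA-A*02:01")
        b = p.predict("SIINFEKL", "HLA-A*02:01")
        assert a == b

    def test_range_and_distribution(self):
        rng = np.random.default_rng(0)
        p = ToyPredictor("toy-a")
        vals = [p.predict(e, "HLA-A*02:01") for e in random_peptides(rng, 500)]
        assert all(1 <= v <= 50000 for v in vals)
        # log-uniform: roughly uniform in log space over [0, log 50000]
        logs = np.log(vals) / np.log(50000)
        assert 0.4 < np.mean(logs) < 0.6

    def test_distinct_predictors_disagree(self):
        a = ToyPredictor("toy-a").predict("SIINFEKL", "HLA-A*02:01")
        b = ToyPredictor("toy-b").predict("SIINFEKL", "HLA-A*02:01")
        assert a != b

    def test_class_restricted_predictor_warns(self, caplog):
        panel = AllelePanel("II", ("DRB1*01:01",))
        pred = ToyPredictor("toy-i", mhc_classes=("I",))
        with caplog.at_level("WARNING", logger="msneoforge"):
            scores = predict_binding(["A" * 15], panel, [pred])
        assert scores == [] and "supports no epitopes" in caplog.text

    def test_score_cardinality_bound(self):
        panel = AllelePanel("I", ("HLA-A*01:01", "HLA-A*02:01"))
        preds = [ToyPredictor("a"), ToyPredictor("b")]
        scores = predict_binding(["ACDEFGHIK", "ACDEFGHIL", "ACDEFGHIM"],
                                 panel, preds)
        assert len(scores) == 12  # 3 epitopes x 2 alleles x 2 predictors

    def test_failing_predictor_dropped_run_continues(self, caplog):
        class Exploding:
            name = "boom"
            def supports(self, mhc_class, length):
                return True
            def predict(self, epitope, allele):
                raise RuntimeError("no model")
        panel = AllelePanel("I", ("HLA-A*01:01",))
        with caplog.at_level("WARNING", logger="msneoforge"):
            scores = predict_binding(["ACDEFGHIK"], panel,
                                     [Exploding(), ToyPredictor("ok")])
        assert {s.algorithm for s in scores} == {"ok"}
        assert "boom" in caplog.text


class TestAggregateAndFilter:
    def mk(self, epitope, allele, alg, ic50):
        return BindingScore(epitope, allele, alg, ic50)

    def test_any_algorithm_below_threshold_retains(self):
        scores = [self.mk("ACDEFGHIK", "X", "a", 40.0),
                  self.mk("ACDEFGHIK", "X", "b", 600.0)]
        out = aggregate_and_filter(scores, "I")
        assert len(out) == 1 and out[0].best == 40.0

    def test_all_above_threshold_dropped(self):
        scores = [self.mk("ACDEFGHIK", "X", "a", 60.0),
                  self.mk("ACDEFGHIK", "X", "b", 70.0)]
        assert aggregate_and_filter(scores, "I") == []

    def test_median_matches_sort_oracle(self):
        scores = [self.mk("ACDEFGHIK", "X", a, v)
                  for a, v in [("a", 10.0), ("b", 40.0), ("c", 600.0)]]
        out = aggregate_and_filter(scores, "I")
        vals = sorted([10.0, 40.0, 600.0])
        assert out[0].median == vals[1] == 40.0
        assert out[0].best == min(vals)
        assert out[0].mean == pytest.approx(sum(vals) / 3)

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(1)
        pred = default_predictors()
        panel = AllelePanel("I", tuple(default_panel("I").alleles[:5]))
        scores = predict_binding(random_peptides(rng, 50), panel, pred)
        kept_strict = {(c.epitope, c.allele)
                       for c in aggregate_and_filter(scores, "I", 25.0)}
        kept_loose = {(c.epitope, c.allele)
                      for c in aggregate_and_filter(scores, "I", 50.0)}
        assert kept_strict <= kept_loose

    def test_invariant_best_le_median_le_mean_ordering(self):
        rng = np.random.default_rng(2)
        scores = predict_binding(
            random_peptides(rng, 100),
            AllelePanel("I", ("HLA-A*02:01",)), default_predictors())
        for c in aggregate_and_filter(scores, "I", 50000.0):
            assert c.best <= c.median and c.best <= c.mean


class TestAnnotations:
    def test_gravy_known_values(self):
        assert gravy("III") == pytest.approx(4.5)
        assert gravy("RRR") == pytest.approx(-4.5)

    def test_gravy_matches_lookup_oracle(self):
        rng = np.random.default_rng(3)
        for pep in random_peptides(rng, 200, length=11):
            assert gravy(pep) == pytest.approx(sum(KD[a] for a in pep) / 11)

    def test_gravy_rejects_nonstandard(self):
        with pytest.raises(ValueError):
            gravy("ACX")
        with pytest.raises(ValueError):
            gravy("")

    def test_terminal_residues(self):
        assert terminal_residues("ACDEF") == ("A", "F")
        assert terminal_residues("M") == ("M", "M")
        with pytest.raises(ValueError):
            terminal_residues("")

    @given(st.text(alphabet=AA, min_size=1, max_size=20))
    @settings(derandomize=True, max_examples=100)
    def test_terminals_swap_under_reversal(self, pep):
        f, l = terminal_residues(pep)
        rf, rl = terminal_residues(pep[::-1])
        assert (f, l) == (rl, rf)
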