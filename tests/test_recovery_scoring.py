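import numpy as np
import pandas as pd
import pytest

from hybqc.core_io import RecoveryMatrix
from hybqc.recovery_scoring import (
    age_effect_report,
    capture_success,
    coverage_scores,
    filter_by_score,
)


def matrix(values, accessions, loci, target=100.0):
    rec = pd.DataFrame(values, index=accessions, columns=loci, dtype=float)
    return RecoveryMatrix(rec, pd.Series({l: target for l in loci}))


class TestCaptureSuccess:
    def test_simple_ratio(self):
        assert capture_success(28, 100) == pytest.approx(0.28)

    def test_zero(self):
        assert capture_success(0, 500) == 0.0

    def test_over_recovery_capped_with_warning(self):
        with pytest.warns(UserWarning, match="capping"):
            assert capture_success(120, 100) == 1.0

    def test_bad_target(self):
        with pytest.raises(ValueError):
            capture_success(10, 0)


class TestCoverageScores:
    def test_perfect_recovery_scores_one(self):
        m = matrix([[100, 100, 100, 100]], ["a"], ["l1", "l2", "l3", "l4"])
        (s,) = coverage_scores(m)
        assert (s.representativeness, s.completeness, s.evenness, s.score) \
            == (1.0, 1.0, 1.0, 1.0)

    def test_nothing_recovered_scores_zero(self):
        m = matrix([[0, 0, 0, 0]], ["a"], ["l1", "l2", "l3", "l4"])
        (s,) = coverage_scores(m)
        assert s.score == 0.0 and s.representativeness == 0.0

    def test_worked_half_example(self):
        m = matrix([[50, 50, 0, 0]], ["a"], ["l1", "l2", "l3", "l4"])
        (s,) = coverage_scores(m)
        assert s.representativeness == pytest.approx(0.5)
        assert s.completeness == pytest.approx(0.5)
        assert s.evenness == pytest.approx(np.log(2) / np.log(4))
        assert s.score == pytest.approx(0.125)

    def test_total_completeness_variant(self):
        m = matrix([[50, 50, 0, 0]], ["a"], ["l1", "l2", "l3", "l4"])
        (s,) = coverage_scores(m, completeness="total")
        assert s.completeness == pytest.approx(0.25)

    def test_single_locus_evenness_defined_as_one(self):
        m = matrix([[70]], ["a"], ["l1"])
        (s,) = coverage_scores(m)
        assert s.evenness == 1.0
        assert s.score == pytest.approx(0.7)

    def test_transpose_symmetry(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            n_a, n_l = rng.integers(2, 6, size=2)
            vals = rng.integers(0, 101, size=(n_a, n_l)).astype(float)
            m = matrix(vals, [f"a{i}" for i in range(n_a)],
                       [f"l{j}" for j in range(n_l)])
            by_locus = coverage_scores(m, axis="loci")
            on_transpose = coverage_scores(m.transpose(), axis="accessions")
            for x, y in zip(by_locus, on_transpose):
                assert x.score == pytest.approx(y.score)
                assert x.evenness == pytest.approx(y.evenness)

    def test_uniform_rescaling_preserves_r_and_e(self):
        m1 = matrix([[80, 40, 0, 20]], ["a"], ["l1", "l2", "l3", "l4"])
        m2 = matrix([[40, 20, 0, 10]], ["a"], ["l1", "l2", "l3", "l4"])
        (s1,), (s2,) = coverage_scores(m1), coverage_scores(m2)
        assert s1.representativeness == s2.representativeness
        assert s1.evenness == pytest.approx(s2.evenness)
        assert s1.completeness == pytest.approx(2 * s2.completeness)

    def test_empty_matrix(self):
        m = RecoveryMatrix(pd.DataFrame(dtype=float),
                           pd.Series(dtype=float))
        assert coverage_scores(m) == []


class TestFilterByScore:
    def make(self, values):
        m = matrix([[v * 100] for v in values],
                   [f"a{i}" for i in range(len(values))], ["l1"])
        return coverage_scores(m)

    def test_cutoff_is_inclusive(self):
        scores = self.make([0.49, 0.50, 0.51])
        assert filter_by_score(scores, 0.5) == ["a1", "a2"]

    def test_cutoff_zero_keeps_all(self):
        scores = self.make([0.1, 0.0, 0.9])
        assert len(filter_by_score(scores, 0.0)) == 3

    def test_cutoff_one_keeps_perfect_only(self):
        scores = self.make([1.0, 0.99])
        assert filter_by_score(scores, 1.0) == ["a0"]


class TestAgeEffect:
    def herbarium(self, pairs, extra=()):
        accs, rows, meta = [], [], []
        for i, (year, frac) in enumerate(pairs):
            accs.append(f"h{i}")
            rows.append([frac * 100.0])
            meta.append({"accession": f"h{i}", "collection_year": year,
                         "source": "herbarium"})
        for i, frac in enumerate(extra):
            accs.append(f"b{i}")
            rows.append([frac * 100.0])
            meta.append({"accession": f"b{i}", "collection_year": 2015,
                         "source": "dna_bank"})
        rec = pd.DataFrame(rows, index=accs, columns=["l1"], dtype=float)
        return RecoveryMatrix(
            rec, pd.Series({"l1": 100.0}),
            pd.DataFrame(meta).set_index("accession"),
        )

    def test_collinear_regression(self):
        m = self.herbarium([(2000, 0.0), (2001, 0.5), (2002, 1.0)])
        rep = age_effect_report(m)
        assert rep.slope == pytest.approx(0.5)
        assert rep.r_squared == pytest.approx(1.0)

    def test_closed_form_ols(self):
        m = self.herbarium([(0, 0.0), (1, 0.0), (2, 1.0)])
        rep = age_effect_report(m)
        assert rep.slope == pytest.approx(0.5)
        assert rep.r_squared == pytest.approx(0.75)
        assert rep.df == 1

    def test_identical_groups_give_t_zero(self):
        m = self.herbarium(
            [(2000, 0.2), (2001, 0.4), (2002, 0.6)],
            extra=(0.2, 0.4, 0.6),
        )
        rep = age_effect_report(m)
        assert rep.t_stat == pytest.approx(0.0, abs=1e-12)

    def test_missing_group_warns(self):
        m = self.herbarium([(2000, 0.2), (2001, 0.4), (2002, 0.6)])
        with pytest.warns(UserWarning, match="contrast omitted"):
            rep = age_effect_report(m)
        assert rep.t_stat is None and rep.welch_df is None

    def test_welch_df_matches_satterthwaite(self):
        m = self.herbarium(
            [(2000, 0.1), (2001, 0.3), (2002, 0.2), (2003, 0.25)],
            extra=(0.9, 0.95, 0.85),
        )
        rep = age_effect_report(m)
        a = np.array([0.9, 0.95, 0.85])
        b = np.array([0.1, 0.3, 0.2, 0.25])
        va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
        expected = (va + vb) ** 2 / (
            va**2 / (len(a) - 1) + vb**2 / (len(b) - 1)
        )
        assert rep.welch_df == pytest.approx(expected)
        assert rep.t_stat > 0  # bank/silica recover more
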