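import numpy as np
import pandas as pd
import pytest
from scipy import stats

from autoppi import (co_expression_evidence, compute_feature_table,
                     diversity_of_functions, fit_binning,
                     minimal_shared_term_size, score_features)
from autoppi.catalogs import AnnotationCatalog
from autoppi.features import FEATURES


def _expr(rows: dict) -> pd.DataFrame:
    return pd.DataFrame({g: pd.Series(v) for g, v in rows.items()}).T


class TestCoExpression:
    @pytest.mark.parametrize("xa,xb,expected", [
        ((1, 2, 3), (2, 4, 6), 1.0),
        ((1, 2, 3), (6, 4, 2), -1.0),
        ((1, 2, 3, 4), (1, 3, 2, 4), 0.8),  # cov=1, var=1.25 each -> r=0.8
    ])
    def test_hand_computed_pearson(self, xa, xb, expected):
        expr = _expr({"A": xa, "B": xb})
        assert co_expression_evidence(("A", "B"), expr) == pytest.approx(expected)

    def test_absent_protein_is_missing(self):
        expr = _expr({"A": (1, 2, 3)})
        assert np.isnan(co_expression_evidence(("A", "B"), expr))

    def test_fewer_than_three_shared_samples_is_missing(self):
        expr = _expr({"A": (1, 2, np.nan, np.nan), "B": (np.nan, 2, 3, 4)})
        assert np.isnan(co_expression_evidence(("A", "B"), expr))

    def test_zero_variance_is_missing(self):
        expr = _expr({"A": (5, 5, 5), "B": (1, 2, 3)})
        assert np.isnan(co_expression_evidence(("A", "B"), expr))


class TestMinimalSharedTerm:
    def test_minimum_over_shared_terms(self):
        cat = AnnotationCatalog(
            [("A", "small"), ("B", "small"), ("C", "small"),
             ("A", "big"), ("B", "big")]
            + [(f"X{i}", "big") for i in range(38)])
        assert cat.term_size("big") == 40
        assert minimal_shared_term_size(("A", "B"), cat) == 3

    def test_no_shared_term_is_missing(self):
        cat = AnnotationCatalog([("A", "T1"), ("B", "T2")])
        assert np.isnan(minimal_shared_term_size(("A", "B"), cat))

    def test_matches_exhaustive_scan(self, small_universe):
        cat = small_universe.go
        rng = np.random.default_rng(2)
        proteins = sorted(cat.proteins)
        for _ in range(100):
            a, b = rng.choice(proteins, size=2, replace=False)
            got = minimal_shared_term_size((a, b), cat)
            shared = [t for t in cat.terms
                      if a in cat.members_of(t) and b in cat.members_of(t)]
            if not shared:
                assert np.isnan(got)
            else:
                assert got == min(len(cat.members_of(t)) for t in shared)
                assert all(got <= len(cat.members_of(t)) for t in shared)


class TestDiversity:
    def test_sum_of_annotation_counts(self):
        cat = AnnotationCatalog([("A", f"T{i}") for i in range(5)]
                                + [("B", "T0"), ("B", "T9")])
        assert diversity_of_functions(("A", "B"), cat) == 7

    def test_unannotated_pair_is_zero(self):
        cat = AnnotationCatalog([("X", "T")])
        assert diversity_of_functions(("A", "B"), cat) == 0


def test_all_features_are_swap_symmetric(small_universe):
    rng = np.random.default_rng(4)
    proteins = sorted(small_universe.go.proteins | set(small_universe.expression.index))
    for _ in range(200):
        a, b = rng.choice(proteins, size=2, replace=False)
        for fn, arg in ((co_expression_evidence, small_universe.expression),
                        (minimal_shared_term_size, small_universe.go),
                        (minimal_shared_term_size, small_universe.kegg),
                        (diversity_of_functions, small_universe.go)):
            x, y = fn((a, b), arg), fn((b, a), arg)
            assert (x == y) or (np.isnan(x) and np.isnan(y))


class TestBinning:
    def test_exact_quartiles(self):
        df = pd.DataFrame({"co_expression": np.arange(1, 101, dtype=float)})
        scheme = fit_binning(df, 4, features=("co_expression",))
        bins = scheme.transform_column("co_expression", df["co_expression"].to_numpy())
        counts = np.bincount(bins)
        assert counts.tolist() == [25, 25, 25, 25]

    def test_constant_feature_collapses_with_warning(self, caplog):
        df = pd.DataFrame({"co_expression": np.full(50, 3.0)})
        scheme = fit_binning(df, 5, features=("co_expression",))
        assert scheme.n_value_bins("co_expression") == 1
        assert any("effective bins" in m for m in caplog.messages)

    def test_all_missing_feature_gets_only_missing_bin(self, caplog):
        df = pd.DataFrame({"co_expression": np.full(10, np.nan)})
        scheme = fit_binning(df, 3, features=("co_expression",))
        bins = scheme.transform_column("co_expression", df["co_expression"].to_numpy())
        assert set(bins) == {scheme.missing_bin("co_expression")}
        assert any("all-missing" in m for m in caplog.messages)

    def test_missing_maps_to_dedicated_bin(self):
        df = pd.DataFrame({"co_expression": [0.1, 0.5, 0.9, np.nan]})
        scheme = fit_binning(df, 2, features=("co_expression",))
        bins = scheme.transform_column(
            "co_expression", np.array([0.1, np.nan]))
        assert bins[1] == scheme.missing_bin("co_expression")
        assert bins[0] < bins[1]

    def test_binning_is_monotone(self):
        rng = np.random.default_rng(5)
        values = rng.normal(size=500)
        df = pd.DataFrame({"co_expression": values})
        scheme = fit_binning(df, 5, features=("co_expression",))
        bins = scheme.transform_column("co_expression", np.sort(values))
        assert (np.diff(bins) >= 0).all()

    def test_equal_frequency_within_multinomial_noise(self):
        rng = np.random.default_rng(6)
        train = pd.DataFrame({"co_expression": rng.uniform(size=1000)})
        scheme = fit_binning(train, 5, features=("co_expression",))
        fresh = rng.uniform(size=1000)
        counts = np.bincount(scheme.transform_column("co_expression", fresh),
                             minlength=5)[:5]
        sd = np.sqrt(1000 * 0.2 * 0.8)
        assert (np.abs(counts - 200) <= 2 * sd).all()

    def test_rejects_bad_inputs(self):
        with pytest.raises(ValueError):
            fit_binning(pd.DataFrame(), 5)
        with pytest.raises(ValueError):
            fit_binning(pd.DataFrame({"co_expression": [1.0, 2.0]}), 1,
                        features=("co_expression",))


class TestFeatureScoring:
    def _table(self, x_pos, x_neg):
        return pd.DataFrame({
            "co_expression": np.concatenate([x_pos, x_neg]),
            "label": np.concatenate([np.ones(len(x_pos), int),
                                     np.zeros(len(x_neg), int)])})

    def test_perfect_separation_gives_vanishing_p(self):
        df = self._table(np.ones(50) + np.random.default_rng(0).normal(0, 1e-6, 50),
                         np.zeros(50))
        out = score_features(df, features=("co_expression",))
        assert out.loc[0, "p_value"] < 1e-30
        assert out.loc[0, "rank"] == 1

    def test_f_equals_squared_t(self):
        rng = np.random.default_rng(1)
        df = self._table(rng.normal(1, 1, 40), rng.normal(0, 1, 60))
        out = score_features(df, features=("co_expression",))
        t, _ = stats.ttest_ind(df.loc[df.label == 1, "co_expression"],
                               df.loc[df.label == 0, "co_expression"])
        assert out.loc[0, "score"] == pytest.approx(t**2, rel=1e-10)

    def test_null_feature_type_one_error_rate(self):
        """Independent feature: ~5% of repeats rejected at alpha = 0.05."""
        rng = np.random.default_rng(2)
        rejections = 0
        for _ in range(200):
            df = self._table(rng.normal(size=30), rng.normal(size=30))
            out = score_features(df, features=("co_expression",))
            rejections += out.loc[0, "p_value"] < 0.05
        assert 1 <= rejections <= 25  # binomial(200, .05): far beyond 4 SD on each side

    def test_single_class_rejected(self):
        df = self._table(np.ones(10), np.ones(0))
        with pytest.raises(ValueError):
            score_features(df, features=("co_expression",))


def test_compute_feature_table_assembles_all_columns(small_universe):
    pairs = sorted(small_universe.planted)[:20]
    labels = {p: 1 for p in pairs}
    table = compute_feature_table(pairs, small_universe.go, small_universe.kegg,
                                  small_universe.expression, labels=labels)
    assert list(table.columns) == ["protein_a", "protein_b", *FEATURES, "label"]
    assert len(table) == 20
    ok = table["co_expression"].dropna()
    assert ((ok >= -1) & (ok <= 1)).all()
    mgo = table["minimal_go"].dropna()
    assert (mgo >= 2).all()
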