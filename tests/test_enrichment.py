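import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import omicscore as oc
from conftest import toy_diff_table


# ---------------------------------------------------------------------------
# differential abundance score


def _annotation(mapping):
    rows = [
        {"feature_id": f, "super_pathway": "sp", "sub_pathway": sub}
        for sub, feats in mapping.items()
        for f in feats
    ]
    return oc.PathwayAnnotation(pd.DataFrame(rows).set_index("feature_id"))


class TestDaScore:
    def test_all_members_up_scores_100(self):
        diff = toy_diff_table([(f"m{i}", 1.0, 0.01) for i in range(5)])
        ann = _annotation({"DG": [f"m{i}" for i in range(5)]})
        out = oc.differential_abundance_score(diff, ann)
        assert out.da_score.iloc[0] == 100.0
        assert out.included.iloc[0]

    def test_all_members_down_scores_minus_100(self):
        diff = toy_diff_table([(f"m{i}", -1.0, 0.01) for i in range(5)])
        ann = _annotation({"DG": [f"m{i}" for i in range(5)]})
        assert oc.differential_abundance_score(diff, ann).da_score.iloc[0] == -100.0

    def test_mixed_counts_follow_formula(self):
        records = (
            [(f"u{i}", 1.0, 0.01) for i in range(7)]
            + [(f"d{i}", -1.0, 0.01) for i in range(2)]
            + [("n0", 0.5, 0.9)]
        )
        diff = toy_diff_table(records)
        ann = _annotation({"sub": [r[0] for r in records]})
        row = oc.differential_abundance_score(diff, ann).iloc[0]
        assert (row.n_measured, row.n_up, row.n_down) == (10, 7, 2)
        assert row.da_score == pytest.approx(50.0)

    def test_no_significant_members_scores_zero_and_excluded(self):
        diff = toy_diff_table([(f"m{i}", 0.3, 0.5) for i in range(3)])
        ann = _annotation({"quiet": [f"m{i}" for i in range(3)]})
        out = oc.differential_abundance_score(diff, ann, min_altered_rule="altered")
        assert out.da_score.iloc[0] == 0.0
        assert not out.included.iloc[0]
        # the figure-legend variant includes it: 3 measured members suffice
        alt = oc.differential_abundance_score(diff, ann, min_altered_rule="measured")
        assert alt.included.iloc[0]

    def test_score_bounded(self, rng):
        for _ in range(50):
            n = rng.integers(3, 12)
            records = [
                (f"m{i}", float(rng.normal()), float(rng.random())) for i in range(n)
            ]
            diff = toy_diff_table(records)
            ann = _annotation({"s": [r[0] for r in records]})
            row = oc.differential_abundance_score(diff, ann).iloc[0]
            assert -100 <= row.da_score <= 100
            assert row.n_up + row.n_down <= row.n_measured
            # ±100 iff every measured member significant in one direction
            if abs(row.da_score) == 100:
                assert row.n_up == row.n_measured or row.n_down == row.n_measured

    def test_empty_annotation_errors(self):
        diff = toy_diff_table([("m0", 1.0, 0.01)])
        empty = oc.PathwayAnnotation(
            pd.DataFrame(columns=["super_pathway", "sub_pathway"])
        )
        with pytest.raises(ValueError, match="empty"):
            oc.differential_abundance_score(diff, empty)


# ---------------------------------------------------------------------------
# over-representation


def exhaustive_ora_p(N, K, n, k):
    """P(overlap ≥ k) by enumerating every n-subset of an N universe."""
    universe = range(N)
    sig = set(range(K))
    hits = total = 0
    for subset in itertools.combinations(universe, n):
        total += 1
        if len(sig.intersection(subset)) >= k:
            hits += 1
    return hits / total


class TestOra:
    def test_hand_enumerated_example(self):
        # N=10, K=4, n=3, k=3 → C(4,3)/C(10,3) = 4/120
        diff = toy_diff_table(
            [(f"s{i}", 1.0, 0.01) for i in range(4)]
            + [(f"x{i}", 0.1, 0.9) for i in range(6)]
        )
        sets = oc.MetaboliteSetCollection({"hot": ["s0", "s1", "s2"]})
        out = oc.ora_hypergeometric(diff, sets)
        assert out.loc["hot", "p"] == pytest.approx(4 / 120)

    def test_no_significant_features_gives_p1(self):
        diff = toy_diff_table([(f"x{i}", 0.1, 0.9) for i in range(6)])
        sets = oc.MetaboliteSetCollection({"s": ["x0", "x1"]})
        assert oc.ora_hypergeometric(diff, sets).loc["s", "p"] == pytest.approx(1.0)

    def test_member_outside_universe_dropped(self):
        diff = toy_diff_table([("a", 1.0, 0.01), ("b", 0.1, 0.9), ("c", 0.2, 0.8)])
        sets = oc.MetaboliteSetCollection({"s": ["a", "b", "ghost"]})
        assert oc.ora_hypergeometric(diff, sets).loc["s", "n"] == 2

    def test_equals_exhaustive_enumeration_small_universes(self, rng):
        """Hypergeometric upper tail ≡ subset enumeration for N ≤ 12."""
        for _ in range(60):
            N = int(rng.integers(3, 13))
            K = int(rng.integers(0, N + 1))
            n = int(rng.integers(1, N + 1))
            k = int(rng.integers(0, min(K, n) + 1))
            expected = exhaustive_ora_p(N, K, n, k)
            assert stats.hypergeom.sf(k - 1, N, K, n) == pytest.approx(expected, abs=1e-12)

    def test_empty_universe_errors(self):
        diff = toy_diff_table([("a", 1.0, 0.01)]).iloc[:0]
        with pytest.raises(ValueError, match="universe"):
            oc.ora_hypergeometric(diff, oc.MetaboliteSetCollection({"s": ["a"]}))


# ---------------------------------------------------------------------------
# asterisk ranking


class TestRankSubpathways:
    @staticmethod
    def _da(rows):
        return pd.DataFrame(rows, columns=["sub_pathway", "comparison", "da_score"]).assign(
            n_measured=5, n_up=0, n_down=0, included=True, exclusion_reason=None
        )

    @staticmethod
    def _ora(fdrs):
        return pd.DataFrame({"fdr": pd.Series(fdrs)}).rename_axis("set")

    def test_more_stars_ranks_first(self):
        da = self._da([("A", "c1", 10.0), ("B", "c1", 90.0), ("A", "c2", 10.0), ("B", "c2", 90.0)])
        ora = {"c1": self._ora({"A": 0.01, "B": 0.01}), "c2": self._ora({"A": 0.1, "B": 0.5})}
        out = oc.rank_subpathways(da, ora)
        assert list(out.sub_pathway) == ["A", "B"]
        assert list(out.stars) == [2, 1]

    def test_equal_stars_broken_by_mean_abs_da(self):
        da = self._da([("A", "c1", 40.0), ("B", "c1", -60.0)])
        ora = {"c1": self._ora({"A": 0.01, "B": 0.01})}
        out = oc.rank_subpathways(da, ora)
        assert list(out.sub_pathway) == ["B", "A"]

    def test_full_tie_breaks_alphabetically(self):
        da = self._da([("zeta", "c1", 50.0), ("alpha", "c1", 50.0)])
        ora = {"c1": self._ora({"zeta": 0.5, "alpha": 0.5})}
        assert list(oc.rank_subpathways(da, ora).sub_pathway) == ["alpha", "zeta"]


# ---------------------------------------------------------------------------
# signal-to-noise ranking


def _two_group_matrix(rng, n_features=10, n_per=5, shift=0.0):
    vals = rng.normal(size=(2 * n_per, n_features))
    vals[n_per:, :] += shift
    df = pd.DataFrame(vals, index=[f"s{i}" for i in range(2 * n_per)],
                      columns=[f"f{j}" for j in range(n_features)])
    meta = pd.DataFrame({"group": ["a"] * n_per + ["b"] * n_per}, index=df.index)
    return oc.FeatureMatrix(df, sample_metadata=meta, unit="log2")


class TestSignalToNoise:
    def test_direct_formula_with_sigma_floor(self):
        vals = pd.DataFrame(
            {"f": [1.0, 2.0, 3.0, 0.0, 1.0, 2.0]}, index=[f"s{i}" for i in range(6)]
        )
        meta = pd.DataFrame({"group": ["a"] * 3 + ["b"] * 3}, index=vals.index)
        m = oc.FeatureMatrix(vals, sample_metadata=meta, unit="log2")
        out = oc.signal_to_noise_ranking(m, m.groups(), positive_label="a")
        # μ1=2, μ2=1, σ=1 each (floor inactive) → 0.5
        assert out.metric.iloc[0] == pytest.approx(0.5)

    def test_identical_groups_give_zero(self):
        vals = pd.DataFrame({"f": [1.0, 2.0, 1.0, 2.0]}, index=list("abcd"))
        meta = pd.DataFrame({"group": ["x", "x", "y", "y"]}, index=vals.index)
        m = oc.FeatureMatrix(vals, sample_metadata=meta, unit="log2")
        assert oc.signal_to_noise_ranking(m, m.groups()).metric.iloc[0] == 0.0

    def test_label_swap_negates_and_reverses(self, rng):
        m = _two_group_matrix(rng)
        fwd = oc.signal_to_noise_ranking(m, m.groups(), positive_label="a")
        rev = oc.signal_to_noise_ranking(m, m.groups(), positive_label="b")
        merged = fwd.set_index("feature_id").join(rev.set_index("feature_id"), rsuffix="_r")
        np.testing.assert_allclose(merged.metric, -merged.metric_r, atol=1e-12)
        assert list(fwd.feature_id) == list(rev.feature_id[::-1])

    def test_too_few_samples_errors(self):
        vals = pd.DataFrame({"f": [1.0, 2.0, 3.0]}, index=list("abc"))
        meta = pd.DataFrame({"group": ["x", "x", "y"]}, index=vals.index)
        m = oc.FeatureMatrix(vals, sample_metadata=meta, unit="log2")
        with pytest.raises(ValueError, match="≥2"):
            oc.signal_to_noise_ranking(m, m.groups())


# ---------------------------------------------------------------------------
# GSEA


def brute_force_es(order, metrics, members, weight=1.0):
    """Walk the ranked list step by step and track the running sum extremum."""
    member_set = set(members)
    nr = sum(abs(metrics[f]) ** weight for f in order if f in member_set)
    n_miss = len(order) - len(member_set & set(order))
    running = 0.0
    best = 0.0
    for f in order:
        if f in member_set:
            running += (abs(metrics[f]) ** weight) / nr if nr > 0 else 1.0 / len(member_set)
        else:
            running -= 1.0 / n_miss
        # keep the first-attained extreme on a magnitude tie (within round-off)
        if abs(running) > abs(best) + 1e-12:
            best = running
    return best


def _ranked(metrics):
    items = sorted(metrics.items(), key=lambda kv: (-kv[1], kv[0]))
    return pd.DataFrame({"feature_id": [k for k, _ in items], "metric": [v for _, v in items]})


class TestGsea:
    def test_top_feature_singleton_set_scores_1(self):
        ranked = _ranked({"a": 3.0, "b": 2.0, "c": 1.0})
        out = oc.gsea_enrichment(ranked, oc.MetaboliteSetCollection({"s": ["a"]}),
                                 n_perm=50, min_set=1, seed=0)
        assert out.loc["s", "es"] == pytest.approx(1.0)

    def test_es_matches_brute_force_oracle_on_short_lists(self, rng):
        """Weighted running-sum ES ≡ step-by-step oracle, all subsets, n ≤ 10."""
        from omicscore.enrichment import _enrichment_score

        for trial in range(10):
            n = int(rng.integers(4, 11))
            feats = [f"f{i}" for i in range(n)]
            metrics = {f: float(rng.normal()) for f in feats}
            ranked = _ranked(metrics)
            order = list(ranked.feature_id)
            weights = np.abs(ranked.metric.to_numpy())
            for r in range(1, n):
                for members in itertools.combinations(order, r):
                    hit_pos = np.array(sorted(order.index(m) for m in members))
                    es = _enrichment_score(hit_pos, weights, n)
                    assert es == pytest.approx(
                        brute_force_es(order, metrics, members), abs=1e-12
                    ), (order, members)

    def test_metric_negation_flips_es_sign(self, rng):
        metrics = {f"f{i}": float(rng.normal()) for i in range(12)}
        sets = oc.MetaboliteSetCollection({"s": ["f0", "f3", "f7"]})
        fwd = oc.gsea_enrichment(_ranked(metrics), sets, n_perm=50, seed=0)
        neg = oc.gsea_enrichment(
            _ranked({k: -v for k, v in metrics.items()}), sets, n_perm=50, seed=0
        )
        assert fwd.loc["s", "es"] == pytest.approx(-neg.loc["s", "es"], abs=1e-12)

    def test_p_never_below_estimator_bound(self, rng):
        metrics = {f"f{i}": float(rng.normal()) for i in range(30)}
        sets = oc.MetaboliteSetCollection(
            {f"s{j}": [f"f{i}" for i in rng.choice(30, 5, replace=False)] for j in range(5)}
        )
        out = oc.gsea_enrichment(_ranked(metrics), sets, n_perm=100, seed=1)
        assert (out.p_perm.dropna() >= 1 / 101).all()

    def test_seed_determinism(self, rng):
        metrics = {f"f{i}": float(rng.normal()) for i in range(40)}
        sets = oc.MetaboliteSetCollection({"s": [f"f{i}" for i in range(0, 12, 3)]})
        a = oc.gsea_enrichment(_ranked(metrics), sets, n_perm=200, seed=42)
        b = oc.gsea_enrichment(_ranked(metrics), sets, n_perm=200, seed=42)
        pd.testing.assert_frame_equal(a, b)

    def test_small_sets_skipped_with_reason(self, rng):
        metrics = {f"f{i}": float(rng.normal()) for i in range(10)}
        sets = oc.MetaboliteSetCollection({"tiny": ["f0", "ghost1", "ghost2"]})
        out = oc.gsea_enrichment(_ranked(metrics), sets, n_perm=10, seed=0)
        assert out.loc["tiny", "skipped"] is not None
        assert np.isnan(out.loc["tiny", "es"])

    def test_permutation_p_uniform_under_null(self):
        """Random sets on a null ranking give uniform p (KS p > 0.01, 1000 sets)."""
        rng = np.random.default_rng(2024)
        n_universe = 200
        metrics = {f"f{i}": float(rng.normal()) for i in range(n_universe)}
        sets = {}
        for j in range(1000):
            size = int(rng.integers(5, 16))
            members = rng.choice(n_universe, size=size, replace=False)
            sets[f"null{j}"] = [f"f{i}" for i in members]
        out = oc.gsea_enrichment(
            _ranked(metrics), oc.MetaboliteSetCollection(sets), n_perm=999, seed=9
        )
        ks = stats.kstest(out.p_perm.dropna(), "uniform")
        assert ks.pvalue > 0.01


# ---------------------------------------------------------------------------
# classification network


class TestClassificationNetwork:
    def test_direction_and_size_attributes(self):
        diff = toy_diff_table([("m1", -1.0, 0.01), ("m2", 0.4, 0.2)])
        ann = _annotation({"DG": ["m1", "m2"]})
        net = oc.build_classification_network({"c": diff}, ann, "c")
        assert net.nodes["m1"]["direction_class"] == "down"
        assert net.nodes["m1"]["size"] == pytest.approx(1.0)
        assert net.nodes["m2"]["direction_class"] == "ns"

    def test_counts_two_subpathways_three_metabolites_each(self):
        diff = toy_diff_table([(f"m{i}", 1.0, 0.01) for i in range(6)])
        ann = _annotation({"A": ["m0", "m1", "m2"], "B": ["m3", "m4", "m5"]})
        net = oc.build_classification_network({"c": diff}, ann, "c")
        assert net.number_of_nodes() == 8
        assert net.number_of_edges() == 6
        # every metabolite hangs from exactly one subpathway
        for node, data in net.nodes(data=True):
            if data.get("kind") == "metabolite":
                assert net.in_degree(node) == 1

    def test_missing_comparison_errors(self):
        diff = toy_diff_table([("m1", 1.0, 0.01)])
        ann = _annotation({"A": ["m1"]})
        with pytest.raises(ValueError, match="other"):
            oc.build_classification_network({"c": diff}, ann, "other")


# ---------------------------------------------------------------------------
# planted-effect recovery through the whole subpathway stage


def test_planted_dg_attains_top_combined_rank():
    """DG planted up (effect 2, n=10/group) tops the asterisk ranking in ≥95/100 seeds."""
    wins = 0
    for seed in range(100):
        cfg = oc.SimulationConfig(
            n_samples_per_group=10, n_subpathways=20, metabolites_per_subpathway=5,
            planted_effects={"DG": ("up", 2.0)}, noise_sd=1.0, seed=seed,
        )
        matrix, annotation, _ = oc.simulate_metabolomics(cfg)
        diff = oc.differential_table(matrix, oc.ComparisonDesign("group2", "group1"))
        da = oc.differential_abundance_score(diff, annotation)
        ora = oc.ora_hypergeometric(diff, annotation.as_sets())
        ranked = oc.rank_subpathways(da, {"comparison": ora})
        if ranked.sub_pathway.iloc[0] == "DG":
            wins += 1
    assert wins >= 95
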