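import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mirmint.enrichment import (
    EnrichConfig,
    PrerankedGSEA,
    RankedList,
    enrichment_score,
    nes_and_fdr,
    permutation_null,
    run_preranked,
)
from mirmint.errors import ConfigError
from mirmint.genesets import GeneSet, GeneSetCollection
from tests.oracles import brute_force_es


def ranked(n, rng=None, scores=None):
    ids = [f"g{i:03d}" for i in range(n)]
    if scores is None:
        scores = np.sort(rng.normal(0, 1, n))[::-1]
    return RankedList(np.array(ids, object), np.asarray(scores, float))


class TestEnrichmentScore:
    def test_singleton_at_top_is_plus_one(self):
        rl = ranked(10, scores=np.arange(10, 0, -1, dtype=float))
        for p_w in (0.0, 1.0, 2.0):
            es, _, leading = enrichment_score(rl, ["g000"], p_w)
            assert es == pytest.approx(1.0)
            assert leading == ["g000"]

    def test_singleton_at_bottom_is_minus_one(self):
        rl = ranked(10, scores=np.arange(10, 0, -1, dtype=float))
        es, _, leading = enrichment_score(rl, ["g009"], 1.0)
        assert es == pytest.approx(-1.0)
        assert leading == ["g009"]

    def test_ten_item_exhaustive_oracle(self):
        """3-member set on a 10-item list: every running-sum position
        agrees with the literal brute-force accumulation."""
        scores = np.arange(10, 0, -1, dtype=float)
        rl = ranked(10, scores=scores)
        members = ["g001", "g004", "g008"]
        for p_w in (0.0, 1.0, 1.7):
            es, running, _ = enrichment_score(rl, members, p_w)
            es_bf, running_bf = brute_force_es(
                rl.item_ids, rl.scores, members, p_w
            )
            np.testing.assert_allclose(running, running_bf, atol=1e-12)
            assert es == pytest.approx(es_bf)

    def test_random_sets_match_oracle(self, rng):
        rl = ranked(40, rng)
        for _ in range(20):
            size = int(rng.integers(1, 15))
            members = list(
                rl.item_ids[rng.choice(40, size=size, replace=False)]
            )
            p_w = float(rng.choice([0.0, 0.5, 1.0, 2.0]))
            es, _, _ = enrichment_score(rl, members, p_w)
            es_bf, _ = brute_force_es(rl.item_ids, rl.scores, members, p_w)
            assert es == pytest.approx(es_bf)

    def test_unweighted_reduces_to_classical_ks(self, rng):
        """p_w = 0 equals the two-sample KS statistic between in-set and
        out-of-set rank positions."""
        rl = ranked(60, rng)
        for _ in range(10):
            members = list(
                rl.item_ids[rng.choice(60, size=int(rng.integers(3, 20)),
                                       replace=False)]
            )
            es, _, _ = enrichment_score(rl, members, 0.0)
            hit_pos = rl.positions(members)
            miss_pos = np.setdiff1d(np.arange(60), hit_pos)
            d = stats.ks_2samp(hit_pos, miss_pos).statistic
            assert abs(es) == pytest.approx(d)

    def test_complement_running_sum_is_negated_when_unweighted(self, rng):
        rl = ranked(30, rng)
        members = list(rl.item_ids[:8])
        complement = list(rl.item_ids[8:])
        _, run_a, _ = enrichment_score(rl, members, 0.0)
        _, run_b, _ = enrichment_score(rl, complement, 0.0)
        np.testing.assert_allclose(run_a, -np.asarray(run_b), atol=1e-12)

    def test_scale_invariance(self, rng):
        rl = ranked(50, rng)
        members = list(rl.item_ids[rng.choice(50, 12, replace=False)])
        for p_w in (0.0, 1.0, 2.0):
            es1, _, _ = enrichment_score(rl, members, p_w)
            rl2 = RankedList(rl.item_ids, rl.scores * 37.5)
            es2, _, _ = enrichment_score(rl2, members, p_w)
            assert es1 == pytest.approx(es2)

    def test_full_coverage_and_empty_intersection_rejected(self, rng):
        rl = ranked(5, rng)
        with pytest.raises(ValueError, match="entire"):
            enrichment_score(rl, list(rl.item_ids), 1.0)
        with pytest.raises(ValueError, match="no member"):
            enrichment_score(rl, ["absent"], 1.0)

    def test_leading_edge_within_set_and_list(self, rng):
        rl = ranked(40, rng)
        members = list(rl.item_ids[rng.choice(40, 10, replace=False)])
        es, _, leading = enrichment_score(rl, members, 1.0)
        assert set(leading) <= set(members)
        assert len(leading) >= 1

    def test_matches_gseapy_reference(self):
        """ES agrees with the reference GSEA implementation (gseapy) on a
        small instance."""
        gseapy = pytest.importorskip("gseapy")
        rng = np.random.default_rng(0)
        ids = [f"g{i:02d}" for i in range(40)]
        scores = np.sort(rng.normal(0, 1, 40))[::-1]
        gs = {
            "S1": ids[2:9],
            "S2": ids[25:38],
            "S3": [ids[i] for i in (0, 5, 11, 17, 23, 29, 35)],
        }
        res = gseapy.prerank(
            rnk=pd.DataFrame({"gene": ids, "score": scores}),
            gene_sets=gs, permutation_num=50, min_size=2, max_size=30,
            weight=1.0, seed=1, outdir=None, no_plot=True, threads=1,
        ).res2d.set_index("Term")
        rl = RankedList(np.array(ids, object), scores)
        for name, members in gs.items():
            es, _, _ = enrichment_score(rl, members, 1.0)
            assert es == pytest.approx(float(res.loc[name, "ES"]), abs=1e-9)


class TestPermutationNull:
    def test_same_seed_identical(self, rng):
        rl = ranked(80, rng)
        cfg = EnrichConfig(n_permutations=100, seed=7)
        a = permutation_null(rl, [5, 9], cfg)
        b = permutation_null(rl, [5, 9], cfg)
        for k in a:
            np.testing.assert_array_equal(a[k], b[k])

    def test_symmetric_around_zero_for_constant_scores(self):
        rl = ranked(100, scores=np.ones(100))
        cfg = EnrichConfig(
            n_permutations=400, seed=3, weight_exponent=0.0
        )
        null = permutation_null(rl, [10], cfg)[10]
        se = null.std(ddof=1) / np.sqrt(null.size)
        assert abs(null.mean()) <= 3 * se

    def test_size_n_minus_one_finite(self, rng):
        rl = ranked(20, rng)
        cfg = EnrichConfig(n_permutations=100, seed=1)
        null = permutation_null(rl, [19], cfg)[19]
        assert np.isfinite(null).all()

    def test_config_validation(self):
        with pytest.raises(ConfigError):
            EnrichConfig(n_permutations=10)
        with pytest.raises(ConfigError):
            EnrichConfig(weight_exponent=-1)


class TestNESAndFDR:
    def test_nes_is_one_at_null_mean(self):
        null = {5: np.array([0.4, 0.6, -0.3, -0.5] * 50)}
        obs = pd.DataFrame({"set_name": ["a"], "size": [5], "es": [0.5]})
        cfg = EnrichConfig(n_permutations=200)
        out = nes_and_fdr(obs, null, cfg)
        assert out["nes"].iloc[0] == pytest.approx(1.0)

    def test_p_zero_reported_as_one_over_b_plus_one(self):
        null = {3: np.concatenate([np.full(100, 0.2), np.full(100, -0.2)])}
        obs = pd.DataFrame({"set_name": ["a"], "size": [3], "es": [0.9]})
        cfg = EnrichConfig(n_permutations=200)
        out = nes_and_fdr(obs, null, cfg)
        assert out["p_nominal"].iloc[0] == pytest.approx(1.0 / 201)

    def test_sign_of_nes_matches_es(self, rng):
        rl = ranked(120, rng)
        coll = GeneSetCollection(
            [
                GeneSet(f"S{k}", "",
                        list(rl.item_ids[rng.choice(120, 10, replace=False)]))
                for k in range(15)
            ]
        )
        cfg = EnrichConfig(n_permutations=100, min_size=2, max_size=60,
                           seed=2)
        res = run_preranked(rl, coll, cfg)
        ok = res["nes"].notna() & (res["es"] != 0)
        assert (np.sign(res.loc[ok, "nes"]) == np.sign(res.loc[ok, "es"])).all()

    def test_nominal_p_calibrated_under_null(self):
        """Random sets on random rankings: the nominal-p rate at 0.05
        stays near 0.05 across seeds."""
        fracs = []
        for seed in range(10):
            rng = np.random.default_rng(1000 + seed)
            rl = ranked(200, rng)
            coll = GeneSetCollection(
                [
                    GeneSet(f"S{k}", "",
                            list(rl.item_ids[rng.choice(200, 10,
                                                        replace=False)]))
                    for k in range(50)
                ]
            )
            cfg = EnrichConfig(n_permutations=200, min_size=2,
                               max_size=100, seed=seed)
            res = run_preranked(rl, coll, cfg)
            fracs.append((res["p_nominal"] < 0.05).mean())
        fracs = np.asarray(fracs)
        sem = fracs.std(ddof=1) / np.sqrt(fracs.size)
        assert abs(fracs.mean() - 0.05) <= max(3 * sem, 0.02)


class TestRunPreranked:
    def test_planted_top_decile_set_recovered(self):
        """A set drawn entirely from the top decile is significant at
        q <= 0.25 in >= 9 of 10 seeds."""
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(2000 + seed)
            rl = ranked(200, rng)
            planted = GeneSet(
                "planted", "",
                list(rl.item_ids[rng.choice(20, 15, replace=False)]),
            )
            decoys = [
                GeneSet(f"S{k}", "",
                        list(rl.item_ids[rng.choice(200, 15,
                                                    replace=False)]))
                for k in range(20)
            ]
            coll = GeneSetCollection([planted, *decoys])
            cfg = EnrichConfig(n_permutations=250, min_size=2,
                               max_size=100, seed=seed)
            res = run_preranked(rl, coll, cfg).set_index("set_name")
            row = res.loc["planted"]
            if row["p_nominal"] < 0.05 and row["fdr_q"] <= 0.25:
                hits += 1
        assert hits >= 9

    def test_empty_collection_warns_and_returns_empty(self, rng, caplog):
        rl = ranked(20, rng)
        coll = GeneSetCollection([GeneSet("S", "", ["absent1", "absent2"])])
        cfg = EnrichConfig(n_permutations=100, min_size=1, max_size=10)
        res = run_preranked(rl, coll, cfg)
        assert res.empty

    def test_collection_order_invariance(self, rng):
        rl = ranked(100, rng)
        sets = [
            GeneSet(f"S{k}", "",
                    list(rl.item_ids[rng.choice(100, 10, replace=False)]))
            for k in range(8)
        ]
        cfg = EnrichConfig(n_permutations=100, min_size=2, max_size=50,
                           seed=5)
        a = run_preranked(rl, GeneSetCollection(sets), cfg)
        b = run_preranked(rl, GeneSetCollection(sets[::-1]), cfg)
        a = a.sort_values("set_name").reset_index(drop=True)
        b = b.sort_values("set_name").reset_index(drop=True)
        pd.testing.assert_frame_equal(a, b)

    def test_q_estimates_converge_with_permutations(self, rng):
        rl = ranked(150, rng)
        sets = [
            GeneSet(f"S{k}", "",
                    list(rl.item_ids[rng.choice(150, 12, replace=False)]))
            for k in range(15)
        ]
        coll = GeneSetCollection(sets)
        base = dict(min_size=2, max_size=80, seed=9)
        q1 = run_preranked(
            rl, coll, EnrichConfig(n_permutations=200, **base)
        ).set_index("set_name")["fdr_q"]
        q2 = run_preranked(
            rl, coll, EnrichConfig(n_permutations=400, **base)
        ).set_index("set_name")["fdr_q"]
        med = (q1 - q2).abs().median()
        assert med < 2.0 / np.sqrt(200)

    def test_estimator_wrapper_matches_function(self, rng):
        rl = ranked(80, rng)
        sets = [
            GeneSet(f"S{k}", "",
                    list(rl.item_ids[rng.choice(80, 10, replace=False)]))
            for k in range(5)
        ]
        coll = GeneSetCollection(sets)
        est = PrerankedGSEA(
            gene_sets=coll, n_permutations=100, min_size=2, max_size=40,
            seed=4,
        ).fit(pd.Series(rl.scores, index=rl.item_ids))
        direct = run_preranked(
            rl,
            coll,
            EnrichConfig(n_permutations=100, min_size=2, max_size=40,
                         seed=4),
        )
        pd.testing.assert_frame_equal(est.results_, direct)
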