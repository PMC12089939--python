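import numpy as np
import pandas as pd
import pytest

from drugrank import enrichment as en
from drugrank.geneset_io import GeneSet, GeneSetCollection

from conftest import brute_force_es, brute_force_running_sum


def ranked_frame(n, seed=None, scores=None):
    genes = [f"G{i:04d}" for i in range(n)]
    if scores is None:
        scores = np.sort(np.random.default_rng(seed).uniform(1, 1000, size=n))[::-1]
    return pd.DataFrame({"gene_id": genes, "score": scores})


def collection_of(*sets):
    return GeneSetCollection(
        [GeneSet(f"S{i}", "test", tuple(members)) for i, members in enumerate(sets)]
    )


class TestFilterSets:
    def test_size_bounds_inclusive_five_to_five_hundred(self):
        ranked = ranked_frame(600, seed=0)
        genes = list(ranked.gene_id)
        coll = collection_of(genes[:4], genes[:5], genes[:500], genes[:501])
        kept = en.filter_sets(coll, en.prepare_ranked(ranked))
        assert kept.set_ids() == ["S1", "S2"]

    def test_intersection_before_size_test(self):
        ranked = ranked_frame(50, seed=0)
        members = list(ranked.gene_id[:4]) + [f"X{i}" for i in range(6)]
        kept = en.filter_sets(collection_of(members), en.prepare_ranked(ranked))
        assert len(kept) == 0

    def test_empty_collection_stays_empty(self):
        kept = en.filter_sets(GeneSetCollection(), en.prepare_ranked(ranked_frame(10, seed=0)))
        assert len(kept) == 0


class TestEnrichmentScore:
    def test_single_hit_at_head_weight_zero_gives_one(self):
        ranked = ranked_frame(4, scores=[4.0, 3.0, 2.0, 1.0])
        arr = en.prepare_ranked(ranked, weight_exponent=0.0)
        es, _, edge = en.enrichment_score(arr, ["G0000"])
        assert es == pytest.approx(1.0)
        assert edge == ["G0000"]

    def test_tail_pair_weight_zero_gives_minus_one(self):
        # four leading misses drive the running sum to -1 before any hit
        ranked = ranked_frame(6, scores=[6.0, 5, 4, 3, 2, 1])
        arr = en.prepare_ranked(ranked, weight_exponent=0.0)
        es, _, edge = en.enrichment_score(arr, ["G0004", "G0005"])
        assert es == pytest.approx(-1.0)
        assert set(edge) == {"G0004", "G0005"}

    def test_disjoint_set_rejected(self):
        arr = en.prepare_ranked(ranked_frame(10, seed=1))
        with pytest.raises(ValueError, match="disjoint"):
            en.enrichment_score(arr, ["NOT_A_GENE"])

    @pytest.mark.parametrize("weight", [0.0, 1.0])
    def test_matches_brute_force_oracle(self, weight):
        # 200 random instances per weight; magnitudes to 1e-12, signs
        # asserted whenever the profile extrema are not an exact tie
        rng = np.random.default_rng(20_240_101)
        for _ in range(200):
            n = int(rng.integers(5, 51))
            ranked = ranked_frame(n, scores=np.sort(rng.normal(size=n) * 10)[::-1])
            k = int(rng.integers(1, min(11, n)))
            members = list(rng.choice(ranked.gene_id, size=k, replace=False))
            arr = en.prepare_ranked(ranked, weight_exponent=weight)
            es, _, _ = en.enrichment_score(arr, members)
            mask = np.isin(arr.genes.astype(str), members)
            profile = brute_force_running_sum(arr.scores, mask, weight)
            expected = profile[np.argmax(np.abs(profile))]
            assert abs(abs(es) - abs(expected)) < 1e-12
            if abs(profile.max() - abs(profile.min())) > 1e-9:
                assert np.sign(es) == np.sign(expected)
            # fast positions-only path agrees with the full profile
            pos = np.sort([arr.index[g] for g in members])
            fast = en._es_from_positions(arr.weights, pos[None, :], n)[0]
            assert abs(abs(fast) - abs(expected)) < 1e-12

    def test_weight_zero_is_ks_sup_statistic(self):
        # with p=0 the ES is the sup difference between the hit and miss
        # empirical CDFs along the list
        rng = np.random.default_rng(7)
        for _ in range(20):
            n = int(rng.integers(10, 80))
            ranked = ranked_frame(n, scores=np.sort(rng.uniform(size=n))[::-1])
            k = int(rng.integers(2, min(12, n)))
            members = list(rng.choice(ranked.gene_id, size=k, replace=False))
            arr = en.prepare_ranked(ranked, weight_exponent=0.0)
            es, _, _ = en.enrichment_score(arr, members)
            mask = np.isin(arr.genes.astype(str), members)
            hit_cdf = np.cumsum(mask) / k
            miss_cdf = np.cumsum(~mask) / (n - k)
            diff = hit_cdf - miss_cdf
            assert abs(es) == pytest.approx(np.max(np.abs(diff)), abs=1e-12)

    def test_es_always_within_unit_interval(self):
        rng = np.random.default_rng(99)
        for _ in range(50):
            n = int(rng.integers(5, 60))
            ranked = ranked_frame(n, scores=rng.uniform(0.5, 100, size=n))
            k = int(rng.integers(1, n))
            members = list(rng.choice(ranked.gene_id, size=k, replace=False))
            arr = en.prepare_ranked(ranked)
            es, _, _ = en.enrichment_score(arr, members)
            assert -1.0 <= es <= 1.0

    def test_matches_gseapy_reference_implementation(self):
        # independent cross-check against the GSEA reference used in the field
        gp = pytest.importorskip("gseapy")
        rng = np.random.default_rng(3)
        n = 200
        ranked = ranked_frame(n, scores=np.sort(rng.uniform(1, 100, size=n))[::-1])
        sets = {
            f"S{j}": list(rng.choice(ranked.gene_id, size=15, replace=False))
            for j in range(5)
        }
        res = gp.prerank(
            rnk=ranked.rename(columns={"gene_id": 0, "score": 1}),
            gene_sets=sets,
            permutation_num=4,
            min_size=5,
            max_size=500,
            weight=1.0,
            seed=1,
            threads=1,
            outdir=None,
            no_plot=True,
        ).res2d
        arr = en.prepare_ranked(ranked)
        for name, members in sets.items():
            es, _, _ = en.enrichment_score(arr, members)
            reference = float(res.loc[res.Term == name, "ES"].iloc[0])
            assert es == pytest.approx(reference, abs=1e-9)


class TestPermutationNull:
    def test_seed_determinism(self):
        arr = en.prepare_ranked(ranked_frame(100, seed=0))
        a = en.permutation_null(arr, [10], n_perm=50, seed=7)
        b = en.permutation_null(arr, [10], n_perm=50, seed=7)
        np.testing.assert_array_equal(a[10], b[10])

    def test_seed_required(self):
        arr = en.prepare_ranked(ranked_frame(20, seed=0))
        with pytest.raises(ValueError, match="seed"):
            en.permutation_null(arr, [5], n_perm=10)

    def test_set_size_exceeding_universe_rejected(self):
        arr = en.prepare_ranked(ranked_frame(10, seed=0))
        with pytest.raises(ValueError, match="universe"):
            en.permutation_null(arr, [10], n_perm=10, seed=1)

    def test_singleton_null_matches_position_enumeration(self):
        # |S|=1, weight 0: the ES is a deterministic function of the single
        # hit position, enumerable in closed form over all positions
        n = 21
        ranked = ranked_frame(n, scores=np.arange(n, 0, -1.0))
        arr = en.prepare_ranked(ranked, weight_exponent=0.0)
        d = 1.0 / (n - 1)
        def es_at(j):
            up, down = 1.0 - j * d, -j * d
            return up if abs(up) > abs(down) else down
        enumerated = {round(es_at(j), 12) for j in range(n)}
        null = en.permutation_null(arr, [1], n_perm=500, seed=3)[1]
        assert {round(v, 12) for v in null} <= enumerated
        exact_mean = np.mean([es_at(j) for j in range(n)])
        assert null.mean() == pytest.approx(exact_mean, abs=0.08)


def oracle_normalize_and_test(es_obs, sizes, null, n_perm):
    """Plain-loop reimplementation of NES/p/FDR/FWER used as the oracle."""
    ids = list(es_obs)
    nes = {}
    null_nes = {}
    for sid in ids:
        arr = null[sizes[sid]]
        pos = arr[arr > 0]
        neg = arr[arr < 0]
        pm = pos.mean() if len(pos) else np.nan
        nm = np.abs(neg).mean() if len(neg) else np.nan
        e = es_obs[sid]
        nes[sid] = e / pm if e >= 0 else e / nm
        nn = np.where(arr >= 0, arr / pm, arr / nm)
        null_nes[sid] = nn
    pooled = np.concatenate([null_nes[s] for s in ids])
    obs = np.array([nes[s] for s in ids])
    out = {}
    for sid in ids:
        e, v = es_obs[sid], nes[sid]
        arr = null[sizes[sid]]
        if e >= 0:
            same = arr[arr > 0]
            exceed = (same >= e).sum()
            p = exceed / max(len(same), 1) if exceed else 1 / (2 * n_perm)
            num = (pooled[pooled > 0] >= v).mean()
            den = (obs[obs > 0] >= v).mean()
            permmax = np.max(
                np.vstack([np.where(null_nes[s] > 0, null_nes[s], -np.inf) for s in ids]),
                axis=0,
            )
            fwer = (permmax >= v).mean()
        else:
            same = arr[arr < 0]
            exceed = (same <= e).sum()
            p = exceed / max(len(same), 1) if exceed else 1 / (2 * n_perm)
            num = (pooled[pooled < 0] <= v).mean()
            den = (obs[obs < 0] <= v).mean()
            permmin = np.min(
                np.vstack([np.where(null_nes[s] < 0, null_nes[s], np.inf) for s in ids]),
                axis=0,
            )
            fwer = (permmin <= v).mean()
        out[sid] = dict(
            nes=v,
            p=p,
            fdr_q=min(1.0, num / den),
            fwer_p=fwer,
            fwer_bonferroni=min(1.0, p * len(ids)),
        )
    return out


class TestNormalizeAndTest:
    def test_nes_is_ratio_to_same_sign_null_mean(self):
        null = {5: np.array([0.1, 0.1, 0.1, -0.2, -0.2])}
        res = en.normalize_and_test({"S": 0.2}, {"S": 5}, null, n_perm=5)
        assert res.nes.iloc[0] == pytest.approx(2.0)
        res_neg = en.normalize_and_test({"S": -0.4}, {"S": 5}, null, n_perm=5)
        assert res_neg.nes.iloc[0] == pytest.approx(-2.0)

    def test_most_extreme_observed_set_has_zero_fdr(self):
        rng = np.random.default_rng(0)
        null = {5: rng.normal(scale=0.1, size=200)}
        res = en.normalize_and_test(
            {"A": -0.9, "B": -0.05}, {"A": 5, "B": 5}, null, n_perm=200
        )
        assert res.set_id.iloc[0] in ("A", "B")
        assert res.loc[res.set_id == "A", "fdr_q"].iloc[0] == 0.0
        assert res.loc[res.set_id == "A", "p_below_floor"].iloc[0]

    def test_small_instance_matches_brute_force_oracle(self):
        rng = np.random.default_rng(42)
        null = {4: rng.normal(scale=0.2, size=50), 7: rng.normal(scale=0.15, size=50)}
        es_obs = {"A": 0.35, "B": -0.28, "C": 0.05}
        sizes = {"A": 4, "B": 7, "C": 7}
        res = en.normalize_and_test(es_obs, sizes, null, n_perm=50).set_index("set_id")
        expected = oracle_normalize_and_test(es_obs, sizes, null, 50)
        for sid, exp in expected.items():
            for key, val in exp.items():
                assert res.loc[sid, key] == pytest.approx(val, abs=1e-12), (sid, key)

    def test_empty_null_rejected(self):
        with pytest.raises(ValueError, match="null"):
            en.normalize_and_test({"S": 0.5}, {"S": 5}, {5: np.array([])}, n_perm=0)

    def test_p_and_q_within_unit_interval(self):
        rng = np.random.default_rng(8)
        null = {6: rng.normal(scale=0.2, size=300)}
        es_obs = {f"S{i}": float(rng.uniform(-0.8, 0.8)) for i in range(10)}
        res = en.normalize_and_test(es_obs, {s: 6 for s in es_obs}, null, 300)
        assert ((res.fdr_q >= 0) & (res.fdr_q <= 1)).all()
        assert ((res.fwer_p >= 0) & (res.fwer_p <= 1)).all()
        assert ((res.p > 0) & (res.p <= 1)).all()


class TestRunEnrichment:
    def planted_inputs(self, n=400, k=12):
        # scores are median-rank-like values: best genes have score near 1
        # and sit at the BOTTOM of the descending-sorted list
        ranked = ranked_frame(n, scores=np.arange(n, 0, -1.0))
        best = list(ranked.gene_id.iloc[-k:])  # rank values closest to 1
        worst = list(ranked.gene_id.iloc[:k])
        rng = np.random.default_rng(5)
        random_sets = [
            list(rng.choice(ranked.gene_id, size=k, replace=False)) for _ in range(6)
        ]
        coll = GeneSetCollection(
            [GeneSet("planted", "best ranks", tuple(best)),
             GeneSet("worst", "worst ranks", tuple(worst))]
            + [GeneSet(f"null{i}", "random", tuple(s)) for i, s in enumerate(random_sets)]
        )
        return ranked, coll

    def test_planted_best_rank_set_has_negative_es(self):
        ranked, coll = self.planted_inputs()
        res = en.run_enrichment(ranked, coll, n_perm=200, seed=11)
        planted = res[res.set_id == "planted"].iloc[0]
        assert planted.es < 0 and planted.nes < 0
        assert planted.fdr_q < 0.05
        worst = res[res.set_id == "worst"].iloc[0]
        assert worst.es > 0

    def test_same_seed_gives_byte_identical_output(self):
        ranked, coll = self.planted_inputs()
        a = en.run_enrichment(ranked, coll, n_perm=100, seed=3).to_csv()
        b = en.run_enrichment(ranked, coll, n_perm=100, seed=3).to_csv()
        assert a == b

    def test_row_order_of_input_is_irrelevant(self):
        ranked, coll = self.planted_inputs()
        shuffled = ranked.sample(frac=1.0, random_state=1).reset_index(drop=True)
        a = en.run_enrichment(ranked, coll, n_perm=50, seed=3).to_csv()
        b = en.run_enrichment(shuffled, coll, n_perm=50, seed=3).to_csv()
        assert a == b

    def test_no_surviving_sets_warns_and_returns_empty(self):
        ranked = ranked_frame(30, seed=0)
        coll = collection_of(list(ranked.gene_id[:3]))  # below min size
        with pytest.warns(UserWarning, match="size filter"):
            res = en.run_enrichment(ranked, coll, n_perm=10, seed=1)
        assert len(res) == 0

    def test_empirical_p_floor_is_flagged(self):
        ranked, coll = self.planted_inputs()
        res = en.run_enrichment(ranked, coll, n_perm=200, seed=11)
        planted = res[res.set_id == "planted"].iloc[0]
        assert planted.p_below_floor
        assert planted.p == pytest.approx(1 / 400)

    def test_tier_labels(self):
        assert en.assign_tier(0.01, 0.01) == "strong"
        assert en.assign_tier(0.01, 0.2) == "moderate"
        assert en.assign_tier(0.2, 0.01) == "moderate"
        assert en.assign_tier(0.2, 0.2) == ""


class TestCompareNesVectors:
    def results(self, ids, nes):
        return pd.DataFrame({"set_id": ids, "nes": nes})

    def test_identical_vectors_give_tau_one(self):
        a = self.results(list("ABCDE"), [1.0, 2.0, -1.0, 0.5, 3.0])
        tau, _ = en.compare_nes_vectors(a, a)
        assert tau == pytest.approx(1.0)

    def test_reversed_order_gives_tau_minus_one(self):
        a = self.results(list("ABCD"), [1.0, 2.0, 3.0, 4.0])
        b = self.results(list("ABCD"), [4.0, 3.0, 2.0, 1.0])
        tau, _ = en.compare_nes_vectors(a, b)
        assert tau == pytest.approx(-1.0)

    def test_too_few_shared_sets_rejected(self):
        a = self.results(["A", "B"], [1.0, 2.0])
        with pytest.raises(ValueError, match="shared"):
            en.compare_nes_vectors(a, a)

    def test_tau_b_matches_pairwise_enumeration_under_ties(self):
        rng = np.random.default_rng(17)
        x = rng.integers(0, 4, size=30).astype(float)  # heavy ties
        y = rng.integers(0, 4, size=30).astype(float)
        ids = [f"S{i}" for i in range(30)]
        tau, _ = en.compare_nes_vectors(self.results(ids, x), self.results(ids, y))
        conc = disc = tx = ty = 0
        for i in range(30):
            for j in range(i + 1, 30):
                a, b = x[i] - x[j], y[i] - y[j]
                if a == 0 and b == 0:
                    continue
                if a == 0:
                    tx += 1
                elif b == 0:
                    ty += 1
                elif np.sign(a) == np.sign(b):
                    conc += 1
                else:
                    disc += 1
        expected = (conc - disc) / np.sqrt((conc + disc + tx) * (conc + disc + ty))
        assert tau == pytest.approx(expected, abs=1e-12)
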