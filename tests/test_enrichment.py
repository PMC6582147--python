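"""Causal-category probabilities, enrichment ratios, bootstrap, priors."""

import numpy as np
import pandas as pd
import pytest

from finemapkit import enrichment as en


Q2 = pd.Series({"coding": 0.1, "noncoding": 0.9})


def _simulate_signals(n_signals, p_causal_coding, rng, set_size=15, ppc_top=0.8):
    """Signals with a concentrated PPC on a causal variant whose category is
    drawn from p; the other variants' categories come from the background."""
    ppcs, cats = [], []
    for _ in range(n_signals):
        causal = "coding" if rng.random() < p_causal_coding else "noncoding"
        other = list(rng.choice(Q2.index, p=Q2.to_numpy(), size=set_size - 1))
        rest = rng.dirichlet(np.ones(set_size - 1))
        ppcs.append(np.concatenate([[ppc_top], (1 - ppc_top) * rest]))
        cats.append([causal] + other)
    return ppcs, cats


class TestEstimateQc:
    def test_two_way_split(self):
        ann = en.AnnotationMap(
            "s", pd.Series(["a"] * 30 + ["b"] * 70, index=[f"v{i}" for i in range(100)])
        )
        q = en.estimate_qc(ann)
        assert q["a"] == pytest.approx(0.3) and q["b"] == pytest.approx(0.7)

    def test_single_category(self):
        ann = en.AnnotationMap("s", pd.Series(["x"] * 5, index=list("abcde")))
        assert en.estimate_qc(ann)["x"] == 1.0

    def test_counts_1_1_2(self):
        ann = en.AnnotationMap(
            "s", pd.Series(["a", "b", "c", "c"], index=list("wxyz"))
        )
        q = en.estimate_qc(ann)
        assert list(q[["a", "b", "c"]]) == [0.25, 0.25, 0.5]


class TestEstimatePc:
    def test_single_category_forced_to_one(self, rng):
        q = pd.Series({"only": 1.0})
        ppcs = [rng.dirichlet(np.ones(5)) for _ in range(8)]
        cats = [["only"] * 5] * 8
        p = en.estimate_pc(ppcs, cats, q)
        assert p["only"] == pytest.approx(1.0)

    def test_all_mass_in_one_category(self, rng):
        ppcs, cats = [], []
        for _ in range(10):
            ppcs.append(np.array([0.7, 0.3, 0.0]))
            cats.append(["a", "a", "b"])
        p = en.estimate_pc(ppcs, cats, pd.Series({"a": 0.2, "b": 0.8}))
        assert p["a"] == pytest.approx(1.0, abs=1e-6)

    def test_matches_grid_search_oracle(self):
        # 3 signals, 2 categories: maximise the mixture likelihood on a grid
        ppcs = [np.array([0.5, 0.5]), np.array([0.9, 0.1]), np.array([0.2, 0.8])]
        cats = [["a", "b"], ["a", "b"], ["b", "a"]]
        q = pd.Series({"a": 0.3, "b": 0.7})
        p_hat = en.estimate_pc(ppcs, cats, q)

        def loglik(pa):
            p = {"a": pa, "b": 1 - pa}
            total = 0.0
            for ppc, cc in zip(ppcs, cats):
                total += np.log(sum(v * p[c] / q[c] for v, c in zip(ppc, cc)))
            return total

        grid = np.linspace(1e-6, 1 - 1e-6, 20001)
        best = grid[np.argmax([loglik(g) for g in grid])]
        assert p_hat["a"] == pytest.approx(best, abs=1e-4)

    def test_em_simplex_and_monotone_loglik(self, rng):
        ppcs, cats = _simulate_signals(40, 0.5, rng)
        P, C = en._pad_signals(ppcs, cats, list(Q2.index))
        q = Q2.to_numpy()
        lls = []
        p = np.tile(q, (1, 1)) / q.sum()
        # replicate the EM loop step by step to watch the likelihood
        for _ in range(50):
            Csafe = np.where(C >= 0, C, 0)
            valid = C >= 0
            q_at = np.where(valid, q[Csafe], 1.0)
            lift = p[:, Csafe] / q_at[None, :, :]
            w = P[None] * np.where(valid[None], lift, 0.0)
            norm = w.sum(axis=2, keepdims=True)
            lls.append(np.log(norm[..., 0]).sum())
            r = w / np.where(norm > 0, norm, 1.0)
            K = len(q)
            newp = np.stack(
                [(r * (valid & (Csafe == k))[None]).sum(axis=(1, 2)) for k in range(K)],
                axis=1,
            ) / P.shape[0]
            p = newp
            assert np.all(p >= -1e-12)
            assert p.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(np.diff(lls) > -1e-9)

    def test_recovers_planted_probabilities(self):
        from finemapkit.synthetic import simulate_enrichment_signals

        ppcs, cats, truth = simulate_enrichment_signals(250, seed=2)
        p = en.estimate_pc(ppcs, cats, Q2)
        assert p["coding"] == pytest.approx(truth["p"]["coding"], abs=0.07)

    def test_empty_signal_list_rejected(self):
        with pytest.raises(ValueError):
            en.estimate_pc([], [], Q2)


class TestEnrichmentRatio:
    def test_background_is_one(self):
        q = pd.Series({"a": 0.4, "b": 0.6})
        assert (en.enrichment_ratio(q, q) == 1.0).all()

    def test_fivefold(self):
        e = en.enrichment_ratio(pd.Series({"a": 0.5}), pd.Series({"a": 0.1}))
        assert e["a"] == pytest.approx(5.0)

    def test_zero_is_depletion_and_q_zero_undefined(self):
        e = en.enrichment_ratio(
            pd.Series({"a": 0.0, "b": 1.0}), pd.Series({"a": 0.5, "b": 0.0})
        )
        assert e["a"] == 0.0 and np.isnan(e["b"])


class TestBootstrapCi:
    def test_degenerate_mass_collapses_interval(self, rng):
        ppcs = [np.array([1.0])] * 12
        cats = [["a"]] * 12
        q = pd.Series({"a": 0.5, "b": 0.5})
        model = en.bootstrap_ci(ppcs, cats, q, n_boot=50, rng=rng)
        assert model.ci.loc["a", "low"] == pytest.approx(model.ci.loc["a", "high"])
        assert model.p_c["a"] == pytest.approx(1.0)

    def test_single_resample_interval_is_point(self, rng):
        ppcs, cats = _simulate_signals(30, 0.5, rng)
        model = en.bootstrap_ci(ppcs, cats, Q2, n_boot=1, rng=np.random.default_rng(0))
        assert model.ci["low"].equals(model.ci["high"])

    def test_equivariant_under_relabeling(self, rng):
        ppcs, cats = _simulate_signals(40, 0.5, rng)
        m1 = en.bootstrap_ci(ppcs, cats, Q2, n_boot=100, rng=np.random.default_rng(3))
        swap = {"coding": "noncoding", "noncoding": "coding"}
        cats2 = [[swap[c] for c in cc] for cc in cats]
        q2 = pd.Series({"coding": 0.9, "noncoding": 0.1})
        m2 = en.bootstrap_ci(ppcs, cats2, q2, n_boot=100, rng=np.random.default_rng(3))
        assert m1.p_c["coding"] == pytest.approx(m2.p_c["noncoding"], abs=1e-9)
        assert m1.ci.loc["coding", "low"] == pytest.approx(
            m2.ci.loc["noncoding", "low"], abs=1e-9
        )

    def test_small_empty_category_dropped(self, rng):
        ppcs, cats = _simulate_signals(30, 0.5, rng)
        q3 = pd.Series({"coding": 0.095, "noncoding": 0.9, "rare": 0.005})
        model = en.bootstrap_ci(ppcs, cats, q3, n_boot=20, rng=rng)
        assert "rare" not in model.p_c.index


class TestMakePriors:
    def test_uniform_categories_give_uniform_prior(self):
        p = pd.Series({"a": 0.5, "b": 0.5})
        q = pd.Series({"a": 0.5, "b": 0.5})
        np.testing.assert_allclose(
            en.make_priors(p, q, ["a", "b", "a"]), np.full(3, 1 / 3)
        )

    def test_ratio_normalisation(self):
        # p/q per category = (5, 0.5) -> prior (10/11, 1/11)
        p = pd.Series({"a": 0.5, "b": 0.45})
        q = pd.Series({"a": 0.1, "b": 0.9})
        np.testing.assert_allclose(
            en.make_priors(p, q, ["a", "b"]), [10 / 11, 1 / 11]
        )

    def test_q_zero_rejected(self):
        p = pd.Series({"a": 1.0, "b": 0.0})
        q = pd.Series({"a": 1.0, "b": 0.0})
        with pytest.raises(ValueError):
            en.make_priors(p, q, ["a", "b"])

    def test_update_matches_em_responsibility_step(self, rng):
        ppcs, cats = _simulate_signals(25, 0.6, rng)
        p_hat = en.estimate_pc(ppcs, cats, Q2)
        P, C = en._pad_signals(ppcs, cats, list(Q2.index))
        # one responsibility step at p_hat
        q = Q2.to_numpy()
        Csafe = np.where(C >= 0, C, 0)
        valid = C >= 0
        lift = p_hat.to_numpy()[Csafe] / np.where(valid, q[Csafe], 1.0)
        w = P * np.where(valid, lift, 0.0)
        resp = w / w.sum(axis=1, keepdims=True)
        for i in (0, 7, 19):
            prior = en.make_priors(p_hat, Q2, cats[i])
            updated = en.update_ppc(
                pd.Series(ppcs[i], index=range(len(ppcs[i]))), prior
            )
            np.testing.assert_allclose(
                updated.to_numpy(), resp[i, : len(ppcs[i])], atol=1e-12
            )


class TestRatioPermutationTest:
    def test_identical_groups_not_significant(self, rng):
        ppcs, cats = _simulate_signals(60, 0.5, rng)
        res = en.ratio_permutation_test(
            (ppcs[:30], cats[:30]), (ppcs[30:], cats[30:]), Q2, "coding",
            n_perm=200, rng=rng,
        )
        assert res["p_value"] > 0.05

    def test_planted_difference_detected(self):
        hits = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            ppcs_a, cats_a = _simulate_signals(100, 0.65, rng)
            ppcs_b, cats_b = _simulate_signals(100, 0.1, rng)
            res = en.ratio_permutation_test(
                (ppcs_a, cats_a), (ppcs_b, cats_b), Q2, "coding",
                n_perm=150, rng=rng,
            )
            hits += res["p_value"] < 0.05
        assert hits >= 9

    def test_zero_permutations_rejected(self, rng):
        ppcs, cats = _simulate_signals(10, 0.5, rng)
        with pytest.raises(ValueError):
            en.ratio_permutation_test((ppcs, cats), (ppcs, cats), Q2, "coding", n_perm=0)


class TestGeneLocationClasses:
    def test_five_way_classification(self):
        features = pd.DataFrame(
            [
                {"chrom": "1", "type": "gene", "start": 10_000, "end": 30_000,
                 "strand": "+", "attributes": "ID=g1;Name=G1"},
                {"chrom": "1", "type": "five_prime_UTR", "start": 10_000, "end": 10_499,
                 "strand": "+", "attributes": "Parent=g1"},
                {"chrom": "1", "type": "CDS", "start": 10_500, "end": 12_000,
                 "strand": "+", "attributes": "Parent=g1"},
                {"chrom": "1", "type": "exon", "start": 10_000, "end": 12_000,
                 "strand": "+", "attributes": "Parent=g1"},
                {"chrom": "1", "type": "exon", "start": 20_000, "end": 30_000,
                 "strand": "+", "attributes": "Parent=g1"},
                {"chrom": "1", "type": "three_prime_UTR", "start": 29_000, "end": 30_000,
                 "strand": "+", "attributes": "Parent=g1"},
            ]
        )
        variants = pd.DataFrame(
            {
                "id": ["a", "b", "c", "d", "e", "f"],
                "chrom": "1",
                "pos": [11_000, 10_200, 15_000, 29_500, 9_000, 500_000],
                "ref": "A", "alt": "C", "maf": 0.3,
            }
        )
        ann = en.gene_location_classes(variants, features)
        assert ann.categories["a"] == "CDS"
        assert ann.categories["b"] == "UTR5_upstream"
        assert ann.categories["c"] == "intron"
        assert ann.categories["d"] == "UTR3_downstream"
        assert ann.categories["e"] == "UTR5_upstream"  # within 2 kb upstream
        assert ann.categories["f"] == "other"


class TestAnnotationMap:
    def test_cross_product_scheme(self):
        a = en.AnnotationMap("impact", pd.Series({"v1": "MODERATE", "v2": "LOW"}))
        b = en.AnnotationMap("gerp", pd.Series({"v1": "in", "v2": "out"}))
        cross = a.cross(b)
        assert cross.categories["v1"] == "MODERATE&in"
        assert cross.scheme == "impactxgerp"

    def test_duplicate_variant_rejected(self):
        with pytest.raises(ValueError):
            en.AnnotationMap(
                "s", pd.Series(["a", "b"], index=["v1", "v1"])
            )
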