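"""Locus construction, forward selection, repositioning, PPC, credible sets."""

import numpy as np
import pandas as pd
import pytest

from finemapkit import finemap as fm
from finemapkit.finemap import LocusModel
from finemapkit.io import GenotypeSet
from finemapkit.model_core import ModelSpec, reliability_to_weight
from finemapkit.synthetic import SimulationConfig, simulate_dataset


def _genotypes(dosages, positions, chrom="1"):
    dosages = np.asarray(dosages, dtype=float)
    variants = pd.DataFrame(
        {
            "id": [f"{chrom}:{p}:A:C" for p in positions],
            "chrom": chrom,
            "pos": list(positions),
            "ref": "A",
            "alt": "C",
            "maf": np.nan,
        }
    )
    return GenotypeSet(
        variants, dosages, [f"i{j}" for j in range(dosages.shape[1])]
    )


def _spec(n, **kw):
    return ModelSpec(covariates=np.ones((n, 1)), **kw)


def _sim_locus(seed, n=2000, m=300, effect=0.165, **kw):
    cfg = SimulationConfig(
        seed=seed, n_individuals=n, n_variants=m, h2_polygenic=0.0,
        causal_effect_sd=effect, n_causal_per_locus=1 if effect else 0, **kw
    )
    ds = simulate_dataset(cfg)
    ids, y, r2 = ds.panel.observed("trait1")
    spec = _spec(len(y), residual_weights=reliability_to_weight(r2))
    locus = fm.build_locus([(cfg.chrom, 1000)], ds.genotypes, trait="trait1")
    return ds, locus, y, spec


class TestBuildLocus:
    def test_single_lead_flanked(self, rng):
        pos = np.arange(3_900_000, 6_100_000, 10_000)
        dos = rng.binomial(2, 0.3, (len(pos), 20)).astype(float)
        gs = _genotypes(dos, pos)
        locus = fm.build_locus([("1", 5_000_000)], gs)
        assert (locus.region.start, locus.region.end) == (4_000_000, 6_000_000)

    def test_two_leads_span_at_least_2mb(self, rng):
        pos = np.arange(2_900_000, 5_500_000, 25_000)
        gs = _genotypes(rng.binomial(2, 0.3, (len(pos), 20)).astype(float), pos)
        locus = fm.build_locus([("1", 4_000_000), ("1", 4_400_000)], gs)
        assert (locus.region.start, locus.region.end) == (3_000_000, 5_400_000)
        assert locus.region.end - locus.region.start >= 2_000_000

    def test_clipped_at_chromosome_start(self, rng):
        pos = np.arange(10_000, 1_400_000, 10_000)
        gs = _genotypes(rng.binomial(2, 0.3, (len(pos), 20)).astype(float), pos)
        locus = fm.build_locus([("1", 300_000)], gs)
        assert locus.region.start == 1

    def test_empty_locus_error(self, rng):
        gs = _genotypes(rng.binomial(2, 0.3, (5, 20)).astype(float), [10, 20, 30, 40, 50])
        with pytest.raises(fm.EmptyLocusError):
            fm.build_locus([("1", 50_000_000)], gs)


class TestEffectiveTests:
    def test_independent_variants(self, rng):
        dos = rng.binomial(2, 0.4, (6, 4000)).astype(float)
        assert fm.effective_tests(dos) == pytest.approx(6.0, abs=0.2)

    def test_perfect_pair_counts_once(self, rng):
        v = rng.binomial(2, 0.4, 500).astype(float)
        m_eff = fm.effective_tests(np.vstack([v, v]))
        # eigenvalues (2, 0): 1 + 0 contributions
        assert m_eff == pytest.approx(1.0)

    def test_pair_plus_independent(self, rng):
        v = rng.binomial(2, 0.4, 20000).astype(float)
        w = rng.binomial(2, 0.3, 20000).astype(float)
        m_eff = fm.effective_tests(np.vstack([v, v, w]))
        assert m_eff == pytest.approx(2.0, abs=0.05)

    @pytest.mark.parametrize("seed", [0, 1])
    def test_matches_eigenvalue_oracle(self, seed):
        rng = np.random.default_rng(seed)
        dos = rng.binomial(2, rng.uniform(0.1, 0.5, 15)[:, None], (15, 300)).astype(float)
        evals = np.clip(np.linalg.eigvalsh(np.corrcoef(dos)), 0, None)
        oracle = float(np.sum((evals >= 1) + (evals - np.floor(evals))))
        assert fm.effective_tests(dos) == pytest.approx(oracle, rel=1e-12)


class TestForwardSelect:
    def test_recovers_single_planted_causal(self):
        hits = 0
        for seed in range(15):
            ds, locus, y, spec = _sim_locus(seed, n=2000, m=120, effect=0.25, ld_rho=0.0)
            leads = fm.forward_select(locus, y, spec)
            hits += leads == ds.truth["causal_ids"]
        assert hits >= 14  # >= 95% of replicates at high power, no LD partners

    def test_pure_noise_selects_nothing(self):
        clean = 0
        for seed in range(20):
            ds, locus, y, spec = _sim_locus(seed + 100, n=1000, m=200, effect=0.0)
            clean += not fm.forward_select(locus, y, spec)
        assert clean >= 19

    def test_two_causals_on_separate_blocks(self):
        found_two = 0
        for seed in range(10):
            cfg = SimulationConfig(
                seed=seed + 50, n_individuals=2000, n_variants=100,
                block_length=50, ld_rho=0.9, h2_polygenic=0.0,
                causal_effect_sd=0.35, n_causal_per_locus=1, n_loci=2,
            )
            ds = simulate_dataset(cfg)
            ids, y, r2 = ds.panel.observed("trait1")
            spec = _spec(len(y), residual_weights=reliability_to_weight(r2))
            locus = fm.build_locus([(cfg.chrom, 1000)], ds.genotypes, trait="trait1")
            leads = fm.forward_select(locus, y, spec)
            blocks = {ds.genotypes.variants.set_index("id")["pos"][l] // 50001 for l in leads}
            found_two += len(leads) == 2 and len(blocks) == 2
        assert found_two >= 8

    def test_monotone_stopping_in_m_eff(self):
        ds, locus, y, spec = _sim_locus(7, n=1500, m=150, effect=0.2)
        model = fm.LocusModel(y, locus.genotypes, spec)
        paths = [
            fm.forward_select(locus, y, spec, m_eff=m_eff, model=model)
            for m_eff in (2.0, 50.0, 5000.0)
        ]
        for shorter, longer in zip(paths[1:], paths[:-1]):
            assert shorter == longer[: len(shorter)]


class TestReposition:
    def test_fixed_point_unchanged(self):
        ds, locus, y, spec = _sim_locus(3, effect=0.3)
        leads = fm.forward_select(locus, y, spec)
        assert leads
        repositioned = fm.reposition(leads, locus, y, spec)
        again = fm.reposition(repositioned, locus, y, spec)
        assert again == repositioned

    def test_single_signal_global_argmax(self):
        ds, locus, y, spec = _sim_locus(4, effect=0.3)
        leads = fm.forward_select(locus, y, spec, max_signals=1)
        new = fm.reposition(leads, locus, y, spec)
        model = fm.LocusModel(y, locus.genotypes, spec)
        _, lbf = model.conditional_log_bf([])
        best = model.ids[int(np.argmax(lbf))]
        assert new == [best]

    def test_masked_causal_recovered_by_enumeration(self, rng):
        # 3 variants: proxy correlated with both causals is picked first;
        # repositioning must land on the enumeration argmax
        n = 3000
        c1 = rng.binomial(1, 0.5, n).astype(float)
        c2 = rng.binomial(1, 0.5, n).astype(float)
        noise = rng.binomial(1, 0.04, n)
        proxy = np.clip(np.maximum(c1, c2) - noise * (c1 * c2), 0, 1).astype(float)
        dos = np.vstack([proxy, c1, c2]) * 2
        gs = _genotypes(dos, [1000, 2000, 3000])
        y = 0.35 * dos[1] + 0.35 * dos[2] + rng.standard_normal(n)
        spec = _spec(n)
        model = fm.LocusModel(y, gs, spec)
        first, _ = model.best_candidate([])
        assert first == 0  # the proxy wins marginally
        locus = fm.Locus(
            region=fm.QtlRegion("1", 1, 4000, "", 1000, np.nan, []),
            genotypes=gs, trait="t", m_eff=3.0,
        )
        leads = fm.reposition([model.ids[0], model.ids[2]], locus, y, spec)
        # oracle: enumerate all 2-subsets, take the best configuration
        subsets = [(a, b) for a in range(3) for b in range(3) if a < b]
        best = max(subsets, key=lambda s: model.log_marginal(list(s)))
        assert sorted(leads) == sorted(model.ids[i] for i in best)


class TestSignalSet:
    def test_no_other_signals_r2_zero_keeps_all(self, rng):
        dos = rng.binomial(2, 0.3, (5, 300)).astype(float)
        gs = _genotypes(dos, [1000, 2000, 3000, 4000, 5000])
        ids = list(gs.variants["id"])
        assert fm.signal_set(ids[0], [], gs, r2_in=0.0) == ids

    def test_membership_matches_hand_computed_r2(self, rng):
        base = rng.binomial(1, 0.5, 400).astype(float)
        flip = lambda frac: np.where(rng.random(400) < frac, 1 - base, base)
        rows = np.vstack([base, flip(0.05), flip(0.45), rng.binomial(1, 0.5, 400),
                          flip(0.02)]) * 2
        gs = _genotypes(rows, [1000, 2000, 3000, 4000, 5000])
        ids = list(gs.variants["id"])
        r2 = np.corrcoef(rows) ** 2
        expected = [ids[i] for i in range(5) if r2[0, i] >= 0.3 or i == 0]
        assert fm.signal_set(ids[0], [], gs, r2_in=0.3) == expected

    def test_variant_in_ld_with_other_lead_excluded(self, rng):
        v = rng.binomial(2, 0.4, 300).astype(float)
        w = rng.binomial(2, 0.4, 300).astype(float)
        dos = np.vstack([v, w, w])  # variant 2 is a perfect copy of lead w
        gs = _genotypes(dos, [1000, 2000, 3000])
        ids = list(gs.variants["id"])
        out = fm.signal_set(ids[0], [ids[1]], gs, r2_in=0.0, r2_out=0.25)
        assert ids[2] not in out and ids[0] in out

    def test_lead_among_others_rejected(self, rng):
        gs = _genotypes(rng.binomial(2, 0.3, (2, 100)).astype(float), [1, 2])
        ids = list(gs.variants["id"])
        with pytest.raises(ValueError):
            fm.signal_set(ids[0], [ids[0]], gs)


class TestPpc:
    def test_singleton_set(self):
        ds, locus, y, spec = _sim_locus(9, n=500, m=50, effect=0.3)
        model = LocusModel(y, locus.genotypes, spec)
        ppc = fm.compute_ppc([model.ids[0]], [], model)
        assert ppc.iloc[0] == 1.0

    def test_identical_columns_split_mass(self, rng):
        v = rng.binomial(2, 0.4, 500).astype(float)
        w = rng.binomial(2, 0.3, 500).astype(float)
        gs = _genotypes(np.vstack([v, v, w]), [1000, 2000, 3000])
        y = 0.4 * v + rng.standard_normal(500)
        model = LocusModel(y, gs, _spec(500))
        ppc = fm.compute_ppc(list(gs.variants["id"]), [], model)
        assert ppc.iloc[0] == pytest.approx(ppc.iloc[1], rel=1e-9)
        assert ppc.sum() == pytest.approx(1.0, abs=1e-10)

    def test_matches_direct_marginal_enumeration(self):
        ds, locus, y, spec = _sim_locus(11, n=800, m=10, effect=0.3)
        model = LocusModel(y, locus.genotypes, spec)
        ids = model.ids
        ppc = fm.compute_ppc(ids, [], model)
        logml = np.array([model.log_marginal([model.index[v]]) for v in ids])
        direct = np.exp(logml - logml.max())
        direct /= direct.sum()
        np.testing.assert_allclose(ppc.to_numpy(), direct, atol=1e-10)

    def test_normalisation_under_arbitrary_priors(self, rng):
        ds, locus, y, spec = _sim_locus(12, n=600, m=40, effect=0.3)
        model = LocusModel(y, locus.genotypes, spec)
        ids = model.ids
        priors = pd.Series(rng.uniform(0.1, 5.0, len(ids)), index=ids)
        ppc = fm.compute_ppc(ids, [], model, priors=priors)
        assert ppc.sum() == pytest.approx(1.0, abs=1e-10)


class TestCredibleSet:
    def test_prefix_rule(self):
        ppc = pd.Series([0.6, 0.3, 0.08, 0.02], index=list("abcd"))
        assert fm.credible_set(ppc, level=0.95) == ["a", "b", "c"]

    def test_single_confident_variant(self):
        ppc = pd.Series([0.96, 0.04], index=list("ab"))
        assert fm.credible_set(ppc, level=0.95) == ["a"]

    def test_uniform_twenty_variants(self):
        ppc = pd.Series(np.full(20, 1 / 20), index=[f"v{i}" for i in range(20)])
        assert len(fm.credible_set(ppc, level=0.95)) == 19


class TestGenePpc:
    def _signal(self, ppc_map):
        ppc = pd.Series(ppc_map)
        return fm.Signal(
            lead=ppc.idxmax(), candidate_ids=list(ppc.index), ppc=ppc,
            credible=list(ppc.index), conditional_p=1e-9, log_bf=10.0, trait="t",
        )

    def _variants(self, positions):
        return pd.DataFrame(
            {
                "id": [f"1:{p}:A:C" for p in positions],
                "chrom": "1",
                "pos": positions,
                "ref": "A",
                "alt": "C",
                "maf": 0.3,
            }
        )

    def test_mass_inside_gene_body(self):
        variants = self._variants([10_000, 11_000])
        genes = pd.DataFrame({"chrom": ["1"], "start": [9_000], "end": [12_000],
                              "name": ["G1"], "strand": ["+"]})
        sig = self._signal({"1:10000:A:C": 0.7, "1:11000:A:C": 0.3})
        out = fm.gene_ppc([sig], genes, variants)
        assert out.loc["G1"].iloc[0] == pytest.approx(1.0)

    @pytest.mark.parametrize("offset, counted", [(1_500, True), (2_500, False)])
    def test_upstream_flank(self, offset, counted):
        gene_start = 50_000
        variants = self._variants([gene_start - offset])
        genes = pd.DataFrame({"chrom": ["1"], "start": [gene_start], "end": [60_000],
                              "name": ["G1"], "strand": ["+"]})
        sig = self._signal({variants["id"][0]: 1.0})
        out = fm.gene_ppc([sig], genes, variants)
        assert out.loc["G1"].iloc[0] == pytest.approx(1.0 if counted else 0.0)


class TestPostFilters:
    def _result(self, seed, n_signals, n=400, m=40):
        ds, locus, y, spec = _sim_locus(seed, n=n, m=m, effect=0.3)
        model = LocusModel(y, locus.genotypes, spec)
        ids = model.ids
        signals = []
        for k in range(n_signals):
            cand = ids[k * 5 : k * 5 + 12]
            ppc = fm.compute_ppc(cand, [], model)
            signals.append(
                fm.Signal(lead=cand[0], candidate_ids=cand, ppc=ppc,
                          credible=cand[:3], conditional_p=1e-9, log_bf=20.0,
                          trait="trait1")
            )
        return fm.FineMapResult(locus=locus, signals=signals)

    def test_locus_with_too_many_signals_dropped(self):
        res = self._result(21, 4)
        out = fm.apply_post_filters([res])
        assert out["kept"] == []
        assert any(">3 signals" in f["reason"] for f in out["flags"])

    def test_distinct_genotype_boundary(self, rng):
        # 10 distinct columns -> removed; 11 -> kept
        ds, locus, y, spec = _sim_locus(22, n=500, m=40, effect=0.3)
        model = LocusModel(y, locus.genotypes, spec)

        def signal_with_k_distinct(k):
            sub = locus.genotypes
            distinct = []
            seen = set()
            for i, row in enumerate(np.rint(sub.dosages).astype(int)):
                key = row.tobytes()
                if key not in seen:
                    seen.add(key)
                    distinct.append(i)
                if len(distinct) == k:
                    break
            cand = [model.ids[i] for i in distinct]
            ppc = fm.compute_ppc(cand, [], model)
            return fm.Signal(lead=cand[0], candidate_ids=cand, ppc=ppc,
                             credible=cand[:1], conditional_p=1e-9, log_bf=20.0,
                             trait="trait1")

        res10 = fm.FineMapResult(locus=locus, signals=[signal_with_k_distinct(10)])
        res11 = fm.FineMapResult(locus=locus, signals=[signal_with_k_distinct(11)])
        out = fm.apply_post_filters([res10, res11])
        assert len(out["kept"][0].signals) == 0
        assert len(out["kept"][1].signals) == 1

    def test_weak_lead_removed(self):
        res = self._result(23, 1)
        res.signals[0].conditional_p = 1e-5
        out = fm.apply_post_filters([res])
        assert len(out["kept"][0].signals) == 0

    def test_lead_ld_prunes_enrichment_subset_only(self, rng):
        ds, locus, y, spec = _sim_locus(24, n=500, m=40, effect=0.3, ld_rho=0.98)
        model = LocusModel(y, locus.genotypes, spec)
        ids = model.ids
        r2 = np.corrcoef(locus.genotypes.dosages) ** 2
        j = next(j for j in range(1, 40) if 0.25 < r2[0, j] < 0.9)
        signals = []
        for lead_i in (0, j):
            cand = [ids[lead_i]] + [ids[k] for k in range(12, 24)]
            ppc = fm.compute_ppc(cand, [], model)
            signals.append(fm.Signal(lead=ids[lead_i], candidate_ids=cand, ppc=ppc,
                                     credible=cand[:2], conditional_p=1e-9,
                                     log_bf=20.0, trait="trait1"))
        res = fm.FineMapResult(locus=locus, signals=signals)
        out = fm.apply_post_filters([res])
        assert len(out["kept"][0].signals) == 2  # both survive the main filters
        assert len(out["enrichment_signals"]) == 1  # LD prune hits the subset
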