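"""Seed-deterministic synthetic datasets with the structure the model assumes.

Genotypes come from a haplotype-copying process (block LD with tunable
adjacent-variant correlation), optionally with full-sib families sharing
recombinant parental haplotypes.  Phenotypes follow the mixed model: planted
causal effects, a marker-based polygenic background, and per-individual
residual variance proportional to 1/r^2 - 1 so that supplying the true
reliabilities to the analysis is the correctly specified model.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .assoc import PhenotypePanel
from .io import GenotypeSet, variant_key, write_vcf

__all__ = [
    "SimulationConfig",
    "SyntheticDataset",
    "simulate_genotypes",
    "simulate_phenotype",
    "simulate_annotations",
    "simulate_dataset",
    "write_fixture",
]


@dataclasses.dataclass
class SimulationConfig:
    """Study conditions for a synthetic dataset.

    Effect sizes are in units of the phenotypic standard deviation.
    ``ld_rho`` is the probability that a haplotype allele copies its
    left-hand neighbour within an LD block (0 = linkage equilibrium,
    -> 1 = near-duplicate variants).  ``h2_polygenic`` is the fraction of
    phenotypic variance from the polygenic background.  Reliabilities are
    drawn uniformly from ``reliability_bounds``.
    """

    seed: int
    n_individuals: int = 1000
    n_variants: int = 2000
    n_loci: int = 1
    block_length: int = 25
    ld_rho: float = 0.95
    freq_bounds: tuple[float, float] = (0.05, 0.95)
    n_families: int = 0
    family_size: int = 0
    recombination_rate: float = 0.01
    n_causal_per_locus: int = 1
    causal_effect_sd: float = 0.15
    causal_maf_range: tuple[float, float] = (0.1, 0.5)
    h2_polygenic: float = 0.25
    n_traits: int = 1
    reliability_bounds: tuple[float, float] = (0.5, 0.95)
    annotation_p: dict | None = None
    annotation_q: dict | None = None
    annotation_scheme: str = "functional"
    chrom: str = "1"
    variant_spacing: int = 1000

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("a seed is mandatory")
        lo, hi = self.freq_bounds
        if not (0 < lo <= hi < 1):
            raise ValueError("freq_bounds must satisfy 0 < lo <= hi < 1")
        if not 0 <= self.ld_rho <= 1:
            raise ValueError("ld_rho must be in [0, 1]")
        if not 0 <= self.h2_polygenic < 1:
            raise ValueError("h2_polygenic must be in [0, 1)")
        rlo, rhi = self.reliability_bounds
        if not (0 < rlo <= rhi <= 1):
            raise ValueError("reliability_bounds must lie in (0, 1]")
        if self.n_families * self.family_size > self.n_individuals:
            raise ValueError("families exceed n_individuals")
        if (self.annotation_p is None) != (self.annotation_q is None):
            raise ValueError("annotation_p and annotation_q go together")
        if self.annotation_p is not None:
            for d in (self.annotation_p, self.annotation_q):
                if abs(sum(d.values()) - 1.0) > 1e-9:
                    raise ValueError("annotation probabilities must sum to 1")
            if set(self.annotation_p) != set(self.annotation_q):
                raise ValueError("annotation_p/q categories differ")


@dataclasses.dataclass
class SyntheticDataset:
    genotypes: GenotypeSet
    panel: PhenotypePanel
    annotations: pd.DataFrame | None
    truth: dict
    genes: pd.DataFrame


def _copy_chain_haplotypes(n_hap, freqs, blocks, rho, rng):
    """Haplotypes from a first-order allele-copying chain within LD blocks."""
    m = len(freqs)
    H = np.empty((n_hap, m), dtype=np.int8)
    for j in range(m):
        fresh = rng.random(n_hap) < freqs[j]
        if j == 0 or blocks[j] != blocks[j - 1] or rho == 0.0:
            H[:, j] = fresh
        else:
            copy = rng.random(n_hap) < rho
            H[:, j] = np.where(copy, H[:, j - 1], fresh)
    return H


def _recombine(hap_a, hap_b, rate, rng):
    """Child haplotype switching between the two parental haplotypes."""
    m = hap_a.shape[-1]
    switch = rng.random(m) < rate
    switch[0] = rng.random() < 0.5
    phase = np.cumsum(switch) % 2
    return np.where(phase == 0, hap_a, hap_b)


def simulate_genotypes(config: SimulationConfig, rng=None) -> GenotypeSet:
    """Diploid 0/1/2 genotypes with block LD and optional full-sib families."""
    rng = np.random.default_rng(config.seed if rng is None else rng)
    m, n = config.n_variants, config.n_individuals
    freqs = rng.uniform(*config.freq_bounds, size=m)
    blocks = np.arange(m) // max(config.block_length, 1)

    n_fam_members = config.n_families * config.family_size
    n_unrelated = n - n_fam_members
    family_labels = ["unrelated"] * n

    hap_rows = []
    if config.n_families:
        parent_haps = _copy_chain_haplotypes(
            4 * config.n_families, freqs, blocks, config.ld_rho, rng
        )
        idx = 0
        for fam in range(config.n_families):
            pa = parent_haps[4 * fam : 4 * fam + 2]
            pb = parent_haps[4 * fam + 2 : 4 * fam + 4]
            for _ in range(config.family_size):
                hap_rows.append(_recombine(pa[0], pa[1], config.recombination_rate, rng))
                hap_rows.append(_recombine(pb[0], pb[1], config.recombination_rate, rng))
                family_labels[idx] = f"fam{fam}"
                idx += 1
    if n_unrelated:
        hap_rows.append(
            _copy_chain_haplotypes(2 * n_unrelated, freqs, blocks, config.ld_rho, rng)
        )
    haps = np.vstack(hap_rows)
    dosages = (haps[0::2] + haps[1::2]).T.astype(float)  # (m, n)

    # guard against the rare monomorphic draw
    for j in np.flatnonzero(dosages.std(axis=1) == 0):
        for _ in range(10):
            col = (rng.random(n) < freqs[j]).astype(float) + (
                rng.random(n) < freqs[j]
            )
            if col.std() > 0:
                dosages[j] = col
                break

    pos = (np.arange(m) + 1) * config.variant_spacing
    variants = pd.DataFrame(
        {
            "id": [variant_key(config.chrom, p, "A", "C") for p in pos],
            "chrom": config.chrom,
            "pos": pos,
            "ref": "A",
            "alt": "C",
            "maf": np.nan,
        }
    )
    gs = GenotypeSet(variants, dosages, [f"ind{i:05d}" for i in range(n)])
    gs.family_labels = family_labels
    return gs


def _pick_causals(config, genotypes, rng):
    maf = genotypes.compute_maf()
    m = genotypes.n_variants
    locus_bounds = np.array_split(np.arange(m), config.n_loci)
    causal_idx = []
    lo, hi = config.causal_maf_range
    for locus_vars in locus_bounds:
        eligible = locus_vars[(maf[locus_vars] >= lo) & (maf[locus_vars] <= hi)]
        if len(eligible) < config.n_causal_per_locus:
            eligible = locus_vars
        causal_idx.extend(
            rng.choice(eligible, size=config.n_causal_per_locus, replace=False)
        )
    return np.array(sorted(causal_idx), dtype=int)


def simulate_phenotype(
    genotypes: GenotypeSet,
    config: SimulationConfig,
    rng=None,
    causal_index: np.ndarray | None = None,
) -> tuple[PhenotypePanel, dict]:
    """Phenotypes y = Z beta + g + e on the deregressed-proof scale.

    Working on the model's sigma_e^2 = 1 scale: the polygenic background has
    variance eta = h2/(1-h2), the residual of individual i has variance
    1/r_i^2 - 1, and causal effects are back-computed from their size in
    phenotypic SD so that the realised variance budget is consistent.
    """
    rng = np.random.default_rng(
        np.random.default_rng(config.seed).integers(2**31) if rng is None else rng
    )
    n = genotypes.n_individuals
    if causal_index is None:
        causal_index = _pick_causals(config, genotypes, rng)
    X_causal = genotypes.dosages[causal_index].T  # (n, k)
    if X_causal.shape[1] and X_causal.std(axis=0).min() == 0:
        raise ValueError("causal variant is monomorphic")

    eta = config.h2_polygenic / (1.0 - config.h2_polygenic)
    reliab = rng.uniform(*config.reliability_bounds, size=(n, config.n_traits))
    # reliab stores the reliability r^2 itself; residual variance is R_ii
    resid_var = np.maximum(1.0 / reliab - 1.0, 0.0)
    mean_resid = float(resid_var.mean())

    # phenotypic variance (sigma_e^2 = 1 units) solves
    #   sp2 = beta_sd^2 * sp2 * sum(2 p q) + eta + mean_resid
    p_c = X_causal.mean(axis=0) / 2.0
    het = float(np.sum(2.0 * p_c * (1.0 - p_c)))
    denom = 1.0 - config.causal_effect_sd**2 * het
    if denom <= 0:
        raise ValueError("causal effects explain >= 100% of phenotypic variance")
    sp2 = (eta + mean_resid) / denom if (eta + mean_resid) > 0 else 1.0
    beta_mag = config.causal_effect_sd * np.sqrt(sp2)
    betas = beta_mag * rng.choice([-1.0, 1.0], size=X_causal.shape[1])

    values = np.empty((n, config.n_traits))
    for t in range(config.n_traits):
        g = np.zeros(n)
        if eta > 0:
            u = rng.standard_normal(genotypes.n_variants)
            centered = genotypes.dosages - genotypes.dosages.mean(axis=1, keepdims=True)
            g = centered.T @ u
            g *= np.sqrt(eta) / max(g.std(), 1e-12)
        e = rng.standard_normal(n) * np.sqrt(resid_var[:, t])
        values[:, t] = X_causal @ betas + g + e

    trait_names = [f"trait{t + 1}" for t in range(config.n_traits)]
    ids = list(genotypes.individuals)
    panel = PhenotypePanel(
        trait_values=pd.DataFrame(values, index=ids, columns=trait_names),
        reliabilities=pd.DataFrame(reliab, index=ids, columns=trait_names),
    )
    truth = {
        "causal_ids": list(genotypes.variants["id"].iloc[causal_index]),
        "causal_index": [int(i) for i in causal_index],
        "effects": [float(b) for b in betas],
        "effect_sd_units": config.causal_effect_sd,
        "eta": eta,
        "h2_polygenic": config.h2_polygenic,
        "phenotypic_variance": float(sp2),
        "family_labels": getattr(genotypes, "family_labels", None),
    }
    return panel, truth


def simulate_annotations(
    genotypes: GenotypeSet,
    causal_ids,
    config: SimulationConfig,
    rng=None,
) -> pd.DataFrame:
    """Categories drawn from p_C for causal variants and q_C otherwise."""
    p = config.annotation_p or {"coding": 0.5, "noncoding": 0.5}
    q = config.annotation_q or {"coding": 0.1, "noncoding": 0.9}
    rng = np.random.default_rng(
        np.random.default_rng(config.seed + 1).integers(2**31) if rng is None else rng
    )
    cats = sorted(q)
    p_vec = np.array([p[c] for c in cats])
    q_vec = np.array([q[c] for c in cats])
    causal = genotypes.variants["id"].isin(set(causal_ids)).to_numpy()
    m = genotypes.n_variants
    labels = np.empty(m, dtype=object)
    labels[causal] = rng.choice(cats, size=int(causal.sum()), p=p_vec)
    labels[~causal] = rng.choice(cats, size=int((~causal).sum()), p=q_vec)
    return pd.DataFrame(
        {
            "variant_id": genotypes.variants["id"],
            "scheme": config.annotation_scheme,
            "category": labels,
        }
    )


def _tile_genes(config: SimulationConfig, span_bp: int) -> pd.DataFrame:
    """Synthetic gene models tiling the simulated region (20 kb per 50 kb)."""
    starts = np.arange(10_000, max(span_bp - 10_000, 10_001), 50_000)
    return pd.DataFrame(
        {
            "chrom": config.chrom,
            "start": starts,
            "end": starts + 20_000,
            "name": [f"GENE{i + 1:04d}" for i in range(len(starts))],
            "strand": "+",
        }
    )


def simulate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Full dataset: genotypes, phenotypes, annotations, genes, truth manifest."""
    rng = np.random.default_rng(config.seed)
    genotypes = simulate_genotypes(config, rng)
    panel, truth = simulate_phenotype(genotypes, config, rng)
    annotations = simulate_annotations(genotypes, truth["causal_ids"], config, rng)
    genes = _tile_genes(config, int(genotypes.variants["pos"].max()))
    truth["seed"] = config.seed
    truth["annotation_p"] = config.annotation_p or {"coding": 0.5, "noncoding": 0.5}
    truth["annotation_q"] = config.annotation_q or {"coding": 0.1, "noncoding": 0.9}
    truth["config"] = dataclasses.asdict(config)
    return SyntheticDataset(genotypes, panel, annotations, truth, genes)


def simulate_enrichment_signals(
    n_signals: int,
    seed: int,
    n_individuals: int = 500,
    n_variants: int = 20,
    effect_sd: float = 0.45,
    ld_rho: float = 0.9,
    annotation_p: dict | None = None,
    annotation_q: dict | None = None,
) -> tuple[list[np.ndarray], list[list[str]], dict]:
    """Independent association signals with model-derived equal-prior PPCs.

    Each signal is a small single-causal locus; the PPC vector is the actual
    posterior over the locus variants under the fine-mapping model (equal
    prior), and categories are drawn from p for the causal variant and q for
    the rest — the generative model that the enrichment likelihood assumes.
    Returns (ppc vectors, category lists, truth dict).
    """
    from .finemap import LocusModel, compute_ppc
    from .model_core import ModelSpec, reliability_to_weight

    p = annotation_p or {"coding": 0.5, "noncoding": 0.5}
    q = annotation_q or {"coding": 0.1, "noncoding": 0.9}
    cats_sorted = sorted(q)
    p_vec = np.array([p[c] for c in cats_sorted])
    q_vec = np.array([q[c] for c in cats_sorted])
    rng = np.random.default_rng(seed)
    ppcs, cat_lists = [], []
    for _ in range(n_signals):
        cfg = SimulationConfig(
            seed=int(rng.integers(2**31)),
            n_individuals=n_individuals,
            n_variants=n_variants,
            ld_rho=ld_rho,
            h2_polygenic=0.0,
            causal_effect_sd=effect_sd,
            n_causal_per_locus=1,
        )
        gs = simulate_genotypes(cfg, rng)
        panel, truth = simulate_phenotype(gs, cfg, rng)
        _, y, r2 = panel.observed("trait1")
        spec = ModelSpec(
            covariates=np.ones((len(y), 1)),
            residual_weights=reliability_to_weight(r2),
        )
        model = LocusModel(y, gs, spec)
        ppc = compute_ppc(model.ids, [], model)
        causal_id = truth["causal_ids"][0]
        labels = list(rng.choice(cats_sorted, p=q_vec, size=len(model.ids)))
        labels[model.ids.index(causal_id)] = str(rng.choice(cats_sorted, p=p_vec))
        ppcs.append(ppc.to_numpy())
        cat_lists.append(labels)
    return ppcs, cat_lists, {"p": p, "q": q}


def write_fixture(dataset: SyntheticDataset, directory, force: bool = False) -> dict:
    """Emit VCF + TSV + GFF3 + JSON truth manifest; byte-identical per seed."""
    directory = Path(directory)
    if directory.exists() and any(directory.iterdir()) and not force:
        raise FileExistsError(f"{directory} is not empty (use force=True)")
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "genotypes": directory / "genotypes.vcf",
        "phenotypes": directory / "phenotypes.tsv",
        "annotations": directory / "annotations.tsv",
        "genes": directory / "genes.gff3",
        "truth": directory / "truth.json",
    }
    write_vcf(dataset.genotypes, paths["genotypes"])
    dataset.panel.to_long_tsv(paths["phenotypes"])
    if dataset.annotations is not None:
        dataset.annotations.to_csv(paths["annotations"], sep="\t", index=False)
    with open(paths["genes"], "w") as fh:
        fh.write("##gff-version 3\n")
        for i, g in dataset.genes.iterrows():
            attrs = f"ID=gene:{g['name']};Name={g['name']}"
            fh.write(
                f"{g.chrom}\tfinemapkit\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t{attrs}\n"
            )
    with open(paths["truth"], "w") as fh:
        json.dump(dataset.truth, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return {k: str(v) for k, v in paths.items()}
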