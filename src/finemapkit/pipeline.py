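"""End-to-end orchestration: scan -> peaks -> multi-trait -> fine-mapping ->
enrichment -> prior-updated fine-mapping, with a reproducibility manifest."""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .assoc import (
    PhenotypePanel,
    compute_grm,
    detect_peaks,
    multi_trait_scan,
    qc_filter,
    single_marker_scan,
    trait_correlation,
)
from .enrichment import (
    AnnotationMap,
    bootstrap_ci,
    enrichment_ratio,
    estimate_pc,
    estimate_qc,
    make_priors,
)
from .finemap import apply_post_filters, build_locus, fine_map_locus
from .io import GenotypeSet, read_genotypes, read_gff3_genes, write_json
from .model_core import ModelSpec, fit_null_reml, reliability_to_weight
from .synthetic import SimulationConfig, simulate_dataset, write_fixture

logger = logging.getLogger(__name__)

__all__ = ["run_pipeline"]

STAGES = ["scan", "peaks", "multitrait", "finemap_equal", "enrichment", "finemap_prior"]


def _validate(config: dict) -> None:
    if "simulate" not in config:
        for key in ("genotypes", "phenotypes"):
            if key not in config:
                raise ValueError(f"config missing required input {key!r}")
            if not Path(config[key]).exists():
                raise FileNotFoundError(config[key])


def _signal_tables(results, out_dir: Path, label: str):
    sig_rows, var_rows = [], []
    for res in results:
        for k, sig in enumerate(res.signals):
            sig_rows.append(
                {
                    "chrom": res.locus.region.chrom,
                    "start": res.locus.region.start,
                    "end": res.locus.region.end,
                    "trait": res.locus.trait,
                    "signal": k + 1,
                    "lead": sig.lead,
                    "conditional_p": sig.conditional_p,
                    "log_bf": sig.log_bf,
                    "set_size": len(sig.candidate_ids),
                    "credible_size": len(sig.credible),
                }
            )
            for vid, ppc in sig.ppc.items():
                var_rows.append(
                    {
                        "variant": vid,
                        "trait": res.locus.trait,
                        "signal": k + 1,
                        "ppc": ppc,
                        "in_credible_set": vid in sig.credible,
                    }
                )
    pd.DataFrame(sig_rows).to_csv(out_dir / f"signals_{label}.tsv", sep="\t", index=False)
    pd.DataFrame(var_rows).to_csv(out_dir / f"ppc_{label}.tsv", sep="\t", index=False)


def run_pipeline(config: dict, out_dir, seed: int = 1) -> dict:
    """Run the full analysis described by ``config`` into ``out_dir``.

    Config keys: either ``simulate`` (a SimulationConfig field mapping) or
    ``genotypes``/``phenotypes`` paths, with optional ``annotations``
    (TSV), ``genes`` (GFF3), ``grm``; analysis keys ``maf_min``,
    ``hwe_alpha``, ``alpha``, ``merge_window``, ``min_cluster``, ``level``,
    ``r2_in``, ``r2_out``, ``phi``, ``gamma``, ``use_grm``.
    Stages run in order; a failure halts with the stage named, keeping
    partial outputs.  Returns the manifest dict.
    """
    _validate(config)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "version": __version__,
        "seed": seed,
        "parameters": {k: v for k, v in config.items() if not isinstance(v, dict)},
        "stages": [],
    }
    stage = "inputs"
    try:
        if "simulate" in config:
            sim_cfg = SimulationConfig(seed=seed, **config["simulate"])
            dataset = simulate_dataset(sim_cfg)
            write_fixture(dataset, out_dir / "inputs", force=True)
            genotypes = dataset.genotypes
            panel = dataset.panel
            annotations = (
                AnnotationMap(
                    scheme=sim_cfg.annotation_scheme,
                    categories=dataset.annotations.set_index("variant_id")["category"],
                )
                if dataset.annotations is not None
                else None
            )
            genes = dataset.genes
        else:
            genotypes = read_genotypes(config["genotypes"])
            panel = PhenotypePanel.from_long_tsv(config["phenotypes"])
            annotations = (
                AnnotationMap.from_tsv(config["annotations"])
                if config.get("annotations")
                else None
            )
            genes = read_gff3_genes(config["genes"]) if config.get("genes") else None

        genotypes, qc_report = qc_filter(
            genotypes,
            maf_min=config.get("maf_min", 0.01),
            hwe_alpha=config.get("hwe_alpha", 1e-6),
            return_report=True,
        )
        manifest["qc"] = qc_report

        grm = compute_grm(genotypes) if config.get("use_grm", False) else None

        # stage 1: single-trait scans
        stage = "scan"
        scans = []
        for trait in panel.trait_names:
            scan = single_marker_scan(panel, trait, genotypes, grm=grm)
            scan.to_tsv(out_dir / f"scan_{trait}.tsv")
            scans.append(scan)
        manifest["stages"].append("scan")
        manifest["lambda_gc"] = {s.trait: s.lambda_gc for s in scans}

        # stage 2: peaks
        stage = "peaks"
        alpha = config.get("alpha", 5e-8)
        regions = []
        for scan in scans:
            regions.extend(
                detect_peaks(
                    scan,
                    alpha=alpha,
                    merge_window=config.get("merge_window", 1_000_000),
                    min_cluster=config.get("min_cluster", 3),
                )
            )
        pd.DataFrame([dataclasses.asdict(r) for r in regions]).to_csv(
            out_dir / "peaks.tsv", sep="\t", index=False
        )
        manifest["stages"].append("peaks")

        # stage 3: multi-trait test
        stage = "multitrait"
        V = None
        if len(scans) >= 2:
            t_mat = pd.DataFrame(
                {s.trait: s.table.set_index("variant")["t"] for s in scans}
            ).dropna()
            V = trait_correlation(t_mat)
            mt = multi_trait_scan(scans, V)
            mt.to_tsv(out_dir / "multitrait.tsv")
            regions.extend(
                detect_peaks(
                    mt,
                    alpha=alpha,
                    merge_window=config.get("merge_window", 1_000_000),
                    min_cluster=config.get("min_cluster", 3),
                )
            )
        manifest["stages"].append("multitrait")

        # stage 4: fine-mapping with equal priors
        stage = "finemap_equal"
        results = []
        phi = config.get("phi", 1e8)
        gamma = config.get("gamma", 1e8)
        for region in regions:
            for trait in region.traits:
                if trait not in panel.trait_names:
                    continue
                ids, y, r2 = panel.observed(trait)
                gsub = genotypes.select_individuals(ids)
                locus = build_locus(
                    [(region.chrom, region.lead_pos)], gsub, trait=trait
                )
                weights = reliability_to_weight(r2)
                eta = 0.0
                if grm is not None:
                    null = fit_null_reml(y, np.ones((len(y), 1)), grm, weights)
                    eta = null["eta"]
                spec = ModelSpec(
                    covariates=np.ones((len(y), 1)),
                    relatedness=grm,
                    residual_weights=weights,
                    phi=phi,
                    gamma=gamma,
                    eta=eta,
                )
                results.append(
                    fine_map_locus(
                        locus,
                        y,
                        spec,
                        level=config.get("level", 0.95),
                        r2_in=config.get("r2_in", 0.3),
                        r2_out=config.get("r2_out", 0.25),
                        genes=genes,
                    )
                )
        filtered = apply_post_filters(
            results,
            max_signals_per_locus=config.get("max_signals", 3),
            lead_alpha=config.get("lead_alpha", 5e-7),
            trait_correlation=V,
            genotypes=genotypes,
        )
        _signal_tables(filtered["kept"], out_dir, "equal_prior")
        manifest["stages"].append("finemap_equal")
        manifest["n_signals"] = sum(len(r.signals) for r in filtered["kept"])

        # stage 5: enrichment
        stage = "enrichment"
        model = None
        if annotations is not None and filtered["enrichment_signals"]:
            q_c = estimate_qc(annotations, list(genotypes.variants["id"]))
            sig_ppcs = [s.ppc.to_numpy() for s in filtered["enrichment_signals"]]
            sig_cats = [
                list(annotations.of(s.ppc.index))
                for s in filtered["enrichment_signals"]
            ]
            model = bootstrap_ci(
                sig_ppcs,
                sig_cats,
                q_c,
                n_boot=config.get("n_boot", 1000),
                rng=np.random.default_rng(seed + 1),
            )
            model.scheme = annotations.scheme
            model.to_frame().to_csv(out_dir / "enrichment.tsv", sep="\t")
        manifest["stages"].append("enrichment")

        # stage 6: fine-mapping with annotation-informed priors
        stage = "finemap_prior"
        if model is not None:
            prior_results = []
            for res in filtered["kept"]:
                new_signals = []
                for sig in res.signals:
                    cats = annotations.of(sig.ppc.index)
                    pri = make_priors(model.p_c, model.q_c, cats)
                    priors = pd.Series(pri, index=sig.ppc.index)
                    locus = res.locus
                    ids, y, r2 = panel.observed(res.locus.trait)
                    # reuse equal-prior likelihoods: updated PPC = ppc * prior
                    from .enrichment import update_ppc
                    from .finemap import Signal, credible_set

                    new_ppc = update_ppc(sig.ppc, pri)
                    cs = credible_set(
                        new_ppc,
                        locus.genotypes.variants.set_index("id")["pos"],
                        level=config.get("level", 0.95),
                    )
                    new_signals.append(
                        dataclasses.replace(sig, ppc=new_ppc, credible=cs)
                    )
                prior_results.append(dataclasses.replace(res, signals=new_signals))
            _signal_tables(prior_results, out_dir, "annotation_prior")
        manifest["stages"].append("finemap_prior")
    except Exception:
        manifest["failed_stage"] = stage
        write_json(manifest, out_dir / "manifest.json")
        logger.exception("pipeline failed at stage %s", stage)
        raise

    write_json(manifest, out_dir / "manifest.json")
    return manifest
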