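"""Configuration-driven end-to-end pipeline.

``run_all`` executes simulate/load -> missingness filter -> TAMPOR ->
outlier screen -> covariate regression -> differential abundance ->
network -> module association -> enrichment -> cross-cohort preservation
and synthetic eigenproteins -> biomarker panels, writing every table to
the output directory plus a JSON manifest (no timestamps, so fixed-seed
runs are byte-identical).
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd
import yaml

from . import io, synthetic
from .adjust import AdjustParams, bootstrap_regress
from .association import dap_module_overlay, eigenprotein_anova, module_trait_bicor
from .differential import anova_bh
from .enrichment import celltype_enrichment, fisher_enrichment, parse_gmt
from .exceptions import ConfigurationError
from .network import NetworkParams, build_network
from .panels import PanelParams, panel_cluster, panel_pca, select_top_daps
from .preprocess import (
    ALL_SAMPLE_DENOMINATOR,
    GIS_DENOMINATOR,
    PreprocessParams,
    detect_outliers,
    filter_by_missingness,
    mds_qc,
    tampor_normalize,
)
from .preservation import (
    PreservationParams,
    SyntheticMEParams,
    module_preservation,
    synthetic_eigenproteins,
)
from ._util import derive_seed

log = logging.getLogger("csfnet")

_KNOWN_KEYS = {
    "": {"seed", "output_dir", "synthetic", "inputs", "genesets", "preprocess",
         "adjust", "network", "preservation", "synthetic_me", "panels",
         "comparisons"},
    "synthetic": {"design", "n_proteins", "n_modules", "max_module_size",
                  "min_module_size", "subthreshold_module_size", "null",
                  "noise_sd", "mcar_rate", "mnar_strength", "n_decoy_sets"},
    "inputs": {"abundance", "traits", "test_abundance", "test_traits",
               "gmt", "markers"},
    "genesets": {"n_decoy_sets"},
    "preprocess": {"max_missing_frac", "tampor_mode", "tol", "max_iter",
                   "outlier_z", "remove_outliers"},
    "adjust": {"nuisance", "n_boot", "min_complete"},
    "network": {"beta", "deep_split", "min_module_size", "merge_cut_height",
                "pam_stage", "max_p_outliers"},
    "preservation": {"enabled", "n_perm"},
    "synthetic_me": {"hub_fraction", "min_hubs"},
    "panels": {"k", "contrasts"},
}

DEFAULT_COMPARISONS = [
    ["control", "sALS"], ["control", "C9_ALS"], ["control", "C9_asym"],
    ["C9_asym", "C9_ALS"],
]
DEFAULT_CONTRASTS = [
    {"name": "ALS_vs_control",
     "a": ["control"], "b": ["sALS", "C9_ALS", "SOD1_ALS"]},
    {"name": "symptomatic_vs_asymptomatic",
     "a": ["C9_asym", "SOD1_asym"], "b": ["sALS", "C9_ALS", "SOD1_ALS"]},
]


def validate_config(cfg: dict) -> None:
    """Reject unknown keys and missing input paths before any compute."""
    if not isinstance(cfg, dict):
        raise ConfigurationError("config must be a mapping")
    unknown = set(cfg) - _KNOWN_KEYS[""]
    if unknown:
        raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
    for section, allowed in _KNOWN_KEYS.items():
        if section and section in cfg and isinstance(cfg[section], dict):
            extra = set(cfg[section]) - allowed
            if extra:
                raise ConfigurationError(
                    f"unknown keys in {section!r}: {sorted(extra)}")
    if "synthetic" not in cfg and "inputs" not in cfg:
        raise ConfigurationError("config needs a 'synthetic' or 'inputs' block")
    for key, path in (cfg.get("inputs") or {}).items():
        if path and not Path(path).exists():
            raise ConfigurationError(f"input path does not exist: {path} ({key})")


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    validate_config(cfg)
    return cfg


def demo_config(seed: int = 1) -> dict:
    """A small synthetic single-center run that exercises every stage."""
    return {
        "seed": seed,
        "synthetic": {"design": "single_center", "n_proteins": 300, "n_modules": 5,
                      "max_module_size": 60, "min_module_size": 15,
                      "subthreshold_module_size": 0, "n_decoy_sets": 10},
        "network": {"min_module_size": 10},
        "preservation": {"enabled": True, "n_perm": 50},
        "comparisons": [["control", "sALS"], ["control", "C9_ALS"]],
        "panels": {"k": 6},
    }


def _truth_params(block: dict) -> synthetic.TruthParams:
    from dataclasses import replace

    null = block.get("null", False)
    if "n_proteins" in block and "max_module_size" not in block:
        base = synthetic.scaled_truth_params(block["n_proteins"], null=null)
    elif null:
        base = synthetic.null_truth_params(block.get("n_proteins", 2000))
    else:
        base = synthetic.default_truth_params()
    kwargs = {}
    for key in ("n_proteins", "n_modules", "max_module_size", "min_module_size",
                "subthreshold_module_size", "noise_sd", "mcar_rate", "mnar_strength"):
        if key in block:
            kwargs[key] = block[key]
    return replace(base, **kwargs)


def _design(name: str) -> synthetic.CohortDesign:
    if name == "single_center":
        return synthetic.single_center_design()
    if name == "multicenter":
        return synthetic.multicenter_design()
    raise ConfigurationError(f"unknown design {name!r} (use 'single_center' or 'multicenter')")


def _preprocess_cohort(matrix, traits, pp: PreprocessParams, remove_outliers: bool):
    filtered = filter_by_missingness(matrix, pp, traits=traits)
    normalized, report = tampor_normalize(filtered, traits, pp)
    outliers = detect_outliers(normalized, pp)
    if remove_outliers and outliers:
        normalized = normalized.drop(columns=outliers)
    return filtered, normalized, report, outliers


def _auto_mode(traits: pd.DataFrame) -> str:
    platform = traits["platform"].iloc[0] if "platform" in traits.columns else "TMT_like"
    return GIS_DENOMINATOR if platform == "TMT_like" else ALL_SAMPLE_DENOMINATOR


def _auto_nuisance(traits: pd.DataFrame) -> list[str]:
    nuis = ["age", "sex"]
    if "batch" in traits.columns and traits["batch"].notna().any():
        nuis.append("batch")
    return nuis


def run_all(cfg: dict, out_dir: str | Path, seed: int | None = None) -> dict:
    """Execute every stage; returns the manifest (also written as JSON)."""
    validate_config(cfg)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    master = int(seed if seed is not None else cfg.get("seed", 0))
    manifest: dict = {"seed": master, "stages": []}

    def record(stage: str, outputs: list[str], **info):
        manifest["stages"].append({"stage": stage, "outputs": outputs, **info})
        log.info("stage %s done: %s", stage, info)

    # ---- stage 1: simulate or load -------------------------------------
    syn = cfg.get("synthetic")
    test_matrix = test_traits = None
    truth = None
    if syn is not None:
        design = _design(syn.get("design", "single_center"))
        params = _truth_params(syn)
        matrix, traits, truth = synthetic.generate_cohort(design, params, master)
        # regenerated cohort from the same truth, for preservation
        if (cfg.get("preservation") or {}).get("enabled", True):
            test_matrix, test_traits, _ = synthetic.generate_cohort(
                design, truth, derive_seed(master, "test_cohort"))
        sets, markers = synthetic.generate_genesets(
            truth, syn.get("n_decoy_sets", 20), master)
        io.write_abundance(matrix, out / "abundance_raw.tsv")
        io.write_traits(traits, out / "traits.csv")
        io.write_json(truth.to_dict(), out / "ground_truth.json")
        io.write_gmt(sets, out / "genesets.gmt")
        io.write_markers(markers, out / "celltype_markers.tsv")
        gmt_path, markers_path = out / "genesets.gmt", out / "celltype_markers.tsv"
        record("simulate", ["abundance_raw.tsv", "traits.csv", "ground_truth.json",
                            "genesets.gmt", "celltype_markers.tsv"],
               n_proteins=len(matrix), n_samples=matrix.shape[1])
    else:
        inputs = cfg["inputs"]
        matrix = io.read_abundance(inputs["abundance"])
        traits = io.read_traits(inputs["traits"])
        if inputs.get("test_abundance"):
            test_matrix = io.read_abundance(inputs["test_abundance"])
            test_traits = io.read_traits(inputs["test_traits"])
        gmt_path = inputs.get("gmt")
        markers_path = inputs.get("markers")
        record("load", [], n_proteins=len(matrix), n_samples=matrix.shape[1])

    # ---- stage 2: preprocess -------------------------------------------
    ppb = cfg.get("preprocess") or {}
    pp = PreprocessParams(
        max_missing_frac=ppb.get("max_missing_frac", 0.5),
        tampor_mode=ppb.get("tampor_mode", _auto_mode(traits)),
        tol=ppb.get("tol", 1e-4),
        max_iter=ppb.get("max_iter", 250),
        outlier_z=ppb.get("outlier_z", -3.0),
    )
    remove_outliers = ppb.get("remove_outliers", False)
    filtered, normalized, report, outliers = _preprocess_cohort(
        matrix, traits, pp, remove_outliers)
    mds = mds_qc(normalized, traits)
    io.write_abundance(normalized, out / "abundance_normalized.tsv")
    mds.to_csv(out / "mds_qc.tsv", sep="\t", index=False)
    io.write_json({"tampor": report.to_dict(), "outliers": outliers},
                  out / "preprocess_report.json")
    record("preprocess", ["abundance_normalized.tsv", "mds_qc.tsv",
                          "preprocess_report.json"],
           n_proteins_after_filter=len(filtered), n_outliers=len(outliers),
           tampor_iterations=report.iterations)

    # ---- stage 3: covariate regression ---------------------------------
    ab = cfg.get("adjust") or {}
    ap = AdjustParams(
        nuisance=ab.get("nuisance", _auto_nuisance(traits)),
        n_boot=ab.get("n_boot", 200),
        min_complete=ab.get("min_complete", 10),
        seed=derive_seed(master, "adjust"),
    )
    adjusted, coef = bootstrap_regress(normalized, traits, ap)
    io.write_abundance(adjusted, out / "abundance_adjusted.tsv")
    coef.to_csv(out / "regression_coefficients.tsv", sep="\t", index=False)
    record("adjust", ["abundance_adjusted.tsv", "regression_coefficients.tsv"],
           n_terms=coef["term"].nunique())

    # ---- stage 4: differential abundance -------------------------------
    groups = traits.loc[~traits["is_reference"].astype(bool)].set_index(
        "sample_id")["group"]
    comparisons = [tuple(c) for c in cfg.get("comparisons", DEFAULT_COMPARISONS)
                   if c[0] in set(groups) and c[1] in set(groups)]
    dap_tables = anova_bh(adjusted, groups, comparisons)
    for t in dap_tables:
        t.to_frame().to_csv(out / f"dap_{t.name}.tsv", sep="\t")
    record("dap", [f"dap_{t.name}.tsv" for t in dap_tables],
           n_significant={t.name: int(len(t.significant())) for t in dap_tables})

    # ---- stage 5: network ----------------------------------------------
    nb = cfg.get("network") or {}
    np_ = NetworkParams(
        beta=nb.get("beta", 4.0), deep_split=nb.get("deep_split", 4),
        min_module_size=nb.get("min_module_size", 15),
        merge_cut_height=nb.get("merge_cut_height", 0.07),
        pam_stage=nb.get("pam_stage", True),
        max_p_outliers=nb.get("max_p_outliers", 0.05),
    )
    net = build_network(adjusted, np_)
    part_df = net.partition.labels.rename("module").to_frame()
    part_df.index.name = "protein"
    part_df.to_csv(out / "module_partition.tsv", sep="\t")
    net.kme.to_csv(out / "kme.tsv", sep="\t")
    net.eigenproteins.eigenproteins.to_csv(out / "eigenproteins.tsv", sep="\t")
    record("network", ["module_partition.tsv", "kme.tsv", "eigenproteins.tsv"],
           n_modules=len(net.partition.modules),
           frac_assigned=round(net.partition.frac_assigned, 4),
           sizes=net.partition.sizes.to_dict())

    # ---- stage 6: module association -----------------------------------
    assoc = module_trait_bicor(net.eigenproteins, traits)
    assoc.to_csv(out / "module_trait_bicor.tsv", sep="\t", index=False)
    ep_anova = eigenprotein_anova(net.eigenproteins, traits)
    ep_anova.to_csv(out / "eigenprotein_anova.tsv", sep="\t")
    overlays = pd.concat(
        [dap_module_overlay(t, net.partition) for t in dap_tables],
        ignore_index=True)
    overlays.to_csv(out / "dap_module_overlay.tsv", sep="\t", index=False)
    record("association", ["module_trait_bicor.tsv", "eigenprotein_anova.tsv",
                           "dap_module_overlay.tsv"],
           n_associations=len(assoc))

    # ---- stage 7: enrichment -------------------------------------------
    enrich_outputs = []
    if gmt_path:
        collection = parse_gmt(str(gmt_path))
        enr = fisher_enrichment(net.partition, collection)
        enr.to_csv(out / "geneset_enrichment.tsv", sep="\t", index=False)
        enrich_outputs.append("geneset_enrichment.tsv")
    if markers_path:
        markers_df = io.read_markers(markers_path)
        cte = celltype_enrichment(net.partition, markers_df)
        cte.to_csv(out / "celltype_enrichment.tsv", sep="\t", index=False)
        enrich_outputs.append("celltype_enrichment.tsv")
    record("enrichment", enrich_outputs)

    # ---- stage 8: preservation / synthetic eigenproteins ---------------
    pres_cfg = cfg.get("preservation") or {}
    if pres_cfg.get("enabled", True) and test_matrix is not None:
        _, test_norm, _, _ = _preprocess_cohort(
            test_matrix, test_traits, pp, remove_outliers)
        test_ap = AdjustParams(
            nuisance=ab.get("nuisance", _auto_nuisance(test_traits)),
            n_boot=ap.n_boot, min_complete=ap.min_complete,
            seed=derive_seed(master, "adjust_test"))
        test_adj, _ = bootstrap_regress(test_norm, test_traits, test_ap)
        pres = module_preservation(
            adjusted, test_adj, net.partition,
            PreservationParams(n_perm=pres_cfg.get("n_perm", 500),
                               seed=derive_seed(master, "preservation")),
            np_)
        pres.to_csv(out / "module_preservation.tsv", sep="\t", index=False)
        smb = cfg.get("synthetic_me") or {}
        sme, hub_report = synthetic_eigenproteins(
            net.kme, net.partition, test_adj,
            SyntheticMEParams(hub_fraction=smb.get("hub_fraction", 0.20),
                              min_hubs=smb.get("min_hubs", 4)))
        sme.eigenproteins.to_csv(out / "synthetic_eigenproteins.tsv", sep="\t")
        hub_report.to_csv(out / "synthetic_me_hubs.tsv", sep="\t", index=False)
        sme_anova = eigenprotein_anova(sme, test_traits)
        sme_anova.to_csv(out / "synthetic_eigenprotein_anova.tsv", sep="\t")
        record("preservation", ["module_preservation.tsv",
                                "synthetic_eigenproteins.tsv",
                                "synthetic_me_hubs.tsv",
                                "synthetic_eigenprotein_anova.tsv"],
               min_Z_summary=float(pres["Z_summary"].min()) if len(pres) else None)

    # ---- stage 9: biomarker panels -------------------------------------
    pb = cfg.get("panels") or {}
    pparams = PanelParams(k=pb.get("k", 12))
    panel_outputs = []
    for contrast in pb.get("contrasts", DEFAULT_CONTRASTS):
        name = contrast["name"]
        a_groups = [g for g in contrast["a"] if g in set(groups)]
        b_groups = [g for g in contrast["b"] if g in set(groups)]
        if not a_groups or not b_groups:
            continue
        pooled = groups.map(
            lambda g: "A" if g in a_groups else ("B" if g in b_groups else None)
        ).dropna()
        dap = anova_bh(adjusted[pooled.index], pooled, [("A", "B")])[0]
        panel = select_top_daps(dap, pparams)
        pca = panel_pca(adjusted, panel, traits)
        clus = panel_cluster(adjusted, panel, traits, pparams)
        pd.Series(panel, name="protein").to_csv(
            out / f"panel_{name}.tsv", sep="\t", index=False)
        pca.scores.to_csv(out / f"panel_{name}_pca_scores.tsv", sep="\t")
        pca.centroids.to_csv(out / f"panel_{name}_centroids.tsv", sep="\t")
        clus.sample_classes.to_frame().to_csv(
            out / f"panel_{name}_classes.tsv", sep="\t")
        with open(out / f"panel_{name}_dendrograms.txt", "w") as fh:
            fh.write(clus.sample_newick + "\n" + clus.protein_newick + "\n")
        panel_outputs += [f"panel_{name}.tsv", f"panel_{name}_pca_scores.tsv",
                          f"panel_{name}_centroids.tsv", f"panel_{name}_classes.tsv",
                          f"panel_{name}_dendrograms.txt"]
    record("panels", panel_outputs)

    io.write_json(manifest, out / "manifest.json")
    return manifest
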