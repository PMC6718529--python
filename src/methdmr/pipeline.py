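"""Configuration-driven orchestration of the full analysis and of the
two standard simulation suites (null calibration and effect recovery).

The full pipeline mirrors the analysis order of a blood-methylome
case/control study: probe filtering -> quantile normalization -> cell
composition estimation -> composition covariate scores -> correspondence
ordination of the most variable sites -> site-wise linear models (group,
age, and the age-by-group interaction) -> DMR calling -> repeat-element
comparison when an assay table is provided.  Every run is deterministic
given the seed and records a manifest with the package version and a
hash of the configuration.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .datamodel import BetaMatrix, ParameterError, ProbeManifest, SampleSheet
from . import io as mio
from . import synthetic
from .preprocess import filter_probes, quantile_normalize, select_most_variable
from .correspondence import correspondence_analysis, write_coordinates
from .cellcomp import composition_covariate_scores, estimate_cell_composition
from .ewas import age_slopes, build_design, fit_interaction, fit_sitewise
from .dmr import call_dmrs, hypermethylated_fraction
from .downstream import repeat_group_comparison

DEFAULT_DMR_PARAMS = {"dist": 1000, "seed_p": 0.05, "bin_width": 50,
                      "min_probes": 2, "sidak_alpha": 0.05}


def child_seeds(seed: int, n: int) -> list[int]:
    """n reproducible integer seeds (< 2^31) derived from one master seed."""
    ss = np.random.SeedSequence(seed)
    return [int(c.generate_state(1)[0] % (2 ** 31)) for c in ss.spawn(n)]


def load_config(config) -> dict:
    if isinstance(config, dict):
        return config
    with open(config) as fh:
        return yaml.safe_load(fh)


# ---------------------------------------------------------------------------
# shared analysis path
# ---------------------------------------------------------------------------

@dataclass
class AnalysisResult:
    matrix: BetaMatrix                 # filtered, normalized
    manifest: ProbeManifest
    sheet: SampleSheet
    proportions: pd.DataFrame
    scores: pd.DataFrame
    group_results: pd.DataFrame
    age_results: pd.DataFrame
    interaction_results: pd.DataFrame | None
    n_interaction_significant: int | None
    dmrs: list
    dmr_audit: dict


def analyze_cohort(
    matrix: BetaMatrix,
    manifest: ProbeManifest,
    sheet: SampleSheet,
    panel,
    drop_snp: bool = True,
    drop_sex: bool = True,
    normalize: bool = True,
    moderate: bool = True,
    interaction: bool = True,
    dmr_params: dict | None = None,
) -> AnalysisResult:
    """Run the standard analysis chain on one cohort."""
    params = dict(DEFAULT_DMR_PARAMS)
    if dmr_params:
        params.update(dmr_params)
    mat = filter_probes(matrix, manifest, drop_snp=drop_snp, drop_sex=drop_sex)
    if normalize:
        mat = quantile_normalize(mat)
    proportions, _resid = estimate_cell_composition(mat, panel)
    scores = composition_covariate_scores(proportions)
    design = build_design(sheet, scores=scores)
    group_results = fit_sitewise(mat, design, effect_term="group",
                                 moderate=moderate)
    age_results = age_slopes(mat, design, moderate=moderate)
    inter_results, n_inter = None, None
    if interaction:
        design_int = build_design(sheet, scores=scores, interaction=True)
        inter_results, n_inter = fit_interaction(mat, design_int,
                                                 moderate=moderate)
    dmrs, audit = call_dmrs(group_results["p"].to_numpy(), mat, manifest,
                            sheet, **params)
    return AnalysisResult(
        matrix=mat, manifest=manifest, sheet=sheet, proportions=proportions,
        scores=scores, group_results=group_results, age_results=age_results,
        interaction_results=inter_results, n_interaction_significant=n_inter,
        dmrs=dmrs, dmr_audit=audit,
    )


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------

def _validate_config(cfg: dict) -> None:
    if "generator" not in cfg and "inputs" not in cfg:
        raise ParameterError("config needs a 'generator' or 'inputs' section")
    analysis = cfg.get("analysis", {})
    terms = analysis.get("terms")
    if analysis.get("interaction", True) and terms is not None and "age" not in terms:
        raise ParameterError("interaction term requested without an age term")
    if "inputs" in cfg:
        needed = {"beta", "manifest", "samples", "panel"}
        missing = needed - set(cfg["inputs"])
        if missing:
            raise ParameterError(f"inputs section missing: {sorted(missing)}")
        for key, path in cfg["inputs"].items():
            if not os.path.exists(path):
                raise ParameterError(f"input file for {key!r} not found: {path}")


def generate_dataset(gen_cfg: dict, seed: int):
    """Build a synthetic cohort from a generator config section."""
    seeds = child_seeds(seed, 6)
    manifest = synthetic.generate_manifest(
        n_probes=gen_cfg.get("n_probes", 5000),
        n_chroms=gen_cfg.get("n_chroms", 4),
        seed=seeds[0],
        snp_fraction=gen_cfg.get("snp_fraction", 0.02),
    )
    sheet = synthetic.generate_cohort(
        n_cases=gen_cfg.get("n_pairs", 18),
        n_controls=gen_cfg.get("n_pairs", 18),
        age_range=tuple(gen_cfg.get("age_range", (18, 59))),
        seed=seeds[1],
    )
    baselines = synthetic.generate_baselines(manifest, seed=seeds[2])
    panel = synthetic.generate_reference_panel(
        manifest, n_panel_probes=gen_cfg.get("n_panel_probes", 600),
        seed=seeds[3],
    )
    truth = synthetic.generate_truth(
        manifest,
        n_dmrs=gen_cfg.get("n_dmrs", 0),
        seed=seeds[4],
        delta_beta_range=tuple(gen_cfg["delta_beta_range"])
        if "delta_beta_range" in gen_cfg else None,
        baselines=baselines,
        hyper_fraction=gen_cfg.get("hyper_fraction", 0.78),
        n_age_probes=gen_cfg.get("n_age_probes", 0),
        age_slope_range=tuple(gen_cfg.get("age_slope_range", (0.0005, 0.002))),
        n_interaction_probes=gen_cfg.get("n_interaction_probes", 0),
        interaction_slope_range=tuple(
            gen_cfg.get("interaction_slope_range", (0.002, 0.006))),
        min_dmr_probes=gen_cfg.get("min_dmr_probes", 2),
        exclude_probes=panel.probe_ids,
    )
    matrix, proportions = synthetic.simulate_betas(
        manifest, sheet, truth, panel=panel, baselines=baselines,
        noise_sd_logit=gen_cfg.get("noise_sd_logit", 0.15),
        measurement_sd_beta=gen_cfg.get("measurement_sd_beta", 0.01),
        seed=seeds[5],
    )
    return manifest, sheet, panel, truth, matrix, proportions, baselines


def run_full_pipeline(config, outdir, seed: int = 0) -> dict:
    """Execute the configured analysis end to end; returns a summary dict."""
    cfg = load_config(config)
    _validate_config(cfg)
    os.makedirs(outdir, exist_ok=True)
    analysis = cfg.get("analysis", {})

    repeat_table = None
    if "generator" in cfg:
        gen_cfg = cfg["generator"]
        manifest, sheet, panel, truth, matrix, _props, _b = \
            generate_dataset(gen_cfg, seed)
        truth.save(os.path.join(outdir, "truth.json"))
        if gen_cfg.get("repeat_assay", False):
            repeat_table = synthetic.generate_repeat_assay(
                sheet, seed=child_seeds(seed, 7)[6])
    else:
        inputs = cfg["inputs"]
        matrix = mio.read_beta_matrix(inputs["beta"])
        manifest = mio.read_manifest(inputs["manifest"])
        sheet = mio.read_sample_sheet(inputs["samples"])
        panel = mio.read_reference_panel(inputs["panel"])
        if "repeat_assay" in inputs:
            repeat_table = pd.read_csv(inputs["repeat_assay"], sep="\t",
                                       index_col=0)

    result = analyze_cohort(
        matrix, manifest, sheet, panel,
        drop_snp=analysis.get("drop_snp", True),
        drop_sex=analysis.get("drop_sex", True),
        normalize=analysis.get("quantile_normalize", True),
        moderate=analysis.get("moderate", True),
        interaction=analysis.get("interaction", True),
        dmr_params=analysis.get("dmr"),
    )

    # ordination of the most variable sites
    k = min(analysis.get("top_k_variable", 10000), result.matrix.n_probes)
    top = select_most_variable(result.matrix, k)
    ca = correspondence_analysis(top.values, n_axes=2)
    write_coordinates(ca, os.path.join(outdir, "ca_coordinates.tsv"))

    result.group_results.to_csv(os.path.join(outdir, "site_results_group.tsv"),
                                sep="\t")
    result.age_results.to_csv(os.path.join(outdir, "site_results_age.tsv"),
                              sep="\t")
    if result.interaction_results is not None:
        result.interaction_results.to_csv(
            os.path.join(outdir, "site_results_interaction.tsv"), sep="\t")
    result.proportions.to_csv(os.path.join(outdir, "cell_proportions.tsv"),
                              sep="\t", index_label="sample_id")
    result.scores.to_csv(os.path.join(outdir, "composition_scores.tsv"),
                         sep="\t", index_label="sample_id")
    mio.write_dmrs(result.dmrs, os.path.join(outdir, "dmrs.bed"),
                   os.path.join(outdir, "dmrs.tsv"))
    if repeat_table is not None:
        repeat_group_comparison(repeat_table, sheet).to_csv(
            os.path.join(outdir, "repeat_summary.tsv"), sep="\t", index=False)

    summary = {
        "n_probes_analyzed": result.matrix.n_probes,
        "n_samples": result.matrix.n_samples,
        "n_significant_sites": int((result.group_results["q"] < 0.05).sum()),
        "n_dmrs": len(result.dmrs),
        "hyper_fraction": hypermethylated_fraction(result.dmrs)
        if result.dmrs else None,
        "n_interaction_significant": result.n_interaction_significant,
        "ca_axis_inertia_pct": [round(float(f) * 100, 3)
                                for f in ca.inertia_fractions],
    }
    manifest_path = os.path.join(outdir, "run_manifest.json")
    with open(manifest_path, "w") as fh:
        json.dump({
            "package_version": __version__,
            "config_sha256": hashlib.sha256(
                json.dumps(cfg, sort_keys=True, default=str).encode()
            ).hexdigest(),
            "seed": seed,
            "summary": summary,
        }, fh, indent=1)
    return summary


# ---------------------------------------------------------------------------
# simulation suites
# ---------------------------------------------------------------------------

def run_null_calibration(
    n_replicates: int = 20,
    seed: int = 0,
    n_probes: int = 5000,
    n_pairs: int = 18,
    moderate: bool = True,
) -> dict:
    """Replicated null cohorts: type-I rates and spurious DMR counts.

    Each replicate simulates a cohort with no injected effects (cell
    composition still varies, so the covariate path is exercised) and
    reports the fraction of raw site p-values below 0.05, the number of
    Sidak-significant DMRs, and the number of BH-significant
    interaction sites.
    """
    rep_seeds = child_seeds(seed, n_replicates)
    rows = []
    for r, s in enumerate(rep_seeds):
        gen_cfg = {"n_probes": n_probes, "n_pairs": n_pairs, "n_dmrs": 0}
        manifest, sheet, panel, _truth, matrix, _props, _b = \
            generate_dataset(gen_cfg, s)
        result = analyze_cohort(matrix, manifest, sheet, panel,
                                moderate=moderate)
        rows.append({
            "replicate": r,
            "type_i_rate": float((result.group_results["p"] < 0.05).mean()),
            "n_significant_dmrs": len(result.dmrs),
            "n_interaction_significant": result.n_interaction_significant,
        })
    per_rep = pd.DataFrame(rows)
    return {
        "site_type_i": float(per_rep["type_i_rate"].mean()),
        "mean_significant_dmrs": float(per_rep["n_significant_dmrs"].mean()),
        "interaction_significant_total": int(
            per_rep["n_interaction_significant"].sum()),
        "per_replicate": per_rep,
    }


def _match_regions(called, truth_dmrs):
    """Overlap matching of called regions against injected regions."""
    def overlaps(c, t):
        return c.chrom == t.chrom and c.start <= t.end and c.end >= t.start

    recalled = 0
    for t in truth_dmrs:
        if any(overlaps(c, t) for c in called):
            recalled += 1
    matched_called = 0
    direction_ok = 0
    for c in called:
        hits = [t for t in truth_dmrs if overlaps(c, t)]
        if hits:
            matched_called += 1
            truth_dir = "hyper" if hits[0].direction > 0 else "hypo"
            if c.direction == truth_dir:
                direction_ok += 1
    recall = recalled / len(truth_dmrs) if truth_dmrs else np.nan
    precision = matched_called / len(called) if called else np.nan
    direction_acc = direction_ok / matched_called if matched_called else np.nan
    return recall, precision, direction_acc


def run_recovery_benchmark(seed: int = 0, moderate: bool = True) -> dict:
    """Effect cohorts with known truth: DMR recall/precision/direction,
    hypermethylated fraction, age-slope recovery, interaction power.

    Four sub-runs, all at n = 18 + 18:

    * DMR recovery: 6,000 probes, 40 regions of >= 5 CpGs with target
      group differences of 0.08-0.12 beta.
    * Age slopes: 2,000 probes with 34 probes (1.7%, the fraction of
      age-affected sites typical of blood cohorts) gaining 0.0014
      beta/year.
    * Interaction power: 2,000 probes, 50 probes with a group slope
      difference of 0.004 beta/year; power at uncorrected p < 0.05.
    * Direction mix: 24,000 probes with 200 injected regions at hyper
      fraction 0.78; fraction of called regions hypermethylated.

    Injected effects are kept sparse relative to the manifest because
    quantile normalization assumes near-identical sample distributions;
    saturating the synthetic genome with one-signed effects would
    violate that assumption in a way no real cohort does.
    """
    seeds = child_seeds(seed, 4)
    report: dict = {}

    # --- DMR recovery ------------------------------------------------------
    gen = {"n_probes": 6000, "n_chroms": 6, "n_dmrs": 40,
           "delta_beta_range": (0.08, 0.12), "min_dmr_probes": 5}
    manifest, sheet, panel, truth, matrix, _p, _b = generate_dataset(gen, seeds[0])
    result = analyze_cohort(matrix, manifest, sheet, panel, moderate=moderate)
    recall, precision, direction_acc = _match_regions(result.dmrs, truth.dmrs)
    report.update({"dmr_recall": recall, "dmr_precision": precision,
                   "dmr_direction_accuracy": direction_acc,
                   "n_dmrs_called": len(result.dmrs)})

    # --- age-slope recovery ------------------------------------------------
    gen = {"n_probes": 2000, "n_dmrs": 0, "n_age_probes": 34,
           "age_slope_range": (0.0014, 0.0014)}
    manifest, sheet, panel, truth, matrix, _p, _b = generate_dataset(gen, seeds[1])
    result = analyze_cohort(matrix, manifest, sheet, panel, interaction=False,
                            moderate=moderate)
    injected = [p for p in truth.age_slopes
                if p in result.age_results.index]
    report["age_slope_pp_per_year"] = float(
        result.age_results.loc[injected, "slope_pp_per_year"].mean())

    # --- interaction power -------------------------------------------------
    gen = {"n_probes": 2000, "n_dmrs": 0, "n_interaction_probes": 50,
           "interaction_slope_range": (0.004, 0.004)}
    manifest, sheet, panel, truth, matrix, _p, _b = generate_dataset(gen, seeds[2])
    result = analyze_cohort(matrix, manifest, sheet, panel, moderate=moderate)
    injected = [p for p in truth.interaction_slopes
                if p in result.interaction_results.index]
    report["interaction_power"] = float(
        (result.interaction_results.loc[injected, "p"] < 0.05).mean())

    # --- hypermethylated fraction ------------------------------------------
    gen = {"n_probes": 24000, "n_chroms": 8, "n_dmrs": 200,
           "delta_beta_range": (0.08, 0.12), "hyper_fraction": 0.78}
    manifest, sheet, panel, truth, matrix, _p, _b = generate_dataset(gen, seeds[3])
    result = analyze_cohort(matrix, manifest, sheet, panel, interaction=False,
                            moderate=moderate)
    report["hyper_fraction_called"] = hypermethylated_fraction(result.dmrs)
    report["hyper_fraction_truth"] = (
        sum(1 for d in truth.dmrs if d.direction > 0) / len(truth.dmrs))
    return report
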