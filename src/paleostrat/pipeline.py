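"""Seeded simulate -> analyze -> report pipeline.

One YAML/dict config with a single seed drives every stage; the report
bundle (machine-readable JSON plus a Markdown summary) aggregates the
module outputs: the relative-pair cross-cemetery table, the X-vs-autosome
sex-bias table, the ancestry-outlier list, admixture-date estimates, and
cemetery cladality verdicts. The config hash is recorded in every output
so a report can always be traced to the exact run that produced it.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np

from . import admixture, dating, fstats, kinship
from .data import partition_compartments
from .simulate import (SOURCE_NILOTIC, SOURCE_WE, TARGET, SimulationConfig,
                       simulate_admixed_cohort, write_simulation)

logger = logging.getLogger(__name__)

KNOWN_KEYS = {
    "seed", "out_dir", "simulate", "thresholds", "kinship", "dating",
    "stages", "write_files",
}
DEFAULT_THRESHOLDS = {"f3_z": 7.5, "outlier_z": 5.0, "clade_alpha": 0.05,
                      "date_valid_z": 2.8}
DEFAULT_STAGES = ["simulate", "fstats", "outliers", "qpadm", "qpwave",
                  "kinship", "dates", "report"]


def validate_config(config: dict) -> dict:
    unknown = set(config) - KNOWN_KEYS
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "seed" not in config:
        raise ValueError("config must set a seed")
    return config


def config_hash(config: dict) -> str:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_pipeline(config: dict, out_dir=None) -> dict:
    """Execute the configured stages in dependency order.

    Returns the report dict; when ``out_dir`` is set, writes
    ``report.json``, ``report.md`` and (optionally) the simulated dataset
    there. A stage failure raises with the stage named; previously
    completed outputs remain in the report dict.
    """
    validate_config(config)
    thresholds = {**DEFAULT_THRESHOLDS, **config.get("thresholds", {})}
    stages = config.get("stages", DEFAULT_STAGES)
    chash = config_hash(config)
    report = {"config_hash": chash, "seed": config["seed"], "stages": {}}

    sim_kwargs = dict(config.get("simulate", {}))
    sim_kwargs["seed"] = config["seed"]
    if "relative_plan" in sim_kwargs:
        sim_kwargs["relative_plan"] = [
            (int(d), tuple(c)) for d, c in sim_kwargs["relative_plan"]]
    if "cemetery_split" in sim_kwargs:
        sim_kwargs["cemetery_split"] = tuple(sim_kwargs["cemetery_split"])
    sim_config = SimulationConfig(**sim_kwargs)

    dataset = truth = None
    auto = None
    references = None

    def stage(name):
        return name in stages

    try:
        if stage("simulate"):
            dataset, truth = simulate_admixed_cohort(sim_config)
            auto = partition_compartments(dataset)["autosomes"]
            references = [f"Out{j + 1}" for j in range(sim_config.n_outgroups)]
            report["stages"]["simulate"] = {
                "n_individuals": dataset.n_individuals,
                "n_snps": dataset.n_snps,
                "n_target": sim_config.n_target_individuals,
            }
            if out_dir is not None and config.get("write_files", False):
                write_simulation(dataset, truth, Path(out_dir) / "simulated")
        if dataset is None:
            raise ValueError("analysis stages require the simulate stage")

        target_idx = auto.group_indices(TARGET)
        cem = auto.individuals["cemetery"].to_numpy()
        grp = auto.individuals["group"].to_numpy()
        idx_r = np.flatnonzero((grp == TARGET) & (cem == "R"))
        idx_s = np.flatnonzero((grp == TARGET) & (cem == "S"))

        if stage("fstats"):
            f3 = fstats.f3_admixture_test(auto, TARGET, SOURCE_NILOTIC,
                                          SOURCE_WE)
            fst = fstats.fst_hudson(auto, idx_r, idx_s)
            report["stages"]["fstats"] = {
                "admixture_f3": asdict(f3) | {"z": f3.z_score},
                "f3_significant": f3.z_score < -thresholds["f3_z"],
                "fst_r_vs_s": asdict(fst) | {"z": fst.z_score},
            }
        if stage("outliers"):
            scan = fstats.f4_outlier_scan(auto, SOURCE_NILOTIC, SOURCE_WE,
                                          TARGET,
                                          z_threshold=thresholds["outlier_z"])
            report["stages"]["outliers"] = {
                "n_flagged": sum(r["outlier"] for r in scan),
                "flagged": [r["individual_id"] for r in scan if r["outlier"]],
                "z_scores": {r["individual_id"]:
                             (r["result"].z_score if r["scorable"] else None)
                             for r in scan},
            }
        if stage("qpadm"):
            sexbias = admixture.estimate_sex_bias(
                dataset, TARGET, [SOURCE_NILOTIC, SOURCE_WE], references)
            fa = sexbias.fit_auto
            report["stages"]["qpadm"] = {
                "weights_autosomes": list(fa.weights),
                "std_errors": list(fa.std_errors),
                "model_p": fa.p_value,
                "sex_bias": {
                    "p_auto": sexbias.p_auto, "se_auto": sexbias.se_auto,
                    "p_x": sexbias.p_x, "se_x": sexbias.se_x,
                    "z": sexbias.z_score, "F": sexbias.F, "M": sexbias.M,
                    "P_female_fraction": sexbias.P,
                    "P_ci95": list(sexbias.P_ci),
                    "poor_x_fit": sexbias.poor_x_fit,
                },
            }
        if stage("qpwave"):
            clade = admixture.qpwave_clade_test(auto, idx_r, idx_s, references)
            report["stages"]["qpwave"] = clade
        if stage("kinship"):
            kin_cfg = config.get("kinship", {})
            pairs = kinship.pairwise_mismatch(
                dataset, min_overlap=kin_cfg.get("min_overlap", 15000),
                indices=target_idx)
            classified, baseline = kinship.classify_degrees(pairs)
            cem_of = dict(zip(dataset.individuals["individual_id"],
                              dataset.individuals["cemetery"]))
            rows = kinship.cross_cemetery_test(classified, cem_of)
            report["stages"]["kinship"] = {
                "baseline_p0": baseline,
                "n_pairs_classified": int(
                    (classified["degree_class"] != "unrelated").sum()),
                "cross_cemetery_table":
                    kinship.cross_cemetery_table(rows).to_dict("records"),
            }
        if stage("dates"):
            dat_cfg = config.get("dating", {})
            est = dating.date_estimate(
                auto, TARGET, SOURCE_NILOTIC, SOURCE_WE,
                binsize=dat_cfg.get("binsize", 0.001),
                maxdis=dat_cfg.get("maxdis", 1.0),
                start_distance=dat_cfg.get("start_distance", 0.0045),
                label="pooled")
            report["stages"]["dates"] = {"pooled": est.report()}
    except Exception as exc:
        raise RuntimeError(
            f"pipeline stage failed ({type(exc).__name__}): {exc}") from exc

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=1, sort_keys=True, default=float)
        (out / "report.md").write_text(render_markdown(report))
    return report


def render_markdown(report: dict) -> str:
    lines = [f"# Analysis report (config {report['config_hash']}, "
             f"seed {report['seed']})", ""]
    s = report["stages"]
    if "fstats" in s:
        f3 = s["fstats"]["admixture_f3"]
        lines += ["## Admixture f3",
                  f"estimate {f3['estimate']:.5f} ± {f3['std_error']:.5f} "
                  f"(Z = {f3['z']:.1f}); "
                  f"significant: {s['fstats']['f3_significant']}", ""]
    if "qpadm" in s:
        sb = s["qpadm"]["sex_bias"]
        lines += ["## Admixture proportions and sex bias",
                  f"autosomal focal-ancestry proportion "
                  f"{sb['p_auto']:.3f} ± {sb['se_auto']:.3f}; "
                  f"X {sb['p_x']:.3f} ± {sb['se_x']:.3f}; Z {sb['z']:.2f}",
                  f"female fraction P = {sb['P_female_fraction']:.2f} "
                  f"(95% CI {sb['P_ci95'][0]:.2f}-{sb['P_ci95'][1]:.2f})", ""]
    if "qpwave" in s:
        lines += ["## Cemetery cladality",
                  f"p = {s['qpwave']['p_value']:.3f}; consistent with clade: "
                  f"{s['qpwave']['consistent_with_clade']}", ""]
    if "kinship" in s:
        lines += ["## Cross-cemetery relative pairs"]
        for row in s["kinship"]["cross_cemetery_table"]:
            lines.append(
                f"- degrees {row['degrees']}: {row['cross']} cross of "
                f"{row['total_pairs']} pairs, expected "
                f"{row['expected_cross']:.2f}, binomial p = "
                f"{row['binomial_p']:.3f}")
        lines.append("")
    if "dates" in s:
        d = s["dates"]["pooled"]
        lines += ["## Admixture date",
                  f"{d['generations']:.1f} ± {d['se_generations']:.1f} "
                  f"generations (~{d['years']:.0f} years before sampling)", ""]
    if "outliers" in s:
        lines += ["## Ancestry outliers",
                  f"{s['outliers']['n_flagged']} flagged: "
                  f"{', '.join(s['outliers']['flagged']) or 'none'}", ""]
    return "\n".join(lines)
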