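"""End-to-end orchestration of the analysis pipeline.

``run_pipeline`` wires the stages together on synthetic inputs (or skips
stages on request): generate the untargeted feature table, curate it to
informative features, run the wild-type differential screen and the
root-type x genotype interaction screen, quantify the targeted
benzoxazinoid panel and its knockout reduction, compute qPCR relative
expression, run the behavioral statistics, and cross-reference enriched
identified metabolites against the behavioral-activity table. The report
is a plain nested dict (JSON-serializable); the seed of every random stage
is recorded, and the only non-reproducible field is the single top-level
timestamp.
"""

from __future__ import annotations

import json
import time
from pathlib import Path

import pandas as pd
import yaml

from . import behavior, cues, synth
from .curation import FeatureCurator, IdentificationMap
from .diffstats import DifferentialScreen, TwoWayAnovaScreen, interaction_screen
from .targeted import ddct, percent_reduction, quantify_panel

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "synth": {},  # SynthParams overrides
    "curation": {},  # FeatureCurator overrides
    "diff": {"alpha": 0.05, "fc_cut": 2.0, "p_mode": "fdr"},
    "targeted": {"reduction": 0.975, "uv_floor": 5.0},
    "qpcr": {"knockdown": 0.75},
    "behavior": {
        "enabled": True,
        "p_pref": 0.75,
        "n_dishes": 15,
        "larvae_per_dish": 6,
        "damage_effect": 0.8,
        "n_plants": 20,
    },
}


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for key, val in override.items():
        if isinstance(val, dict) and isinstance(out.get(key), dict):
            out[key] = _merge(out[key], val)
        else:
            out[key] = val
    return out


def load_config(path: str | Path | None) -> dict:
    if path is None:
        return dict(DEFAULT_CONFIG)
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    return _merge(DEFAULT_CONFIG, user)


def run_pipeline(
    config: dict | str | Path | None = None,
    seed: int | None = None,
    out_dir: str | Path | None = None,
) -> dict:
    """Run every stage and return the machine-readable report dict."""
    cfg = load_config(config) if not isinstance(config, dict) else _merge(
        DEFAULT_CONFIG, config
    )
    if seed is not None:
        cfg["seed"] = int(seed)
    seed = int(cfg["seed"])
    report: dict = {"seed": seed, "stages": {}}
    t0 = time.time()

    # ---- synthesis + curation -------------------------------------------
    identified = cues.load_identified_metabolites()
    params = synth.SynthParams(seed=seed, **cfg["synth"])
    table, truth = synth.generate_feature_table(params, identified=identified)
    ident_map = IdentificationMap(synth.identification_table(truth))

    curator = FeatureCurator(**cfg["curation"]).fit(table, ident_map)
    informative = curator.transform()
    rep = curator.report_
    report["stages"]["curation"] = {
        "n_features": rep.n_input,
        "n_removed_rt": rep.n_removed_rt,
        "n_after_rt_filter": rep.n_after_rt,
        "n_removed_mass_decimal": rep.n_removed_decimal,
        "n_informative": rep.n_informative,
    }

    # ---- wild-type differential screen ----------------------------------
    screen = DifferentialScreen(
        sample_filter={"genotype": "WT"}, **cfg["diff"]
    ).fit(informative)
    report["stages"]["differential"] = {"class_counts": screen.class_counts_}

    # ---- interaction screen ---------------------------------------------
    anova = TwoWayAnovaScreen().fit(informative)
    compound_of = curator.compound_of_representative()
    inter = interaction_screen(
        anova.results_, identified_ids=list(compound_of), alpha=cfg["diff"]["alpha"]
    )
    report["stages"]["interaction"] = {
        "n_interaction": inter["n_interaction"],
        "n_genotype": inter["n_genotype"],
    }

    # ---- candidate cues --------------------------------------------------
    results = screen.results_
    enriched_ids = results.index[results["enrichment"] == "postembryonic_enriched"]
    enriched = (
        pd.DataFrame(
            {
                "compound": [compound_of[f] for f in enriched_ids if f in compound_of],
            }
        )
        .assign(direction="postembryonic")
    )
    candidates = cues.cross_reference(enriched)
    report["stages"]["cues"] = {
        "n_enriched_identified": len(enriched),
        "candidates": sorted(candidates["compound"].tolist()),
        "n_candidates": len(candidates),
    }

    # ---- targeted panel --------------------------------------------------
    tcfg = dict(cfg["targeted"])
    uv_floor = tcfg.pop("uv_floor", None)
    panel = synth.generate_targeted_panel(seed, **tcfg)
    quant = quantify_panel(
        panel["panel"], panel["standards"], uv_floor=uv_floor,
        extract_volume_ml=panel["truth"]["extract_volume_ml"],
        curve_fallback={"DIM2BOA-Glc": "DIMBOA-Glc"},
    )
    red = percent_reduction(
        quant[quant["genotype"] == "WT"], quant[quant["genotype"] == "bx1"]
    )
    report["stages"]["targeted"] = {
        "percent_reduction_total": red.overall_pct,
        "percent_reduction_by_root_type": red.by_root_type,
        "percent_reduction_by_compound": red.by_compound,
    }

    # ---- qPCR ------------------------------------------------------------
    qpcr = synth.generate_qpcr(seed, **cfg["qpcr"])
    _, qsum = ddct(qpcr, control_group="control")
    report["stages"]["qpcr"] = {
        "percent_knockdown": qsum["percent_knockdown"],
        "group_mean_expression": qsum["group_mean_expression"],
    }

    # ---- behavior --------------------------------------------------------
    bcfg = dict(cfg["behavior"])
    if bcfg.pop("enabled", True):
        choice = synth.generate_behavior_data(
            seed, n_dishes=bcfg["n_dishes"], larvae_per_dish=bcfg["larvae_per_dish"],
            p_pref=bcfg["p_pref"],
        )
        pref = behavior.preference_test(choice)
        damage = synth.generate_damage_scores(
            seed, n_plants=bcfg["n_plants"], effect=bcfg["damage_effect"]
        )
        droot = behavior.damage_roottype_test(damage)
        report["stages"]["behavior"] = {
            "preference": pref.drop(columns=["method"]).to_dict("records"),
            "damage_roottype_p": droot["p"],
            "damage_statistic": droot["statistic"],
        }
    else:
        report["stages"]["behavior"] = {"skipped": True}

    report["runtime_s"] = round(time.time() - t0, 2)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / "report.json").write_text(
            json.dumps(
                report, indent=1,
                default=lambda o: o.item() if hasattr(o, "item") else str(o),
            )
        )
        screen.results_.to_csv(out_dir / "differential_results.csv")
        anova.results_.to_csv(out_dir / "anova_results.csv")
        candidates.to_csv(out_dir / "candidate_cues.csv", index=False)
    return report
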