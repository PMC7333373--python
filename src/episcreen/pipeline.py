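"""End-to-end orchestration: dichotomize -> LCC adjust -> entropy screen ->
regression comparison -> post-hoc -> network export.

:func:`run_pipeline` drives the whole analysis from a config mapping and
writes a deterministic artifact tree (tables as CSV, reports as JSON, a
run manifest with every seed and threshold).  All stage randomness is
derived from the single master seed, so a rerun with the same config is
byte-identical.
"""

from __future__ import annotations

import json
import logging
from itertools import combinations
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import __version__
from .cohort import (DichotomizationRule, DiscreteCohort, PREDICTORS, classify_responder,
                     compute_bdr, dichotomize_median, dichotomize_threshold, eod_any,
                     exclude_bdr_outliers, load_cohort, ses_composite, write_codebook)
from .lcc import lcc_subsample
from .network import build_network, export_network
from .permutation import run_screen
from .posthoc import assign_groups, descriptive_table, group_proportion_tests, group_summary
from .regression import benchmark_models
from .simulate import CohortSpec, PenetranceSpec, generate_cohort

logger = logging.getLogger(__name__)

__all__ = ["dichotomize_raw", "run_pipeline", "spec_from_config"]

#: fixed cutoffs of the coding scheme
AFR_CUTOFF = 0.80        # national-average global African ancestry
BMI_OBESE_PCTILE = 95.0  # CDC obese classification


def dichotomize_raw(raw: pd.DataFrame, ses_cutoff: int = 1, outlier_k: float = 4.0,
                    ) -> tuple[DiscreteCohort, list[DichotomizationRule]]:
    """Code a raw phenotype table into a binary cohort, recording rules.

    Expected columns: ``participant_id, sex, age_years, afr_ancestry,
    bmi_pctile, eod_q1..eod_q4, ses_mother_edu, ses_insurance, ses_income,
    no2, bdr_pct``.  Rows with missing fields are dropped (complete-case);
    BDR outliers outside mean +/- ``outlier_k``*SD are excluded.
    """
    df = raw.dropna().reset_index(drop=True)
    kept, outlier_log = exclude_bdr_outliers(df["bdr_pct"].to_numpy(), k=outlier_k)
    df = df.iloc[kept].reset_index(drop=True)
    rules: list[DichotomizationRule] = []

    age_codes, age_rule = dichotomize_median(df["age_years"].to_numpy(), variable="age_hi")
    rules.append(age_rule)
    no2_codes, no2_rule = dichotomize_median(df["no2"].to_numpy(), variable="no2_hi")
    rules.append(no2_rule)
    afr_codes = dichotomize_threshold(df["afr_ancestry"].to_numpy(), AFR_CUTOFF,
                                      variable="afr_hi")
    rules.append(DichotomizationRule("afr_hi", "fixed_threshold", AFR_CUTOFF, "ge->1"))
    bmi_codes = dichotomize_threshold(df["bmi_pctile"].to_numpy(), BMI_OBESE_PCTILE,
                                      variable="bmi_obese")
    rules.append(DichotomizationRule("bmi_obese", "fixed_threshold", BMI_OBESE_PCTILE, "ge->1"))
    eod_codes = np.array([eod_any(row) for row in
                          df[["eod_q1", "eod_q2", "eod_q3", "eod_q4"]].to_numpy(dtype=np.int64)])
    rules.append(DichotomizationRule("eod_any", "any_affirmative"))
    ses_medhigh = np.array([ses_composite(int(e), int(i), int(c), low_cutoff=ses_cutoff)
                            for e, i, c in df[["ses_mother_edu", "ses_insurance",
                                               "ses_income"]].to_numpy()])
    rules.append(DichotomizationRule("ses_low", "composite_ses", float(ses_cutoff)))

    out = pd.DataFrame({
        "participant_id": df["participant_id"].astype(str),
        "outcome": [classify_responder(v) for v in df["bdr_pct"]],
        "sex": df["sex"].astype(np.int64),
        "age_hi": age_codes.astype(np.int64),
        "afr_hi": afr_codes.astype(np.int64),
        "bmi_obese": bmi_codes.astype(np.int64),
        "eod_any": eod_codes.astype(np.int64),
        "pse": df["pse"].astype(np.int64) if "pse" in df else 0,
        "ses_low": (1 - ses_medhigh).astype(np.int64),
        "no2_hi": no2_codes.astype(np.int64),
        "age_years": df["age_years"].astype(float),
        "bdr_pct": df["bdr_pct"].astype(float),
    })
    cohort = DiscreteCohort(out, meta={"ses_cutoff": ses_cutoff, "outlier_k": outlier_k,
                                       "outliers_excluded": outlier_log})
    return cohort, rules


def spec_from_config(cfg: dict, seed: int) -> CohortSpec:
    """Build a CohortSpec from the ``synthetic`` section of a config."""
    pens = []
    for item in cfg.get("penetrance", []):
        table = {tuple(int(ch) for ch in key): float(v)
                 for key, v in item["table"].items()}
        pens.append(PenetranceSpec(tuple(item["predictors"]), table))
    kwargs = {k: cfg[k] for k in ("n", "baseline", "age_mean", "age_sd", "beta_age")
              if k in cfg}
    if "prevalences" in cfg:
        kwargs["prevalences"] = dict(cfg["prevalences"])
    return CohortSpec(penetrance=pens, seed=seed, **kwargs)


def _child_seeds(master: int, k: int) -> list[int]:
    ss = np.random.SeedSequence(master)
    return [int(c.generate_state(1)[0] % (2 ** 31)) for c in ss.spawn(k)]


def _screen_tables(cohort: DiscreteCohort, out: Path, label: str, B: int,
                   seeds: list[int], orders=(1, 2, 3),
                   predictors: Optional[list[str]] = None) -> dict[int, pd.DataFrame]:
    tables = {}
    for order, seed in zip(orders, seeds):
        df = run_screen(cohort, order=order, B=B, seed=seed, predictors=predictors)
        name = {1: "main", 2: "pairwise", 3: "threeway"}[order]
        path = out / f"screen_{name}_{label}.csv"
        df.to_csv(path, index=False, float_format="%.10g")
        tables[order] = df
    return tables


def run_pipeline(config: dict, out_dir: str | Path) -> dict:
    """Run the full analysis described by ``config``; returns the manifest.

    Config keys (all optional unless noted): ``cohort`` (either
    ``{"csv": path}`` or ``{"synthetic": {...}}``; required), ``seed``,
    ``permutations``, ``adjust`` (``{"enabled": bool, "confounders": [...]}``),
    ``stratify_by_sex``, ``regression``, ``posthoc_pair``.

    On a stage failure the manifest records the stage and reason and later
    stages are skipped.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    master_seed = int(config.get("seed", 0))
    B = int(config.get("permutations", 1000))
    seeds = _child_seeds(master_seed, 12)
    manifest: dict = {"version": __version__, "seed": master_seed, "permutations": B,
                      "config": config, "stages": [], "outputs": {}}

    def record(stage: str, status: str, **extra) -> None:
        manifest["stages"].append({"stage": stage, "status": status, **extra})
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))

    try:
        cohort_cfg = config["cohort"]
        if "csv" in cohort_cfg:
            cohort = load_cohort(cohort_cfg["csv"])
        else:
            spec = spec_from_config(cohort_cfg.get("synthetic", {}), seed=seeds[0])
            cohort = generate_cohort(spec)
        cohort.to_csv(out / "cohort_input.csv")
        manifest["outputs"]["cohort_input"] = "cohort_input.csv"
        record("cohort", "ok", n=len(cohort))
    except Exception as exc:  # noqa: BLE001 - manifest must record any failure
        record("cohort", "failed", reason=repr(exc))
        return manifest

    adjust_cfg = config.get("adjust", {"enabled": True})
    analysis = cohort
    if adjust_cfg.get("enabled", True):
        try:
            confounders = adjust_cfg.get("confounders", ["age_years"])
            draw = lcc_subsample(cohort, confounders=confounders, seed=seeds[1])
            analysis = draw.cohort
            analysis.to_csv(out / "cohort_adjusted.csv")
            (out / "lcc_report.json").write_text(
                json.dumps(draw.report(), indent=2, default=str))
            manifest["outputs"]["lcc_report"] = "lcc_report.json"
            record("adjust", "ok", n_kept=draw.n_kept)
        except Exception as exc:
            record("adjust", "failed", reason=repr(exc))
            return manifest

    try:
        tables = _screen_tables(analysis, out, "full", B, seeds[2:5])
        strata_tables = {}
        if config.get("stratify_by_sex", False):
            names = [p for p in analysis.predictors if p != "sex"]
            for label, value, seed_block in (("female", 1, seeds[5:8]),
                                             ("male", 0, seeds[8:11])):
                sub = analysis.subset(
                    np.flatnonzero(analysis.data["sex"].to_numpy() == value))
                strata_tables[label] = _screen_tables(sub, out, label, B, seed_block,
                                                      predictors=names)
        descriptive_table(analysis, B=B, seed=seeds[2]).to_csv(
            out / "descriptive_table.csv", index=False, float_format="%.10g")
        record("screen", "ok", n_models={o: len(t) for o, t in tables.items()})
    except Exception as exc:
        record("screen", "failed", reason=repr(exc))
        return manifest

    hits = pd.concat([tables[2], tables[3]])
    hits = hits[hits["p_value"] <= config.get("regression_p_cut", 0.05)]
    if config.get("regression", True) and len(hits):
        try:
            models = [tuple(v.split(" x ")) for v in hits["variables"]]
            bench = benchmark_models(analysis, models)
            merged = hits.reset_index(drop=True).merge(
                bench, on=["variables", "order"], suffixes=("_ig", "_regression"))
            merged.to_csv(out / "regression_comparison.csv", index=False,
                          float_format="%.10g")
            manifest["outputs"]["regression"] = "regression_comparison.csv"
            record("regress", "ok", n_models=len(models))
        except Exception as exc:
            record("regress", "failed", reason=repr(exc))
            return manifest
    else:
        record("regress", "skipped", reason="no screen hits or disabled")

    try:
        pair = config.get("posthoc_pair")
        if pair is None:
            sig = tables[2][tables[2]["significance"] == "significant"]
            pair = sig.iloc[0]["variables"].split(" x ") if len(sig) else None
        if pair is not None:
            v1, v2 = pair
            # orient the second variable so that 1 = med/high when it is the
            # low-coded SES column
            v2_vals = analysis.data[v2].to_numpy()
            if v2 == "ses_low":
                v2_vals = 1 - v2_vals
            groups = assign_groups(analysis.data[v1].to_numpy(), v2_vals)
            summary = group_summary(analysis.data["bdr_pct"].to_numpy(), groups,
                                    sex=analysis.data["sex"].to_numpy())
            summary.to_csv(out / "posthoc_groups.csv", index=False, float_format="%.10g")
            comps = list(combinations(sorted(np.unique(groups)), 2))
            tests = group_proportion_tests(analysis.outcome, groups, comps)
            tests.to_csv(out / "posthoc_proportion_tests.csv", index=False,
                         float_format="%.10g")
            manifest["outputs"]["posthoc"] = "posthoc_groups.csv"
            record("posthoc", "ok", pair=list(pair))
        else:
            record("posthoc", "skipped", reason="no significant pairwise model")
    except Exception as exc:
        record("posthoc", "failed", reason=repr(exc))
        return manifest

    try:
        net = build_network(tables[1], tables[2], tables[3])
        for fmt, suffix in (("JSON", "json"), ("GraphML", "graphml"), ("DOT", "dot")):
            export_network(net, out / f"network.{suffix}", fmt=fmt)
        manifest["outputs"]["network"] = "network.json"
        record("network", "ok", nodes=net.graph.number_of_nodes(),
               edges=net.graph.number_of_edges(), hyperedges=len(net.hyperedges))
    except Exception as exc:
        record("network", "failed", reason=repr(exc))
        return manifest

    record("done", "ok")
    return manifest
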