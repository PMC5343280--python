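"""End-to-end orchestration: simulate -> design -> quantify -> stats -> assays.

``run_pipeline`` is deterministic given the seed and writes a tidy CSV
bundle plus a JSON run log (config hash, package and library versions).
The intermediate helpers are plain functions over DataFrames so the
analysis drivers, tests, and the acceptance script can reuse each stage.
"""

from __future__ import annotations

import hashlib
import json
import sys
from dataclasses import dataclass, field, asdict
from functools import lru_cache
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import __version__
from .assays import coupling_params, electron_flow_params, specific_activity
from .mrm import (
    GLYCOLYTIC_ANALYTES,
    TCA_ANALYTES,
    design_transitions,
    emit_transition_table,
    turn_shifts,
)
from .network import build_network
from .pathway import propagate
from .quantify import concentration_table, enrichment_table
from .simulate import CohortConfig, GeneratorOutput, generate_cohort, U13C_GLUCOSE
from .stats import fisher_lsd, pearson, two_way_anova, unpaired_t

__all__ = [
    "RunConfig",
    "run_pipeline",
    "replicate_recovery",
    "enzyme_activity_table",
    "mito_param_table",
    "enrichment_anova_report",
    "correlation_report",
    "group_reduction",
]


@dataclass
class RunConfig:
    out_dir: str | Path = "results/run"
    seed: int = 0
    alpha: float = 0.05
    cohort: CohortConfig = field(default_factory=CohortConfig)

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        self.cohort.seed = self.seed


def enzyme_activity_table(enzyme_traces: list[dict[str, Any]]) -> pd.DataFrame:
    """Fit every kinetic trace; one row per sample x enzyme."""
    rows = []
    for item in enzyme_traces:
        res = specific_activity(item["trace"], item["epsilon"])
        rows.append({
            "sample": item["sample"], "group": item["group"],
            "enzyme": item["enzyme"], "activity": res.specific_activity,
            "r_squared": res.r_squared, "flag": res.flag,
        })
    return pd.DataFrame(rows)


def mito_param_table(ocr_profiles: list[dict[str, Any]]) -> pd.DataFrame:
    """Respiration parameters, one row per sample x assay x parameter."""
    rows = []
    for item in ocr_profiles:
        params = (
            coupling_params(item["profile"])
            if item["assay"] == "coupling"
            else electron_flow_params(item["profile"])
        )
        for name, value in params.values.items():
            rows.append({
                "sample": item["sample"], "group": item["group"],
                "assay": item["assay"], "parameter": name, "value": value,
                "flag": params.flag,
            })
    return pd.DataFrame(rows)


def ocr_long_table(ocr_profiles: list[dict[str, Any]]) -> pd.DataFrame:
    """Serialize OCR profiles to a tidy frame (one row per stage reading)."""
    rows = []
    for item in ocr_profiles:
        for stage, value in item["profile"].stages.items():
            rows.append({"sample": item["sample"], "group": item["group"],
                         "assay": item["assay"], "stage": stage, "value": value,
                         "protein_mg": item["profile"].protein_mg})
    return pd.DataFrame(rows)


def parse_ocr_table(df: pd.DataFrame) -> list[dict[str, Any]]:
    """Inverse of :func:`ocr_long_table`."""
    from .assays import OCRProfile

    out = []
    for (smp, group, assay), block in df.groupby(["sample", "group", "assay"]):
        stages = dict(zip(block["stage"], block["value"]))
        out.append({"sample": smp, "group": group, "assay": assay,
                    "profile": OCRProfile(assay, stages, float(block["protein_mg"].iloc[0]))})
    return out


def traces_long_table(enzyme_traces: list[dict[str, Any]]) -> pd.DataFrame:
    """Serialize kinetic traces to a tidy frame (one row per reading)."""
    rows = []
    for item in enzyme_traces:
        tr = item["trace"]
        for t, a in zip(tr.times_s, tr.absorbances):
            rows.append({
                "sample": item["sample"], "group": item["group"],
                "enzyme": item["enzyme"], "epsilon": item["epsilon"],
                "time_s": t, "absorbance": a,
                "path_length_cm": tr.path_length_cm, "protein_mg": tr.protein_mg,
                "volume_ml": tr.volume_ml, "direction": tr.direction,
            })
    return pd.DataFrame(rows)


def parse_traces_table(df: pd.DataFrame) -> list[dict[str, Any]]:
    """Inverse of :func:`traces_long_table`."""
    from .assays import KineticTrace

    out = []
    for (smp, group, enzyme), block in df.groupby(["sample", "group", "enzyme"]):
        block = block.sort_values("time_s")
        first = block.iloc[0]
        out.append({
            "sample": smp, "group": group, "enzyme": enzyme,
            "epsilon": float(first["epsilon"]),
            "trace": KineticTrace(
                block["time_s"].to_numpy(), block["absorbance"].to_numpy(),
                340.0, float(first["path_length_cm"]), float(first["protein_mg"]),
                float(first["volume_ml"]), str(first["direction"]),
            ),
        })
    return out


PANELS = {
    "glycolysis": [(m, 1) for m in GLYCOLYTIC_ANALYTES],
    "tca_turn1": [(m, 1) for m in TCA_ANALYTES],
    "tca_turn2": [(m, 2) for m in TCA_ANALYTES],
}


def enrichment_anova_report(
    enrich: pd.DataFrame, meta: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Two-way ANOVA (group x metabolite) + LSD posttests per panel."""
    merged = enrich.merge(meta[["sample", "group"]], on="sample").dropna(
        subset=["enrichment"]
    )
    anova_rows, lsd_rows = [], []
    for panel, keys in PANELS.items():
        sel = merged[
            merged[["metabolite", "turn"]].apply(tuple, axis=1).isin(keys)
        ].rename(columns={"enrichment": "value"})
        res = two_way_anova(sel)
        for name, eff in res.effects.items():
            anova_rows.append({"panel": panel, "effect": name, "ss": eff.ss,
                               "df": eff.df, "F": eff.f, "p": eff.p})
        for post in fisher_lsd(res, sel):
            lsd_rows.append({"panel": panel, "metabolite": post.metabolite,
                             "mean_diff": post.mean_diff, "t": post.t,
                             "df": post.df, "p": post.p})
    return pd.DataFrame(anova_rows), pd.DataFrame(lsd_rows)


def correlation_report(enrich: pd.DataFrame, meta: pd.DataFrame) -> pd.DataFrame:
    """The study's correlation battery, per group: G6P vs downstream
    glycolytic enrichment, PYR vs first-turn TCA enrichment, first-turn
    2OG vs SUC, and body weight vs G6P."""
    wide = (
        enrich[enrich["turn"] == 1]
        .pivot(index="sample", columns="metabolite", values="enrichment")
        .join(meta.set_index("sample")[["group", "body_weight_g"]])
    )
    rows = []

    def corr(group: str, xname: str, yname: str, x, y) -> None:
        ok = x.notna() & y.notna()
        res = pearson(x[ok], y[ok])
        rows.append({"group": group, "x": xname, "y": yname, "r": res.r,
                     "n": res.n, "p": res.p, "flag": res.flag})

    for group, block in wide.groupby("group"):
        for met in GLYCOLYTIC_ANALYTES:
            if met != "G6P":
                corr(group, "G6P", met, block["G6P"], block[met])
        for met in TCA_ANALYTES:
            corr(group, "PYR", met, block["PYR"], block[met])
        corr(group, "OG2", "SUC", block["OG2"], block["SUC"])
        corr(group, "body_weight", "G6P", block["body_weight_g"], block["G6P"])
    return pd.DataFrame(rows)


def group_reduction(table: pd.DataFrame, value_col: str) -> float:
    """Percent reduction of the SE group mean relative to No SE."""
    means = table.groupby("group")[value_col].mean()
    return float(100.0 * (1.0 - means["SE"] / means["NoSE"]))


def _ttest_report(table: pd.DataFrame, value_col: str, by: list[str]) -> pd.DataFrame:
    rows = []
    for key, block in table.groupby(by):
        x = block.loc[block["group"] == "NoSE", value_col].dropna()
        y = block.loc[block["group"] == "SE", value_col].dropna()
        res = unpaired_t(x, y)
        row = dict(zip(by, key if isinstance(key, tuple) else (key,)))
        row.update({"mean_NoSE": res.means[0], "mean_SE": res.means[1],
                    "t": res.t, "df": res.df, "p": res.p, "flag": res.flag})
        rows.append(row)
    return pd.DataFrame(rows)


@lru_cache(maxsize=1)
def _default_shifts():
    return turn_shifts(propagate(build_network(), U13C_GLUCOSE, 2))


def replicate_recovery(seed: int, config: CohortConfig | None = None) -> dict[str, float]:
    """One generator round trip: simulate a cohort, run the quantification
    and assay stages, and recover the headline quantities (percent
    reductions of G6P enrichment and PDH/OGDH activity in the SE group, and
    the No SE first-turn 2OG-SUC Pearson r)."""
    config = config or CohortConfig()
    config.seed = seed
    cohort = generate_cohort(config)
    enrich = enrichment_table(cohort.peaks, _default_shifts()).merge(
        cohort.meta[["sample", "group"]], on="sample"
    )
    g6p = enrich[(enrich.metabolite == "G6P") & (enrich.turn == 1)]
    nose = enrich[(enrich.group == "NoSE") & (enrich.turn == 1)]
    wide = nose.pivot(index="sample", columns="metabolite", values="enrichment")
    activities = enzyme_activity_table(cohort.enzyme_traces)
    return {
        "g6p_reduction_pct": group_reduction(g6p, "enrichment"),
        "pdh_reduction_pct": group_reduction(
            activities[activities.enzyme == "PDH"], "activity"),
        "ogdh_reduction_pct": group_reduction(
            activities[activities.enzyme == "OGDH"], "activity"),
        "og2_suc_r_nose": pearson(wide["OG2"], wide["SUC"]).r,
    }


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Run the full analysis on a freshly generated synthetic cohort and
    write the results bundle under ``config.out_dir``."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    cohort: GeneratorOutput = generate_cohort(config.cohort)
    network = build_network()
    prop = propagate(network, U13C_GLUCOSE, 2)
    specs = design_transitions(prop)
    emit_transition_table(specs, out / "transitions.csv")

    cohort.peaks.to_csv(out / "peaks.csv", index=False)
    cohort.meta.to_csv(out / "sample_meta.csv", index=False)
    (out / "ground_truth.json").write_text(json.dumps(cohort.truth, indent=1))

    shifts = turn_shifts(prop)
    enrich = enrichment_table(cohort.peaks, shifts)
    enrich.to_csv(out / "enrichment.csv", index=False)
    conc = concentration_table(cohort.peaks, cohort.meta,
                               config.cohort.response_factors,
                               config.cohort.is_amount_nmol)
    conc.to_csv(out / "concentrations.csv", index=False)

    anova, lsd = enrichment_anova_report(enrich, cohort.meta)
    anova.to_csv(out / "anova_enrichment.csv", index=False)
    lsd.to_csv(out / "lsd_enrichment.csv", index=False)

    conc_tbl = conc.merge(cohort.meta[["sample", "group"]], on="sample").rename(
        columns={"concentration": "value"}
    )
    conc_anova = two_way_anova(conc_tbl)
    conc_anova.to_frame().to_csv(out / "anova_concentration.csv", index=False)
    pd.DataFrame(
        [vars(p) for p in fisher_lsd(conc_anova, conc_tbl)]
    ).to_csv(out / "lsd_concentration.csv", index=False)

    corr = correlation_report(enrich, cohort.meta)
    corr.to_csv(out / "correlations.csv", index=False)

    activities = enzyme_activity_table(cohort.enzyme_traces)
    activities.to_csv(out / "enzyme_activities.csv", index=False)
    enzyme_tests = _ttest_report(activities, "activity", ["enzyme"])
    enzyme_tests.to_csv(out / "enzyme_ttests.csv", index=False)

    traces_long_table(cohort.enzyme_traces).to_csv(out / "enzyme_traces.csv", index=False)
    ocr_long_table(cohort.ocr_profiles).to_csv(out / "ocr_profiles.csv", index=False)

    mito = mito_param_table(cohort.ocr_profiles)
    mito.to_csv(out / "mito_params.csv", index=False)
    mito_tests = _ttest_report(mito, "value", ["assay", "parameter"])
    mito_tests.to_csv(out / "mito_ttests.csv", index=False)

    cfg_repr = repr(sorted(asdict(config.cohort).items(), key=lambda kv: kv[0]))
    log = {
        "glucotrace_version": __version__,
        "python": sys.version.split()[0],
        "numpy": np.__version__,
        "pandas": pd.__version__,
        "seed": config.seed,
        "alpha": config.alpha,
        "config_sha256": hashlib.sha256(cfg_repr.encode()).hexdigest(),
        "outputs": sorted(p.name for p in out.glob("*.csv")),
    }
    (out / "run_log.json").write_text(json.dumps(log, indent=1))

    return {
        "cohort": cohort,
        "enrichment": enrich,
        "concentrations": conc,
        "anova": anova,
        "lsd": lsd,
        "correlations": corr,
        "activities": activities,
        "enzyme_ttests": enzyme_tests,
        "mito_params": mito,
        "mito_ttests": mito_tests,
        "transitions": specs,
        "out_dir": out,
    }
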