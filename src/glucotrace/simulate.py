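"""Seeded synthetic-cohort generator.

Emulates the study's cohort structure so every pipeline stage is testable
without real data: two groups (11 No SE / 10 SE mice), per-animal latent
glucose-uptake factors that make all glycolytic enrichments co-vary, a
pyruvate-driven coupling of first-turn TCA enrichments in the No SE group
(replaced in SE animals by an independent mitochondrial-capacity factor,
which destroys those correlations), a tight 2-oxoglutarate -> succinate
transfer coupling, group effect sizes from the reported percent reductions,
total concentrations drawn around the reported group means, lognormal
peak-area noise, enzyme activity losses (PDH/OGDH), and null group
differences for all respirometry parameters.

Every latent value is recorded in a ground-truth log sufficient to
recompute each expected quantity.  A fixed seed gives identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Any

import numpy as np
import pandas as pd

from .assays import EPSILON_NADH, EPSILON_TNB, KineticTrace, OCRProfile
from .mrm import FRAGMENT_RULES, GLYCOLYTIC_ANALYTES, TCA_ANALYTES
from .network import build_network
from .pathway import IsotopomerPool, PropagationResult, propagate

__all__ = [
    "EffectTable",
    "CohortConfig",
    "GeneratorOutput",
    "default_effect_table",
    "generate_cohort",
    "generate_enzyme_assays",
    "generate_ocr_assays",
]

U13C_GLUCOSE = (1, 1, 1, 1, 1, 1)


@dataclass
class EffectTable:
    """Fractional reductions applied to the SE group (0 = no change)."""

    glycolysis: dict[str, float] = field(default_factory=dict)
    tca_turn1: dict[str, float] = field(default_factory=dict)
    tca_turn2: dict[str, float] = field(default_factory=dict)
    enzymes: dict[str, float] = field(default_factory=dict)
    ocr: dict[str, float] = field(default_factory=dict)

    def validate(self) -> None:
        for table in (self.glycolysis, self.tca_turn1, self.tca_turn2,
                      self.enzymes, self.ocr):
            for key, frac in table.items():
                if not 0 <= frac < 1:
                    raise ValueError(f"effect fraction for {key} outside [0, 1)")


def default_effect_table() -> EffectTable:
    """The reported group effects (figure-legend values).

    Glycolysis: G6P 22%, F6P 21%, DHAP 17%, PEP 20% reductions; TCA first
    turn: CIT/ACO 17%, SUC 35%, FUM 23%; second turn: 2OG 47%, SUC 55%,
    FUM 25%, MAL 29%; enzymes: PDH 33%, OGDH 55%; respirometry: none.
    """
    return EffectTable(
        glycolysis={"G6P": 0.22, "F6P": 0.21, "F16BP": 0.0, "DHAP": 0.17,
                    "PG23": 0.0, "PEP": 0.20, "PYR": 0.0},
        tca_turn1={"CIT": 0.17, "ACO": 0.17, "OG2": 0.0, "SUC": 0.35,
                   "FUM": 0.23, "MAL": 0.0},
        tca_turn2={"CIT": 0.0, "OG2": 0.47, "SUC": 0.55, "FUM": 0.25,
                   "MAL": 0.29},
        enzymes={"HK": 0.0, "PGI": 0.0, "PFK": 0.0, "PK": 0.0, "LDH": 0.0,
                 "G6PDH": 0.0, "CS": 0.0, "PDH": 0.33, "OGDH": 0.55,
                 "PCX": 0.0, "GDH": 0.0, "GPT": 0.0, "GOT": 0.0},
        ocr={},
    )


#: Baseline absolute enrichments (%).  The study reports only relative
#: reductions, so these are the generator's own realistic choices:
#: glycolytic intermediates well-enriched 15 min after a U-13C bolus, TCA
#: first turn lower, second turn lower still.
DEFAULT_BASELINE_ENRICHMENT: dict[tuple[str, int], float] = {
    ("G6P", 1): 28.0, ("F6P", 1): 26.0, ("F16BP", 1): 24.0, ("DHAP", 1): 22.0,
    ("PG23", 1): 18.0, ("PEP", 1): 17.0, ("PYR", 1): 15.0,
    ("CIT", 1): 8.0, ("ACO", 1): 7.0, ("OG2", 1): 6.5, ("SUC", 1): 6.0,
    ("FUM", 1): 5.5, ("MAL", 1): 6.0,
    ("CIT", 2): 3.0, ("ACO", 2): 2.8, ("OG2", 2): 2.5, ("SUC", 2): 2.2,
    ("FUM", 2): 2.0, ("MAL", 2): 2.2,
}

#: Reported group concentration summaries, nmol/g tissue:
#: metabolite -> (mean NoSE, SEM NoSE, mean SE, SEM SE).
DEFAULT_CONCENTRATIONS: dict[str, tuple[float, float, float, float]] = {
    "G6P": (20.1, 1.7, 24.2, 3.4),
    "F6P": (33.0, 2.2, 36.2, 5.9),
    "F16BP": (16.5, 1.0, 17.8, 1.4),
    "DHAP": (0.70, 0.08, 0.67, 0.08),
    "PG23": (11.2, 1.0, 10.9, 1.2),
    "PEP": (8.93, 1.42, 7.50, 1.33),
    "PYR": (38.2, 2.7, 34.2, 6.0),
    "CIT": (109.0, 5.0, 110.0, 17.0),
    "ACO": (1.84, 0.12, 2.24, 0.28),
    "OG2": (90.8, 6.5, 83.9, 17.4),
    "SUC": (10.1, 0.8, 8.1, 1.6),
    "FUM": (12.5, 0.9, 13.2, 2.7),
    "MAL": (45.9, 3.9, 46.1, 6.8),
}

#: Enzyme assay setup: name -> (baseline nmol/min/mg, extinction coefficient
#: mM^-1 cm^-1, trace direction).  MTT-formazan (PDH) uses a per-assay
#: calibration coefficient.
EPSILON_MTT = 17.0
DEFAULT_ENZYMES: dict[str, tuple[float, float, str]] = {
    "HK": (150.0, EPSILON_NADH, "increase"),
    "PGI": (800.0, EPSILON_NADH, "increase"),
    "PFK": (100.0, EPSILON_NADH, "decrease"),
    "PK": (900.0, EPSILON_NADH, "decrease"),
    "LDH": (1200.0, EPSILON_NADH, "decrease"),
    "G6PDH": (40.0, EPSILON_NADH, "increase"),
    "CS": (600.0, EPSILON_TNB, "increase"),
    "PDH": (25.0, EPSILON_MTT, "increase"),
    "OGDH": (20.0, EPSILON_NADH, "increase"),
    "PCX": (15.0, EPSILON_TNB, "increase"),
    "GDH": (300.0, EPSILON_NADH, "decrease"),
    "GPT": (50.0, EPSILON_NADH, "decrease"),
    "GOT": (400.0, EPSILON_NADH, "decrease"),
}

#: Respirometry stage baselines, pmol O2/min per well.
DEFAULT_OCR_BASELINES: dict[str, dict[str, float]] = {
    "coupling": {"state2": 60.0, "state3ADP": 300.0, "state4o": 55.0,
                 "state3u": 320.0, "nonmito": 12.0},
    "electron_flow": {"state3u": 320.0, "post_rotenone": 40.0,
                      "post_succinate": 260.0, "post_malonate": 25.0,
                      "nonmito": 12.0},
}


@dataclass
class CohortConfig:
    """Generator configuration; defaults are the study's conditions."""

    n_nose: int = 11
    n_se: int = 10
    n_enzyme_per_group: int = 8
    n_ocr_per_group: int = 7
    baseline_enrichment: dict[tuple[str, int], float] = field(
        default_factory=lambda: dict(DEFAULT_BASELINE_ENRICHMENT))
    effects: EffectTable = field(default_factory=default_effect_table)
    concentrations: dict[str, tuple[float, float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_CONCENTRATIONS))
    conc_n_assumed: int = 8  # group size behind the reported SEMs
    uptake_sd: float = 0.15  # per-animal glucose-uptake factor SD
    mito_capacity_sd: float = 0.15  # SE-only TCA driver SD
    og_suc_target_r: float = 0.95  # No SE 2OG-SUC first-turn correlation
    se_og_suc_transfer_sd: float = 0.30  # SE-only 2OG->SUC scatter
    gly_noise_cv: float = 0.05
    tca_noise_cv: float = 0.05
    area_block_cv: float = 0.10  # shared lognormal per sample x analyte
    area_transition_cv: float = 0.015  # independent per transition
    enzyme_cv: float = 0.20
    absorbance_noise_au: float = 3e-4
    ocr_animal_sd: float = 0.12
    ocr_stage_cv: float = 0.08
    is_amount_nmol: float = 4.0
    response_factors: dict[str, float] = field(default_factory=dict)
    seed: int = 0

    def validate(self) -> None:
        if min(self.n_nose, self.n_se) < 3:
            raise ValueError("need at least 3 animals per group")
        self.effects.validate()
        for (met, turn), base in self.baseline_enrichment.items():
            if not 0 <= base <= 100:
                raise ValueError(f"baseline enrichment for {met} outside [0, 100]")
        for met in TCA_ANALYTES:
            total = sum(
                self.baseline_enrichment.get((met, t), 0.0) for t in (1, 2)
            )
            if total >= 100:
                raise ValueError(f"{met}: turn-1 + turn-2 baselines exceed 100%")

    def suc_coupling_cv(self) -> float:
        """Noise CV of the No SE 2OG -> SUC transfer, solved so the induced
        sample correlation targets ``og_suc_target_r``.

        Shared relative variance between measured 2OG and SUC is the full
        realized 2OG variation S = uptake_sd^2 + gly_cv^2 + tca_cv^2; each
        measured series adds m2 ~ 2 x transition_cv^2 from the area ratio.
        Solving r = S / sqrt((S+m2)(S+c^2+m2)) for c.
        """
        s = self.uptake_sd**2 + self.gly_noise_cv**2 + self.tca_noise_cv**2
        m2 = 2.0 * self.area_transition_cv**2
        rho = self.og_suc_target_r
        if s + m2 <= 0 or rho >= 1:
            return 0.0
        c2 = s * s / (rho * rho * (s + m2)) - s - m2
        return math.sqrt(max(c2, 0.0))


@dataclass
class GeneratorOutput:
    peaks: pd.DataFrame
    meta: pd.DataFrame
    enrichment_truth: pd.DataFrame  # sample, metabolite, turn, latent %
    enzyme_traces: list[dict[str, Any]]  # sample, group, enzyme, epsilon, trace
    enzyme_truth: pd.DataFrame
    ocr_profiles: list[dict[str, Any]]  # sample, group, assay, profile
    truth: dict[str, Any]
    propagation: PropagationResult


def fragment_fractions(pool: IsotopomerPool, analyte: str) -> dict[tuple[int, int], float]:
    """Fraction of an isotopomer pool's signal landing on each (precursor
    shift, product shift) transition, assuming each allowed carboxyl loss is
    equally likely in the collision cell."""
    rule = FRAGMENT_RULES[analyte]
    out: dict[tuple[int, int], float] = {}
    for mask, w in pool.members.items():
        n = sum(mask)
        if rule.carbon_free_product:
            out[(n, 0)] = out.get((n, 0), 0.0) + w
        else:
            share = w / len(rule.lost_sets)
            for ls in rule.lost_sets:
                k = n - sum(mask[i - 1] for i in ls)
                out[(n, k)] = out.get((n, k), 0.0) + share
    return out


def _lognormal_factor(rng: np.random.Generator, cv: float, size=None):
    if cv <= 0:
        return np.ones(size) if size is not None else 1.0
    sigma = math.sqrt(math.log1p(cv * cv))
    return rng.lognormal(-0.5 * sigma * sigma, sigma, size)


def _trunc_normal(rng: np.random.Generator, mean, sd, lo, size=None):
    x = rng.normal(mean, sd, size)
    return np.maximum(x, lo)


def _latent_enrichment(config: CohortConfig, rng: np.random.Generator):
    """Latent per-animal enrichments (%) and the latent factors."""
    eff = config.effects
    base = config.baseline_enrichment
    samples, groups = [], []
    rows = []
    factors: dict[str, dict[str, float]] = {}

    for group, n in (("NoSE", config.n_nose), ("SE", config.n_se)):
        for i in range(n):
            smp = f"{group}{i + 1:02d}"
            samples.append(smp)
            groups.append(group)
            u = float(_trunc_normal(rng, 1.0, config.uptake_sd, 0.2))
            v = float(_trunc_normal(rng, 1.0, config.mito_capacity_sd, 0.2))
            z = float(_trunc_normal(rng, 1.0, config.uptake_sd, 0.2))
            factors[smp] = {"uptake": u, "mito_capacity": v, "pg23_alt": z}

            e: dict[tuple[str, int], float] = {}
            # glycolysis: all enrichments ride the uptake factor; in SE
            # animals 2+3PG decouples from uptake (independent factor).
            for met in GLYCOLYTIC_ANALYTES:
                red = eff.glycolysis.get(met, 0.0) if group == "SE" else 0.0
                driver = u
                if group == "SE" and met == "PG23":
                    driver = z
                noise = 1.0 + rng.normal(0.0, config.gly_noise_cv)
                e[(met, 1)] = base[(met, 1)] * (1 - red) * driver * max(noise, 0.05)

            pyr_rel = e[("PYR", 1)] / base[("PYR", 1)]
            tca_driver = pyr_rel if group == "NoSE" else v

            for turn, table in ((1, eff.tca_turn1), (2, eff.tca_turn2)):
                for met in TCA_ANALYTES:
                    if (met, turn) not in base:
                        continue
                    if turn == 1 and met == "SUC":
                        continue  # coupled to 2OG below
                    red = table.get(met, 0.0) if group == "SE" else 0.0
                    noise = 1.0 + rng.normal(0.0, config.tca_noise_cv)
                    e[(met, turn)] = base[(met, turn)] * (1 - red) * tca_driver * max(noise, 0.05)

            # first-turn succinate follows realized 2OG (OGDH transfer);
            # SE preparations add independent transfer scatter.
            og_red = eff.tca_turn1.get("OG2", 0.0) if group == "SE" else 0.0
            og_rel = e[("OG2", 1)] / (base[("OG2", 1)] * (1 - og_red))
            suc_red = eff.tca_turn1.get("SUC", 0.0) if group == "SE" else 0.0
            cv = config.suc_coupling_cv() if group == "NoSE" else config.se_og_suc_transfer_sd
            noise = 1.0 + rng.normal(0.0, cv)
            e[("SUC", 1)] = base[("SUC", 1)] * (1 - suc_red) * og_rel * max(noise, 0.05)

            for (met, turn), val in e.items():
                rows.append({"sample": smp, "group": group, "metabolite": met,
                             "turn": turn, "enrichment": val})
            tot = {
                met: e.get((met, 1), 0.0) + e.get((met, 2), 0.0)
                for met in GLYCOLYTIC_ANALYTES + TCA_ANALYTES
            }
            bad = [met for met, t in tot.items() if t >= 100]
            if bad:
                raise ValueError(f"configured baselines/effects give >=100% enrichment: {bad}")

    truth = pd.DataFrame(rows)
    meta = pd.DataFrame({"sample": samples, "group": groups})
    return truth, meta, factors


def _sample_meta(config: CohortConfig, meta: pd.DataFrame, rng: np.random.Generator) -> pd.DataFrame:
    # Reported body weights: 39.8 +/- 0.8 (No SE, n=11) and 39.9 +/- 1.3 g
    # (SE, n=10); SEMs converted to per-animal SDs.
    bw = {"NoSE": (39.8, 0.8 * math.sqrt(11)), "SE": (39.9, 1.3 * math.sqrt(10))}
    rows = []
    for r in meta.itertuples(index=False):
        m, sd = bw[r.group]
        rows.append({
            "sample": r.sample,
            "group": r.group,
            "body_weight_g": float(_trunc_normal(rng, m, sd, 25.0)),
            "tissue_mass_g": float(_trunc_normal(rng, 0.040, 0.004, 0.02)),
            "is_area": float(1e5 * _lognormal_factor(rng, 0.10)),
        })
    return pd.DataFrame(rows)


def _peak_records(
    config: CohortConfig,
    enr_truth: pd.DataFrame,
    meta: pd.DataFrame,
    prop: PropagationResult,
    rng: np.random.Generator,
):
    frag: dict[tuple[str, int], dict[tuple[int, int], float]] = {}
    for met in GLYCOLYTIC_ANALYTES:
        frag[(met, 1)] = fragment_fractions(prop.pool(met), met)
    for met in TCA_ANALYTES:
        for turn in (1, 2):
            frag[(met, turn)] = fragment_fractions(prop.pool(met, turn), met)

    enr = enr_truth.set_index(["sample", "metabolite", "turn"])["enrichment"]
    conc_rows = []
    rows = []
    for m in meta.itertuples(index=False):
        grp_ix = 0 if m.group == "NoSE" else 2
        for met in GLYCOLYTIC_ANALYTES + TCA_ANALYTES:
            mean, sem = config.concentrations[met][grp_ix:grp_ix + 2]
            sd = sem * math.sqrt(config.conc_n_assumed)
            conc = float(_trunc_normal(rng, mean, sd, 0.05 * mean))
            conc_rows.append({"sample": m.sample, "metabolite": met, "concentration": conc})
            rf = config.response_factors.get(met, 1.0)
            total_area = conc * m.tissue_mass_g * rf * m.is_area / config.is_amount_nmol

            turns = (1,) if met in GLYCOLYTIC_ANALYTES else (1, 2)
            fracs = {t: enr[(m.sample, met, t)] / 100.0 for t in turns}
            f0 = 1.0 - sum(fracs.values())
            block = float(_lognormal_factor(rng, config.area_block_cv))
            per_transition = {(0, 0): f0 * total_area}
            for t in turns:
                for (n, k), share in frag[(met, t)].items():
                    key = (n, k)
                    per_transition[key] = per_transition.get(key, 0.0) + fracs[t] * share * total_area
            for (n, k), area in sorted(per_transition.items()):
                noisy = area * block * float(_lognormal_factor(rng, config.area_transition_cv))
                rows.append({
                    "sample": m.sample, "analyte": met,
                    "precursor_shift": n, "product_shift": k,
                    "area": noisy,
                })
    peaks = pd.DataFrame(rows, columns=["sample", "analyte", "precursor_shift",
                                        "product_shift", "area"])
    return peaks, pd.DataFrame(conc_rows)


def generate_enzyme_assays(
    config: CohortConfig, rng: np.random.Generator | None = None
):
    """Enzyme cohort: per animal and enzyme, a latent specific activity and
    a synthetic absorbance trace realizing it."""
    if rng is None:
        config.validate()
        rng = np.random.default_rng(config.seed)
    protein_mg, volume_ml, path_cm = 0.01, 0.2, 0.55
    times = np.arange(0.0, 601.0, 15.0)
    traces, truth_rows = [], []
    for group, n in (("NoSE", config.n_enzyme_per_group), ("SE", config.n_enzyme_per_group)):
        for i in range(n):
            smp = f"ENZ-{group}{i + 1:02d}"
            for enzyme, (base, eps, direction) in DEFAULT_ENZYMES.items():
                red = config.effects.enzymes.get(enzyme, 0.0) if group == "SE" else 0.0
                activity = base * (1 - red) * max(
                    1.0 + rng.normal(0.0, config.enzyme_cv), 0.05
                )
                slope_au_min = (activity * protein_mg / 1000.0 / volume_ml) * eps * path_cm
                signed = slope_au_min if direction == "increase" else -slope_au_min
                start = 0.05 if direction == "increase" else 1.0
                absorb = start + signed * times / 60.0
                absorb = absorb + rng.normal(0.0, config.absorbance_noise_au, len(times))
                traces.append({
                    "sample": smp, "group": group, "enzyme": enzyme, "epsilon": eps,
                    "trace": KineticTrace(times.copy(), absorb, 340.0 if eps == EPSILON_NADH else 412.0,
                                          path_cm, protein_mg, volume_ml, direction),
                })
                truth_rows.append({"sample": smp, "group": group, "enzyme": enzyme,
                                   "activity": activity})
    return traces, pd.DataFrame(truth_rows)


def generate_ocr_assays(
    config: CohortConfig, rng: np.random.Generator | None = None
):
    """Respirometry cohort: staged OCR profiles for both assay types.

    Default effects are all zero (the study found no group differences)."""
    if rng is None:
        config.validate()
        rng = np.random.default_rng(config.seed)
    profiles = []
    for group, n in (("NoSE", config.n_ocr_per_group), ("SE", config.n_ocr_per_group)):
        for i in range(n):
            smp = f"OCR-{group}{i + 1:02d}"
            prep = float(_trunc_normal(rng, 1.0, config.ocr_animal_sd, 0.3))
            protein = float(_trunc_normal(rng, 0.004, 0.0004, 0.001))
            for assay, baselines in DEFAULT_OCR_BASELINES.items():
                stages = {}
                for stage, base in baselines.items():
                    red = 0.0
                    if group == "SE" and stage != "nonmito":
                        red = config.effects.ocr.get(stage, 0.0)
                    scale = prep if stage != "nonmito" else 1.0
                    val = base * (1 - red) * scale * max(
                        1.0 + rng.normal(0.0, config.ocr_stage_cv), 0.05
                    )
                    stages[stage] = max(val, 0.0)
                profiles.append({
                    "sample": smp, "group": group, "assay": assay,
                    "profile": OCRProfile(assay, stages, protein),
                })
    return profiles


def generate_cohort(config: CohortConfig | None = None) -> GeneratorOutput:
    """Generate the full synthetic study: peak tables with metadata, enzyme
    traces, and respirometry profiles, plus the ground-truth log."""
    if config is None:
        config = CohortConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)

    prop = propagate(build_network(), U13C_GLUCOSE, 2)
    enr_truth, meta_core, factors = _latent_enrichment(config, rng)
    meta = _sample_meta(config, meta_core, rng)
    peaks, conc_truth = _peak_records(config, enr_truth, meta, prop, rng)
    enzyme_traces, enzyme_truth = generate_enzyme_assays(config, rng)
    ocr_profiles = generate_ocr_assays(config, rng)

    truth = {
        "seed": config.seed,
        "latent_factors": factors,
        "suc_coupling_cv": config.suc_coupling_cv(),
        "effects": asdict(config.effects),
        "baseline_enrichment": {
            f"{met}:turn{turn}": v
            for (met, turn), v in config.baseline_enrichment.items()
        },
        "concentrations": {
            r["sample"] + ":" + r["metabolite"]: r["concentration"]
            for r in conc_truth.to_dict("records")
        },
        "enzyme_activities": {
            f"{r['sample']}:{r['enzyme']}": r["activity"]
            for r in enzyme_truth.to_dict("records")
        },
    }
    return GeneratorOutput(peaks, meta, enr_truth, enzyme_traces, enzyme_truth,
                           ocr_profiles, truth, prop)
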