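"""Synthetic cohort generator: determinism, structure, exact round-trips."""

import numpy as np
import pandas as pd
import pytest

from glucotrace.quantify import enrichment_table
from glucotrace.simulate import (
    CohortConfig,
    default_effect_table,
    generate_cohort,
    generate_ocr_assays,
)


def noise_free_config(**kw):
    return CohortConfig(
        uptake_sd=0.0, mito_capacity_sd=0.0, og_suc_target_r=1.0,
        se_og_suc_transfer_sd=0.0, gly_noise_cv=0.0, tca_noise_cv=0.0,
        area_block_cv=0.0, area_transition_cv=0.0, enzyme_cv=0.0,
        absorbance_noise_au=0.0, ocr_animal_sd=0.0, ocr_stage_cv=0.0,
        **kw,
    )


class TestDefaultEffectTable:
    def test_reported_effects(self):
        eff = default_effect_table()
        assert eff.glycolysis["G6P"] == 0.22
        assert eff.glycolysis["PEP"] == 0.20
        assert eff.tca_turn1["SUC"] == 0.35
        assert eff.tca_turn2["OG2"] == 0.47
        assert eff.enzymes["PDH"] == 0.33
        assert eff.enzymes["OGDH"] == 0.55
        assert all(v == 0 for v in eff.ocr.values())

    def test_unaffected_entries_are_zero(self):
        eff = default_effect_table()
        assert eff.glycolysis["PYR"] == 0.0
        assert eff.tca_turn1["MAL"] == 0.0
        assert eff.enzymes["HK"] == 0.0


class TestDeterminismAndValidity:
    def test_same_seed_gives_identical_output(self):
        a = generate_cohort(CohortConfig(seed=123))
        b = generate_cohort(CohortConfig(seed=123))
        pd.testing.assert_frame_equal(a.peaks, b.peaks)
        pd.testing.assert_frame_equal(a.meta, b.meta)
        assert a.truth == b.truth

    def test_different_seed_changes_output(self):
        a = generate_cohort(CohortConfig(seed=1))
        b = generate_cohort(CohortConfig(seed=2))
        assert not a.peaks["area"].equals(b.peaks["area"])

    def test_areas_nonnegative_and_group_sizes(self, default_cohort):
        assert (default_cohort.peaks["area"] >= 0).all()
        counts = default_cohort.meta["group"].value_counts()
        assert counts["NoSE"] == 11 and counts["SE"] == 10

    def test_inconsistent_config_rejected(self):
        cfg = CohortConfig()
        cfg.baseline_enrichment[("SUC", 1)] = 70.0
        cfg.baseline_enrichment[("SUC", 2)] = 40.0
        with pytest.raises(ValueError, match="exceed 100"):
            cfg.validate()

    def test_effect_fraction_bounds_enforced(self):
        cfg = CohortConfig()
        cfg.effects.glycolysis["G6P"] = 1.2
        with pytest.raises(ValueError, match="outside"):
            cfg.validate()


class TestNoiseFreeStructure:
    def test_zero_noise_zero_effects_groups_identical(self, shifts):
        cfg = noise_free_config(
            effects=type(default_effect_table())(),  # all-empty tables
            seed=0,
        )
        cohort = generate_cohort(cfg)
        enr = enrichment_table(cohort.peaks, shifts).merge(
            cohort.meta[["sample", "group"]], on="sample")
        means = enr.groupby(["group", "metabolite", "turn"])["enrichment"].mean().unstack(0)
        np.testing.assert_allclose(means["NoSE"], means["SE"], rtol=1e-9)
        spread = enr.groupby(["metabolite", "turn"])["enrichment"].std()
        assert (spread.fillna(0) < 1e-9).all()

    def test_recovered_enrichment_equals_latent_when_noise_free(self, shifts):
        cfg = noise_free_config(seed=0)
        cohort = generate_cohort(cfg)
        enr = enrichment_table(cohort.peaks, shifts)
        merged = enr.merge(
            cohort.enrichment_truth,
            on=["sample", "metabolite", "turn"],
            suffixes=("_recovered", "_latent"),
        )
        np.testing.assert_allclose(
            merged["enrichment_recovered"], merged["enrichment_latent"], rtol=1e-9
        )

    def test_noise_free_se_effects_recover_configured_reduction(self, shifts):
        cfg = noise_free_config(seed=0)
        cohort = generate_cohort(cfg)
        enr = enrichment_table(cohort.peaks, shifts).merge(
            cohort.meta[["sample", "group"]], on="sample")
        g6p = enr[(enr.metabolite == "G6P") & (enr.turn == 1)]
        means = g6p.groupby("group")["enrichment"].mean()
        assert 1 - means["SE"] / means["NoSE"] == pytest.approx(0.22, abs=1e-9)


class TestCorrelationStructure:
    def test_nose_og2_suc_coupling_near_target(self, shifts):
        """Average No SE first-turn 2OG-SUC correlation over seeded cohorts
        should sit near the configured 0.95 coupling."""
        from glucotrace.stats import pearson

        rs = []
        for seed in range(40):
            cohort = generate_cohort(CohortConfig(seed=seed))
            enr = enrichment_table(cohort.peaks, shifts).merge(
                cohort.meta[["sample", "group"]], on="sample")
            nose = enr[(enr.group == "NoSE") & (enr.turn == 1)]
            wide = nose.pivot(index="sample", columns="metabolite", values="enrichment")
            rs.append(pearson(wide["OG2"], wide["SUC"]).r)
        assert np.mean(rs) == pytest.approx(0.95, abs=0.03)

    def test_se_group_decouples_pyruvate_from_tca(self, shifts):
        """SE animals draw an independent mitochondrial factor, so the
        PYR-CIT correlation should be far weaker than in No SE."""
        from glucotrace.stats import pearson

        r_nose, r_se = [], []
        for seed in range(30):
            cohort = generate_cohort(CohortConfig(seed=seed))
            enr = enrichment_table(cohort.peaks, shifts).merge(
                cohort.meta[["sample", "group"]], on="sample")
            t1 = enr[enr.turn == 1]
            for group, acc in (("NoSE", r_nose), ("SE", r_se)):
                wide = t1[t1.group == group].pivot(
                    index="sample", columns="metabolite", values="enrichment")
                acc.append(pearson(wide["PYR"], wide["CIT"]).r)
        assert np.mean(r_nose) > 0.7
        assert abs(np.mean(r_se)) < 0.3


class TestOcrNull:
    def test_default_ocr_effects_are_null(self):
        profiles = generate_ocr_assays(CohortConfig(seed=4))
        rows = [
            {"group": p["group"], "assay": p["assay"], "stage": stage, "value": v}
            for p in profiles
            for stage, v in p["profile"].stages.items()
        ]
        means = pd.DataFrame(rows).groupby(["assay", "stage", "group"])["value"].mean()
        # group means of raw stages differ only by sampling noise (~sd/sqrt(n))
        for (assay, stage), block in means.groupby(level=[0, 1]):
            ratio = block[(assay, stage, "SE")] / block[(assay, stage, "NoSE")]
            assert abs(ratio - 1) < 0.25, (assay, stage)
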