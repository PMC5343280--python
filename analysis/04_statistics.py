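"""The statistical battery on the quantified cohort.

Two-way ANOVA (group x metabolite) with uncorrected Fisher's LSD posttests
per panel (glycolysis, TCA turn 1, TCA turn 2), plus the correlation
analysis: G6P vs downstream glycolytic enrichment, pyruvate vs first-turn
TCA enrichment, and the 2-oxoglutarate-succinate coupling, each per group.
Finding (default cohort): LSD flags the metabolites carrying configured
effects; No SE correlations are strong and SE pyruvate-TCA correlations
collapse, as the generator intends.
"""

from pathlib import Path

import pandas as pd

from glucotrace.workflow import correlation_report, enrichment_anova_report

IN_Q = Path("results/quantified")
IN_C = Path("results/cohort")
OUT = Path("results/stats")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    enrich = pd.read_csv(IN_Q / "enrichment.csv")
    meta = pd.read_csv(IN_C / "sample_meta.csv")

    anova, lsd = enrichment_anova_report(enrich, meta)
    anova.to_csv(OUT / "anova_enrichment.csv", index=False)
    lsd.to_csv(OUT / "lsd_enrichment.csv", index=False)
    corr = correlation_report(enrich, meta)
    corr.to_csv(OUT / "correlations.csv", index=False)

    print("ANOVA group effects per panel:")
    print(anova[anova.effect == "group"][["panel", "F", "p"]].to_string(index=False))
    sig = lsd[lsd.p < 0.05]
    print(f"\nLSD-flagged metabolites (p < 0.05): "
          f"{sorted(set(zip(sig.panel, sig.metabolite)))}")
    og_suc = corr[(corr.x == "OG2") & (corr.y == "SUC")]
    print("\n2OG-SUC coupling by group:")
    print(og_suc[["group", "r", "p"]].to_string(index=False))


if __name__ == "__main__":
    main()
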