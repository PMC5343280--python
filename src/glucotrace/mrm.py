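"""Scheduled-MRM transition design for labeled isotopologues.

Labeled Q1/Q3 masses are computed additively on the unlabeled nominal base
masses (instrument table rounded to the nearest integer): the precursor
gains one Da per 13C, and the product ion gains one Da per 13C retained
after fragmentation.  Two fragment families cover every analyte here:

* phosphate-type fragments (dihydrogen phosphate 97 Da, phosphate 79 Da)
  carry no carbon, so Q3 is label-invariant;
* carboxyl-loss fragments (pyruvate and all TCA intermediates) lose exactly
  one carboxyl carbon; which carboxyl is lost decides how many labels the
  product retains, so one precursor can yield several Q3 masses.

Negative-mode [M-H]- ionization throughout; instrument parameters
(RT/DP/CE/CXP) are label-invariant and copied from the unlabeled analyte.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from importlib import resources
from pathlib import Path

import pandas as pd

from .pathway import IsotopomerPool, PropagationResult

__all__ = [
    "TransitionSpec",
    "FragmentRule",
    "FRAGMENT_RULES",
    "load_unlabeled_table",
    "nominal_bases",
    "labeled_transitions",
    "design_transitions",
    "emit_transition_table",
    "load_transition_table",
    "turn_shifts",
]

TABLE_COLUMNS = [
    "Analyte",
    "PrecursorShift",
    "ProductShift",
    "Q1",
    "Q3",
    "RT",
    "DP",
    "CE",
    "CXP",
]


@dataclass(frozen=True)
class TransitionSpec:
    """One sMRM transition: analyte, mass shifts, masses, instrument values."""

    analyte: str
    precursor_shift: int
    product_shift: int
    q1: float
    q3: float
    rt: float
    dp: float
    ce: float
    cxp: float

    def __post_init__(self) -> None:
        if self.q3 >= self.q1:
            raise ValueError(f"{self.analyte}: Q3 {self.q3} must be < Q1 {self.q1}")
        if not 0 <= self.product_shift <= self.precursor_shift:
            raise ValueError(
                f"{self.analyte}: product shift {self.product_shift} outside "
                f"[0, {self.precursor_shift}]"
            )
        if self.rt <= 0:
            raise ValueError(f"{self.analyte}: RT must be positive")


@dataclass(frozen=True)
class FragmentRule:
    """Which carbons are absent from an analyte's product ion.

    ``lost_sets`` lists the alternative sets of 1-based carbon positions the
    fragment can lose; the empty set family ``((),)`` encodes a carbon-free
    phosphate fragment (no analyte carbon in the product, but equally no
    label loss is *possible* for the carbons retained — the product simply
    carries zero analyte carbons, hence product shift 0).
    """

    analyte: str
    lost_sets: tuple[tuple[int, ...], ...]
    carbon_free_product: bool = False

    def product_shifts(self, mask: tuple[int, ...]) -> set[int]:
        if self.carbon_free_product:
            return {0}
        return {sum(mask) - sum(mask[i - 1] for i in ls) for ls in self.lost_sets}


def _phosphate(analyte: str) -> FragmentRule:
    return FragmentRule(analyte, ((),), carbon_free_product=True)


def _carboxyl(analyte: str, positions: tuple[int, ...]) -> FragmentRule:
    return FragmentRule(analyte, tuple((p,) for p in positions))


#: Packaged fragment rules.  Carboxyl positions follow each metabolite's
#: conventional numbering (citrate: C1 acetyl carboxyl, C5/C6 the
#: oxaloacetate-derived carboxyls; 2-oxoglutarate: C1 and C5).
FRAGMENT_RULES: dict[str, FragmentRule] = {
    "G6P": _phosphate("G6P"),
    "F6P": _phosphate("F6P"),
    "F16BP": _phosphate("F16BP"),
    "DHAP": _phosphate("DHAP"),
    "PG23": _phosphate("PG23"),
    "PEP": _phosphate("PEP"),
    "PYR": _carboxyl("PYR", (1,)),
    "CIT": _carboxyl("CIT", (1, 5, 6)),
    "ACO": _carboxyl("ACO", (1, 5, 6)),
    "OG2": _carboxyl("OG2", (1, 5)),
    "SUC": _carboxyl("SUC", (1, 4)),
    "FUM": _carboxyl("FUM", (1, 4)),
    "MAL": _carboxyl("MAL", (1, 4)),
}

GLYCOLYTIC_ANALYTES = ("G6P", "F6P", "F16BP", "DHAP", "PG23", "PEP", "PYR")
TCA_ANALYTES = ("CIT", "ACO", "OG2", "SUC", "FUM", "MAL")


def load_unlabeled_table(path: str | Path | None = None) -> dict[str, TransitionSpec]:
    """Load the unlabeled (12C) instrument transition table.

    Defaults to the packaged table; accepts any CSV with columns
    Analyte, Q1, Q3, RT, DP, CE, CXP.
    """
    if path is None:
        with resources.files("glucotrace.data").joinpath(
            "transitions_unlabeled.csv"
        ).open("r") as fh:
            df = pd.read_csv(fh)
    else:
        df = pd.read_csv(path)
    out = {}
    for row in df.itertuples(index=False):
        out[row.Analyte] = TransitionSpec(
            row.Analyte, 0, 0, row.Q1, row.Q3, row.RT, row.DP, row.CE, row.CXP
        )
    return out


def nominal_bases(table: dict[str, TransitionSpec]) -> dict[str, tuple[int, int]]:
    """Round instrument Q1/Q3 values to integer nominal base masses."""
    return {a: (round(t.q1), round(t.q3)) for a, t in table.items()}


def labeled_transitions(
    analyte: str,
    pool: IsotopomerPool,
    rule: FragmentRule,
    base: TransitionSpec,
) -> list[TransitionSpec]:
    """All labeled transitions for one analyte given its isotopomer pool.

    One transition per distinct (precursor shift n, product shift k) pair,
    sorted by (n, k).  An unlabeled pool returns the instrument transition
    unchanged.
    """
    if rule.analyte != analyte or base.analyte != analyte:
        raise ValueError(f"rule/base analyte mismatch for {analyte}")
    if pool.metabolite != analyte:
        raise ValueError(f"pool is {pool.metabolite}, expected {analyte}")
    for mask in pool.members:
        if sum(mask) > pool.carbon_count:
            raise ValueError("mask shift exceeds carbon count")
    base_q1, base_q3 = round(base.q1), round(base.q3)
    pairs: set[tuple[int, int]] = set()
    for mask in pool.members:
        n = sum(mask)
        for k in rule.product_shifts(mask):
            pairs.add((n, k))
    specs = []
    for n, k in sorted(pairs):
        if n == 0:
            specs.append(base)
        else:
            specs.append(
                replace(base, precursor_shift=n, product_shift=k,
                        q1=base_q1 + n, q3=base_q3 + k)
            )
    return specs


def design_transitions(
    result: PropagationResult,
    table: dict[str, TransitionSpec] | None = None,
    include_unlabeled: bool = True,
) -> list[TransitionSpec]:
    """Full sMRM design for a propagated tracer.

    Emits, per measured analyte, the unlabeled instrument transition (for
    the enrichment denominator) and every labeled transition implied by the
    tracer's isotopomer pools: the glycolytic fully-propagated pools plus
    both TCA turns.
    """
    if table is None:
        table = load_unlabeled_table()
    specs: list[TransitionSpec] = []
    for analyte in GLYCOLYTIC_ANALYTES + TCA_ANALYTES:
        base = table[analyte]
        rule = FRAGMENT_RULES[analyte]
        if include_unlabeled:
            specs.append(base)
        pools = []
        if analyte in GLYCOLYTIC_ANALYTES:
            pools.append(result.pool(analyte))
        else:
            for turn in sorted(result.tca):
                pools.append(result.pool(analyte, turn))
        seen: set[tuple[int, int]] = set()
        for pool in pools:
            for spec in labeled_transitions(analyte, pool, rule, base):
                key = (spec.precursor_shift, spec.product_shift)
                if spec.precursor_shift > 0 and key not in seen:
                    seen.add(key)
                    specs.append(spec)
    return specs


def turn_shifts(result: PropagationResult) -> dict[str, dict[int, set[int]]]:
    """Map analyte -> turn -> set of labeled precursor shifts.

    Glycolytic analytes carry a single 'turn 1' entry (their labeled species
    is turn-independent).  Used by the quantification stage to assign peak
    records to first- or second-turn enrichment.
    """
    out: dict[str, dict[int, set[int]]] = {}
    for analyte in GLYCOLYTIC_ANALYTES:
        shifts = {n for n in result.pool(analyte).shifts() if n > 0}
        out[analyte] = {1: shifts}
    for analyte in TCA_ANALYTES:
        out[analyte] = {}
        for turn in sorted(result.tca):
            out[analyte][turn] = {
                n for n in result.pool(analyte, turn).shifts() if n > 0
            }
    return out


def emit_transition_table(
    specs: list[TransitionSpec], destination: str | Path
) -> pd.DataFrame:
    """Write transitions as CSV with the canonical header; returns the frame."""
    df = pd.DataFrame(
        [
            {
                "Analyte": s.analyte,
                "PrecursorShift": s.precursor_shift,
                "ProductShift": s.product_shift,
                "Q1": s.q1,
                "Q3": s.q3,
                "RT": s.rt,
                "DP": s.dp,
                "CE": s.ce,
                "CXP": s.cxp,
            }
            for s in specs
        ],
        columns=TABLE_COLUMNS,
    )
    df.to_csv(destination, index=False)
    return df


def load_transition_table(path: str | Path) -> list[TransitionSpec]:
    df = pd.read_csv(path)
    missing = set(TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"transition table missing columns: {sorted(missing)}")
    return [
        TransitionSpec(
            r.Analyte, int(r.PrecursorShift), int(r.ProductShift),
            r.Q1, r.Q3, r.RT, r.DP, r.CE, r.CXP,
        )
        for r in df.itertuples(index=False)
    ]
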