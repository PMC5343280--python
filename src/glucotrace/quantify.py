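"""Percent-enrichment and total-concentration quantification.

Inputs begin at integrated peak areas: one record per sample x analyte x
(precursor shift, product shift) transition.  Percent 13C enrichment of a
metabolite for one cycle turn is the summed area of that turn's labeled
transitions (both product ions where two exist) as a percentage of the
total signal (unlabeled area + all monitored labeled areas), so it is
invariant to any uniform scaling of a sample's analyte block.

Total concentration uses the spiked internal standard (azidothymidine,
AZT): nmol per g tissue = (sum of all isotopologue areas / IS area) x IS
amount / response factor / tissue mass.

Missing transitions are missing data, never imputed zeros: a sample without
the unlabeled channel for a metabolite is excluded from that metabolite's
enrichment (flagged, not silently dropped to zero).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

__all__ = [
    "PeakRecord",
    "SampleMeta",
    "EnrichmentResult",
    "ConcentrationResult",
    "percent_enrichment",
    "enrichment_table",
    "total_concentration",
    "concentration_table",
]

PEAK_COLUMNS = ["sample", "analyte", "precursor_shift", "product_shift", "area"]


@dataclass(frozen=True)
class PeakRecord:
    sample: str
    analyte: str
    precursor_shift: int
    product_shift: int
    area: float

    def __post_init__(self) -> None:
        if self.area < 0:
            raise ValueError("peak area must be nonnegative")


@dataclass(frozen=True)
class SampleMeta:
    sample: str
    group: str  # "SE" or "NoSE"
    body_weight_g: float
    tissue_mass_g: float
    is_area: float

    def __post_init__(self) -> None:
        if self.tissue_mass_g <= 0:
            raise ValueError("tissue mass must be positive")
        if self.is_area <= 0:
            raise ValueError("internal-standard area must be positive")


@dataclass(frozen=True)
class EnrichmentResult:
    sample: str
    metabolite: str
    turn: int
    enrichment: float | None  # percent, None when flagged
    flag: str = ""


@dataclass(frozen=True)
class ConcentrationResult:
    sample: str
    metabolite: str
    concentration: float  # nmol per g tissue


def percent_enrichment(
    records: pd.DataFrame,
    metabolite: str,
    turn: int,
    turn_shifts: dict[str, dict[int, set[int]]],
    sample: str | None = None,
) -> EnrichmentResult:
    """Percent enrichment of one metabolite, one turn, one sample.

    ``records`` holds that sample's peak rows (columns ``PEAK_COLUMNS``);
    ``turn_shifts`` maps analyte -> turn -> labeled precursor shifts, as
    produced by :func:`glucotrace.mrm.turn_shifts`.
    """
    sub = records[records["analyte"] == metabolite]
    if sample is not None:
        sub = sub[sub["sample"] == sample]
    elif not sub.empty:
        ids = sub["sample"].unique()
        if len(ids) > 1:
            raise ValueError("records span several samples; pass sample=")
        sample = ids[0]
    if turn not in turn_shifts.get(metabolite, {}):
        raise ValueError(f"{metabolite}: no turn {turn} in the transition design")
    unlabeled = sub[sub["precursor_shift"] == 0]
    if unlabeled.empty:
        return EnrichmentResult(sample or "", metabolite, turn, None, "missing_unlabeled")
    labeled = sub[sub["precursor_shift"] > 0]
    denom = float(unlabeled["area"].sum() + labeled["area"].sum())
    if denom == 0:
        return EnrichmentResult(sample or "", metabolite, turn, None, "zero_total_signal")
    shifts = turn_shifts[metabolite][turn]
    numer = float(labeled[labeled["precursor_shift"].isin(shifts)]["area"].sum())
    return EnrichmentResult(sample or "", metabolite, turn, 100.0 * numer / denom)


def enrichment_table(
    peaks: pd.DataFrame,
    turn_shifts: dict[str, dict[int, set[int]]],
) -> pd.DataFrame:
    """Tidy enrichment table: one row per sample x metabolite x turn.

    Rows that cannot be computed carry NaN enrichment and a flag.
    """
    rows = []
    for (smp, met), block in peaks.groupby(["sample", "analyte"], sort=True):
        for turn in sorted(turn_shifts.get(met, {})):
            res = percent_enrichment(block, met, turn, turn_shifts, sample=smp)
            rows.append(
                {
                    "sample": smp,
                    "metabolite": met,
                    "turn": turn,
                    "enrichment": res.enrichment,
                    "flag": res.flag,
                }
            )
    return pd.DataFrame(rows, columns=["sample", "metabolite", "turn", "enrichment", "flag"])


def total_concentration(
    records: pd.DataFrame,
    meta: SampleMeta,
    metabolite: str,
    response_factor: float = 1.0,
    is_amount_nmol: float = 4.0,
) -> ConcentrationResult:
    """Total (all isotopologues) concentration in nmol per g tissue.

    ``response_factor`` is the analyte's area response per nmol relative to
    the internal standard; the default AZT spike is 4 nmol (4 uL x 1 mM).
    """
    if response_factor <= 0:
        raise ValueError("response factor must be positive")
    sub = records[
        (records["analyte"] == metabolite) & (records["sample"] == meta.sample)
    ]
    total_area = float(sub["area"].sum())
    conc = (
        (total_area / meta.is_area) * is_amount_nmol / response_factor / meta.tissue_mass_g
    )
    return ConcentrationResult(meta.sample, metabolite, conc)


def concentration_table(
    peaks: pd.DataFrame,
    meta: list[SampleMeta] | pd.DataFrame,
    response_factors: dict[str, float] | None = None,
    is_amount_nmol: float = 4.0,
) -> pd.DataFrame:
    """Tidy concentration table: one row per sample x metabolite."""
    if isinstance(meta, pd.DataFrame):
        meta = [
            SampleMeta(r.sample, r.group, r.body_weight_g, r.tissue_mass_g, r.is_area)
            for r in meta.itertuples(index=False)
        ]
    by_id = {m.sample: m for m in meta}
    response_factors = response_factors or {}
    rows = []
    for (smp, met), block in peaks.groupby(["sample", "analyte"], sort=True):
        m = by_id[smp]
        res = total_concentration(
            block, m, met, response_factors.get(met, 1.0), is_amount_nmol
        )
        rows.append({"sample": smp, "metabolite": met, "concentration": res.concentration})
    return pd.DataFrame(rows, columns=["sample", "metabolite", "concentration"])
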