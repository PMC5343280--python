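"""Enzyme specific activities and mitochondrial respiration parameters.

Enzyme activities come from continuous spectrophotometric traces
(NADH/NAD(P)H at 340 nm, TNB at 412 nm, MTT-formazan): the initial linear
window of the absorbance trace is fitted, the slope converted through the
Beer-Lambert law (epsilon, path length) and the assay volume to nmol/min,
and normalized to protein.  The linear window is the longest initial
segment (>= 5 points) whose fit keeps r^2 >= 0.98; if none exists the trace
is flagged rather than extrapolated.

Respirometry parameters follow the staged extracellular-flux protocols.
Nonmitochondrial respiration is subtracted from every stage and everything
is protein-normalized.  Coupling assay: ATP-linked = state 3 ADP - state 4o,
RCR = state 3 ADP / state 4o, coupling efficiency = ATP-linked / state 3 ADP.
Electron flow assay: complex I-driven = state 3u - post-rotenone, complex
II-driven = post-succinate - post-malonate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "KineticTrace",
    "ActivityResult",
    "OCRProfile",
    "MitoParams",
    "specific_activity",
    "coupling_params",
    "electron_flow_params",
    "EPSILON_NADH",
    "EPSILON_TNB",
]

#: Extinction coefficients (mM^-1 cm^-1): NADH/NAD(P)H at 340 nm, TNB at 412 nm.
EPSILON_NADH = 6.22
EPSILON_TNB = 13.6

MIN_WINDOW = 5
R2_THRESHOLD = 0.98


@dataclass
class KineticTrace:
    """One continuous absorbance trace.

    ``direction`` is "decrease" for NADH-oxidation assays and "increase"
    for NAD+/NADP+ reduction, TNB formation, or MTT reduction; the rate uses
    the slope magnitude either way.  ``volume_ml`` is the assay volume used
    to convert concentration change to amount (default a 0.2 mL microplate
    well); ``path_length_cm`` for plate assays is the per-well liquid height.
    """

    times_s: np.ndarray
    absorbances: np.ndarray
    wavelength_nm: float = 340.0
    path_length_cm: float = 1.0
    protein_mg: float = 1.0
    volume_ml: float = 0.2
    direction: str = "decrease"

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.absorbances = np.asarray(self.absorbances, dtype=float)
        if self.times_s.shape != self.absorbances.shape:
            raise ValueError("times and absorbances must align")
        if len(self.times_s) < MIN_WINDOW:
            raise ValueError(f"need at least {MIN_WINDOW} points")
        if np.any(np.diff(self.times_s) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.direction not in ("decrease", "increase"):
            raise ValueError("direction must be 'decrease' or 'increase'")
        if self.protein_mg <= 0 or self.path_length_cm <= 0 or self.volume_ml <= 0:
            raise ValueError("protein, path length, and volume must be positive")


@dataclass(frozen=True)
class ActivityResult:
    specific_activity: float  # nmol / min / mg protein; NaN when flagged
    window: tuple[int, int]  # [start, stop) indices of the fitted segment
    r_squared: float
    flag: str = ""


def _linear_fit(t: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Least-squares slope and r^2; an exactly flat or exactly linear
    segment counts as a perfect fit."""
    slope, intercept = np.polyfit(t, y, 1)
    resid = y - (slope * t + intercept)
    sse = float(resid @ resid)
    sst = float(((y - y.mean()) ** 2).sum())
    if sst == 0:
        r2 = 1.0 if sse < 1e-20 else 0.0
    else:
        r2 = 1.0 - sse / sst
    return float(slope), r2


def specific_activity(trace: KineticTrace, epsilon_mm_cm: float) -> ActivityResult:
    """Specific activity in nmol / min / mg protein from one trace.

    rate (mM/min) = |slope AU/min| / (epsilon x path length); amount rate
    = rate x assay volume; specific activity = amount rate / protein.
    """
    if epsilon_mm_cm <= 0:
        raise ValueError("extinction coefficient must be positive")
    t_min = trace.times_s / 60.0
    y = trace.absorbances
    best: tuple[int, float, float] | None = None  # (stop, slope, r2)
    for stop in range(MIN_WINDOW, len(y) + 1):
        slope, r2 = _linear_fit(t_min[:stop], y[:stop])
        if r2 >= R2_THRESHOLD:
            best = (stop, slope, r2)
    if best is None:
        return ActivityResult(float("nan"), (0, 0), float("nan"), "no_linear_window")
    stop, slope, r2 = best
    rate_mm_per_min = abs(slope) / (epsilon_mm_cm * trace.path_length_cm)
    nmol_per_min = rate_mm_per_min * trace.volume_ml * 1000.0
    return ActivityResult(nmol_per_min / trace.protein_mg, (0, stop), r2)


@dataclass
class OCRProfile:
    """Staged oxygen-consumption readings (pmol O2/min) for one preparation."""

    assay: str  # "coupling" or "electron_flow"
    stages: dict[str, float] = field(default_factory=dict)
    protein_mg: float = 1.0

    COUPLING_STAGES = ("state2", "state3ADP", "state4o", "state3u", "nonmito")
    ELECTRON_FLOW_STAGES = (
        "state3u",
        "post_rotenone",
        "post_succinate",
        "post_malonate",
        "nonmito",
    )

    def __post_init__(self) -> None:
        required = (
            self.COUPLING_STAGES if self.assay == "coupling" else self.ELECTRON_FLOW_STAGES
        )
        if self.assay not in ("coupling", "electron_flow"):
            raise ValueError("assay must be 'coupling' or 'electron_flow'")
        missing = set(required) - set(self.stages)
        if missing:
            raise ValueError(f"{self.assay} profile missing stages: {sorted(missing)}")
        if any(v < 0 for v in self.stages.values()):
            raise ValueError("stage readings must be nonnegative")
        if self.protein_mg <= 0:
            raise ValueError("protein must be positive")


@dataclass(frozen=True)
class MitoParams:
    """Protein-normalized, nonmito-subtracted respiration parameters
    (pmol O2 / min / mg protein; ratios dimensionless)."""

    values: dict[str, float]
    flag: str = ""


def coupling_params(profile: OCRProfile) -> MitoParams:
    if profile.assay != "coupling":
        raise ValueError("expected a coupling profile")
    nm = profile.stages["nonmito"]
    corr = {
        k: (profile.stages[k] - nm) / profile.protein_mg
        for k in ("state2", "state3ADP", "state4o", "state3u")
    }
    atp_linked = corr["state3ADP"] - corr["state4o"]
    flag = ""
    if corr["state4o"] > 0:
        rcr = corr["state3ADP"] / corr["state4o"]
    else:
        rcr = float("nan")
        flag = "rcr_undefined"
    eff = atp_linked / corr["state3ADP"] if corr["state3ADP"] != 0 else float("nan")
    return MitoParams(
        {**corr, "atp_linked": atp_linked, "rcr": rcr, "coupling_efficiency": eff},
        flag,
    )


def electron_flow_params(profile: OCRProfile) -> MitoParams:
    if profile.assay != "electron_flow":
        raise ValueError("expected an electron_flow profile")
    nm = profile.stages["nonmito"]
    corr = {
        k: (profile.stages[k] - nm) / profile.protein_mg
        for k in ("state3u", "post_rotenone", "post_succinate", "post_malonate")
    }
    ci = corr["state3u"] - corr["post_rotenone"]
    cii = corr["post_succinate"] - corr["post_malonate"]
    flag = "negative_respiration" if ci < 0 or cii < 0 else ""
    return MitoParams({**corr, "complexI": ci, "complexII": cii}, flag)
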