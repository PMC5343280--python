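"""Positional-isotopomer propagation through the atom-mapped network.

A metabolite pool is a weighted set of positional isotopomers (per-carbon
label masks).  Applying a reaction assembles product masks carbon by carbon
from the atom map, drops CO2-lost carbons (their label weight is tracked
separately), and scrambles the label of 2-fold symmetric products
(succinate, fumarate) 50/50 between the two molecular orientations.

``propagate`` runs the whole bookkeeping for a positional glucose tracer:
glycolysis with complete triose-phosphate equilibration, then one or two
TCA-cycle turns.  The first turn condenses tracer-derived acetyl-CoA with
unlabeled oxaloacetate; the second condenses the first turn's (scrambled)
oxaloacetate with tracer-derived acetyl-CoA again.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

from .network import CarbonMap, ReactionNetwork, build_network

__all__ = [
    "Mask",
    "PositionalIsotopomer",
    "IsotopomerPool",
    "ReactionOutcome",
    "PropagationResult",
    "apply_reaction",
    "propagate",
    "isotopologue_distribution",
]

Mask = tuple[int, ...]

WEIGHT_TOL = 1e-9


@dataclass(frozen=True)
class PositionalIsotopomer:
    """One positional labeling state: which carbons of a metabolite are 13C."""

    metabolite: str
    mask: Mask
    weight: float


@dataclass
class IsotopomerPool:
    """Weighted set of positional isotopomers of one metabolite.

    ``members`` maps label mask -> fraction; fractions sum to 1.
    """

    metabolite: str
    carbon_count: int
    members: dict[Mask, float] = field(default_factory=dict)

    @classmethod
    def pure(cls, metabolite: str, mask: Mask) -> "IsotopomerPool":
        return cls(metabolite, len(mask), {tuple(mask): 1.0})

    @classmethod
    def unlabeled(cls, metabolite: str, carbon_count: int) -> "IsotopomerPool":
        return cls.pure(metabolite, (0,) * carbon_count)

    def validate(self) -> None:
        for mask in self.members:
            if len(mask) != self.carbon_count:
                raise ValueError(
                    f"{self.metabolite}: mask {mask} length != {self.carbon_count}"
                )
        total = sum(self.members.values())
        if abs(total - 1.0) > WEIGHT_TOL:
            raise ValueError(f"{self.metabolite}: weights sum to {total}, not 1")

    def isotopomers(self) -> list[PositionalIsotopomer]:
        return [
            PositionalIsotopomer(self.metabolite, m, w)
            for m, w in sorted(self.members.items())
        ]

    def shifts(self) -> dict[int, float]:
        out: dict[int, float] = {}
        for mask, w in self.members.items():
            out[sum(mask)] = out.get(sum(mask), 0.0) + w
        return out

    def mix(self, other: "IsotopomerPool", w_self: float) -> "IsotopomerPool":
        """Weighted mixture of two pools of the same metabolite."""
        if other.metabolite != self.metabolite:
            raise ValueError("cannot mix pools of different metabolites")
        members: dict[Mask, float] = {}
        for mask, w in self.members.items():
            members[mask] = members.get(mask, 0.0) + w_self * w
        for mask, w in other.members.items():
            members[mask] = members.get(mask, 0.0) + (1.0 - w_self) * w
        return IsotopomerPool(self.metabolite, self.carbon_count, members)


def scramble(pool: IsotopomerPool) -> IsotopomerPool:
    """50/50 scrambling over the two orientations of a symmetric skeleton.

    Each mask m is replaced by (m + reversed m) / 2; idempotent.
    """
    members: dict[Mask, float] = {}
    for mask, w in pool.members.items():
        for m in (mask, mask[::-1]):
            members[m] = members.get(m, 0.0) + 0.5 * w
    return IsotopomerPool(pool.metabolite, pool.carbon_count, members)


@dataclass
class ReactionOutcome:
    """Products of one reaction application plus the labeled-CO2 weight
    (expected number of 13C atoms released per substrate conversion)."""

    pools: dict[str, IsotopomerPool]
    labeled_co2: float


def apply_reaction(
    pools: dict[str, IsotopomerPool],
    reaction: CarbonMap,
    network: ReactionNetwork,
) -> ReactionOutcome:
    """Apply one atom-mapped reaction to substrate pools.

    For condensations the substrate pools are treated as statistically
    independent: each product isotopomer's weight is the product of its
    substrate members' weights.
    """
    for sub in reaction.substrates:
        if sub not in pools:
            raise ValueError(f"{reaction.name}: missing substrate pool {sub}")
        pool = pools[sub]
        if pool.metabolite != sub:
            raise ValueError(
                f"{reaction.name}: pool labeled {pool.metabolite} given for {sub}"
            )
        if pool.carbon_count != network.metabolite(sub).carbon_count:
            raise ValueError(f"{reaction.name}: {sub} mask length mismatch")
        pool.validate()

    prod_counts = {p: network.metabolite(p).carbon_count for p in reaction.products}
    out: dict[str, dict[Mask, float]] = {p: {} for p in reaction.products}
    labeled_co2 = 0.0

    sub_items = [sorted(pools[s].members.items()) for s in reaction.substrates]
    for combo in itertools.product(*sub_items):
        weight = 1.0
        labels: dict[tuple[str, int], int] = {}
        for sub, (mask, w) in zip(reaction.substrates, combo):
            weight *= w
            for i, flag in enumerate(mask, start=1):
                labels[(sub, i)] = flag
        prod_masks = {p: [0] * n for p, n in prod_counts.items()}
        for (sub, ci), (prod, cj) in reaction.mapping.items():
            prod_masks[prod][cj - 1] = labels[(sub, ci)]
        labeled_co2 += weight * sum(labels[loc] for loc in reaction.lost)
        for p in reaction.products:
            mask = tuple(prod_masks[p])
            out[p][mask] = out[p].get(mask, 0.0) + weight

    result: dict[str, IsotopomerPool] = {}
    for p in reaction.products:
        pool = IsotopomerPool(p, prod_counts[p], out[p])
        if network.metabolite(p).symmetric:
            pool = scramble(pool)
        pool.validate()
        result[p] = pool
    return ReactionOutcome(result, labeled_co2)


GLYCOLYTIC_ORDER = ("GLC", "G6P", "F6P", "F16BP", "DHAP", "GA3P", "PG23", "PEP", "PYR")
TCA_ORDER = ("CIT", "ACO", "OG2", "SUC", "FUM", "MAL", "OAA")


@dataclass
class PropagationResult:
    """Per-metabolite isotopomer pools from one tracer propagation.

    ``glycolytic`` pools are turn-independent; ``tca`` maps turn number
    (1, 2) to pools of each cycle intermediate.  ``labeled_co2`` records the
    expected 13C atoms released per turn at the decarboxylation steps.
    """

    glycolytic: dict[str, IsotopomerPool]
    acetyl: IsotopomerPool
    tca: dict[int, dict[str, IsotopomerPool]]
    labeled_co2: dict[str, float]

    def pool(self, metabolite: str, turn: int = 1) -> IsotopomerPool:
        if metabolite in self.glycolytic:
            return self.glycolytic[metabolite]
        if metabolite == "ACCOA":
            return self.acetyl
        return self.tca[turn][metabolite]


def propagate(
    network: ReactionNetwork,
    tracer: PositionalIsotopomer | Mask,
    n_turns: int = 2,
) -> PropagationResult:
    """Propagate a positional glucose tracer through glycolysis and
    ``n_turns`` TCA-cycle turns (1 or 2)."""
    if isinstance(tracer, PositionalIsotopomer):
        if tracer.metabolite != "GLC":
            raise ValueError(f"tracer must be glucose, got {tracer.metabolite}")
        mask = tracer.mask
    else:
        mask = tuple(tracer)
    if len(mask) != network.metabolite("GLC").carbon_count:
        raise ValueError("glucose tracer mask must have 6 positions")
    if n_turns not in (1, 2):
        raise ValueError("n_turns must be 1 or 2")

    gly: dict[str, IsotopomerPool] = {"GLC": IsotopomerPool.pure("GLC", mask)}
    co2: dict[str, float] = {}

    def step(rxn_name: str, inputs: dict[str, IsotopomerPool]) -> dict[str, IsotopomerPool]:
        outcome = apply_reaction(inputs, network.reaction(rxn_name), network)
        co2[rxn_name] = co2.get(rxn_name, 0.0) + outcome.labeled_co2
        return outcome.pools

    gly["G6P"] = step("hk", {"GLC": gly["GLC"]})["G6P"]
    gly["F6P"] = step("pgi", {"G6P": gly["G6P"]})["F6P"]
    gly["F16BP"] = step("pfk", {"F6P": gly["F6P"]})["F16BP"]
    ald = step("ald", {"F16BP": gly["F16BP"]})
    # Complete triose-phosphate equilibration: both triose pools become the
    # same 50/50 mixture of the two F16BP halves, each expressed in its own
    # carbon numbering via the TPI map (applied forward and in reverse).
    tpi = network.reaction("tpi")
    dhap_as_ga3p = apply_reaction({"DHAP": ald["DHAP"]}, tpi, network).pools["GA3P"]
    rev = CarbonMap(
        "tpi_rev",
        ("GA3P",),
        ("DHAP",),
        {pc: sc for sc, pc in tpi.mapping.items()},
    )
    ga3p_as_dhap = apply_reaction({"GA3P": ald["GA3P"]}, rev, network).pools["DHAP"]
    gly["GA3P"] = ald["GA3P"].mix(dhap_as_ga3p, 0.5)
    gly["DHAP"] = ald["DHAP"].mix(ga3p_as_dhap, 0.5)

    gly["PG23"] = step("gapdh", {"GA3P": gly["GA3P"]})["PG23"]
    gly["PEP"] = step("eno", {"PG23": gly["PG23"]})["PEP"]
    gly["PYR"] = step("pk", {"PEP": gly["PEP"]})["PYR"]
    acetyl = step("pdh", {"PYR": gly["PYR"]})["ACCOA"]

    def tca_turn(oaa: IsotopomerPool) -> dict[str, IsotopomerPool]:
        pools: dict[str, IsotopomerPool] = {}
        pools["CIT"] = step("cs", {"ACCOA": acetyl, "OAA": oaa})["CIT"]
        pools["ACO"] = step("acn", {"CIT": pools["CIT"]})["ACO"]
        pools["OG2"] = step("idh", {"ACO": pools["ACO"]})["OG2"]
        pools["SUC"] = step("ogdh", {"OG2": pools["OG2"]})["SUC"]
        pools["FUM"] = step("sdh", {"SUC": pools["SUC"]})["FUM"]
        pools["MAL"] = step("fh", {"FUM": pools["FUM"]})["MAL"]
        pools["OAA"] = step("mdh", {"MAL": pools["MAL"]})["OAA"]
        return pools

    tca: dict[int, dict[str, IsotopomerPool]] = {}
    oaa0 = IsotopomerPool.unlabeled("OAA", 4)
    tca[1] = tca_turn(oaa0)
    if n_turns == 2:
        tca[2] = tca_turn(tca[1]["OAA"])
    return PropagationResult(gly, acetyl, tca, co2)


def isotopologue_distribution(pool: IsotopomerPool) -> dict[int, float]:
    """Aggregate a positional pool into its mass-shift (M+n) distribution."""
    pool.validate()
    return dict(sorted(pool.shifts().items()))


def default_network() -> ReactionNetwork:
    return build_network()
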