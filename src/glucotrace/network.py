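"""Carbon-atom-mapped reaction network for glycolysis and the TCA cycle.

The network is a static, validated description of where every carbon of
every substrate ends up: either at a specific 1-based carbon position of a
product, or released as CO2.  It is shipped as plain-text tables
(``data/metabolites.tsv`` and ``data/carbon_maps.tsv``) so users can extend
or replace the map; the loader enforces the atom-balance invariants.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources

__all__ = [
    "MetaboliteDef",
    "CarbonMap",
    "ReactionNetwork",
    "build_network",
    "load_network",
]

CO2 = "CO2"


@dataclass(frozen=True)
class MetaboliteDef:
    """One metabolite node: a short analyte id, its carbon count, and
    whether the carbon skeleton has 2-fold rotational symmetry (succinate
    and fumarate), which scrambles positional label."""

    id: str
    carbon_count: int
    symmetric: bool = False

    def __post_init__(self) -> None:
        if self.carbon_count < 2:
            raise ValueError(f"{self.id}: carbon_count must be >= 2")


@dataclass(frozen=True)
class CarbonMap:
    """One reaction's atom map.

    ``mapping`` sends (substrate id, 1-based carbon index) to
    (product id, 1-based carbon index); ``lost`` lists substrate carbons
    released as CO2.
    """

    name: str
    substrates: tuple[str, ...]
    products: tuple[str, ...]
    mapping: dict[tuple[str, int], tuple[str, int]] = field(default_factory=dict)
    lost: tuple[tuple[str, int], ...] = ()

    def validate(self, metabolites: dict[str, MetaboliteDef]) -> None:
        """Check full atom balance: every substrate carbon appears exactly
        once in mapping or lost, and every product carbon is hit exactly once.
        """
        seen_sub: set[tuple[str, int]] = set()
        seen_prod: set[tuple[str, int]] = set()
        for (sub, ci), (prod, cj) in self.mapping.items():
            if sub not in self.substrates or prod not in self.products:
                raise ValueError(f"{self.name}: {sub}->{prod} not declared")
            if (sub, ci) in seen_sub:
                raise ValueError(f"{self.name}: substrate carbon {sub} C{ci} mapped twice")
            if (prod, cj) in seen_prod:
                raise ValueError(f"{self.name}: product carbon {prod} C{cj} mapped twice")
            seen_sub.add((sub, ci))
            seen_prod.add((prod, cj))
        for sub, ci in self.lost:
            if (sub, ci) in seen_sub:
                raise ValueError(f"{self.name}: {sub} C{ci} both mapped and lost")
            seen_sub.add((sub, ci))
        expect_sub = {
            (s, i) for s in self.substrates for i in range(1, metabolites[s].carbon_count + 1)
        }
        expect_prod = {
            (p, i) for p in self.products for i in range(1, metabolites[p].carbon_count + 1)
        }
        if seen_sub != expect_sub:
            raise ValueError(f"{self.name}: substrate carbons not fully accounted for")
        if seen_prod != expect_prod:
            raise ValueError(f"{self.name}: product carbons not fully covered")


@dataclass(frozen=True)
class ReactionNetwork:
    metabolites: dict[str, MetaboliteDef]
    reactions: dict[str, CarbonMap]

    def metabolite(self, met_id: str) -> MetaboliteDef:
        return self.metabolites[met_id]

    def reaction(self, name: str) -> CarbonMap:
        return self.reactions[name]

    def validate(self) -> None:
        for rxn in self.reactions.values():
            rxn.validate(self.metabolites)


def _read_rows(filename: str) -> list[dict[str, str]]:
    path = resources.files("glucotrace.data").joinpath(filename)
    with path.open("r", encoding="utf-8") as fh:
        rows = [line for line in fh if not line.startswith("#")]
    return list(csv.DictReader(rows, delimiter="\t"))


def load_network(
    metabolites_file: str = "metabolites.tsv",
    carbon_maps_file: str = "carbon_maps.tsv",
) -> ReactionNetwork:
    """Load and validate a network from the packaged plain-text tables."""
    mets = {
        r["id"]: MetaboliteDef(r["id"], int(r["carbons"]), bool(int(r["symmetric"])))
        for r in _read_rows(metabolites_file)
    }
    by_rxn: dict[str, list[dict[str, str]]] = {}
    for row in _read_rows(carbon_maps_file):
        by_rxn.setdefault(row["reaction"], []).append(row)
    reactions: dict[str, CarbonMap] = {}
    for name, rows in by_rxn.items():
        mapping: dict[tuple[str, int], tuple[str, int]] = {}
        lost: list[tuple[str, int]] = []
        subs: list[str] = []
        prods: list[str] = []
        for row in rows:
            sub, ci = row["substrate"], int(row["sub_carbon"])
            if sub not in subs:
                subs.append(sub)
            if row["product"] == CO2:
                lost.append((sub, ci))
            else:
                prod, cj = row["product"], int(row["prod_carbon"])
                if prod not in prods:
                    prods.append(prod)
                mapping[(sub, ci)] = (prod, cj)
        reactions[name] = CarbonMap(name, tuple(subs), tuple(prods), mapping, tuple(lost))
    net = ReactionNetwork(mets, reactions)
    net.validate()
    return net


def build_network() -> ReactionNetwork:
    """Return the packaged glycolysis + TCA-cycle network.

    Glucose -> G6P -> F6P -> F16BP -> {DHAP, GA3P} -> PG23 -> PEP -> PYR;
    pyruvate dehydrogenase loses pyruvate C1 and yields 2-carbon acetyl-CoA;
    citrate synthase condenses acetyl-CoA with oxaloacetate; the CO2 released
    at the IDH and OGDH steps comes from oxaloacetate-derived carboxyls, so
    acetyl carbons survive to 2-oxoglutarate and succinate; succinate and
    fumarate are symmetric.
    """
    return load_network()
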