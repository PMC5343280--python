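"""Atom-map validity and positional label propagation."""

import pytest
from hypothesis import given, settings, strategies as st

from glucotrace.network import build_network
from glucotrace.pathway import (
    IsotopomerPool,
    apply_reaction,
    isotopologue_distribution,
    propagate,
    scramble,
)

from .conftest import U13C
from .oracle import oracle_pools


def mask_strategy(n):
    return st.tuples(*[st.integers(0, 1)] * n)


class TestNetwork:
    def test_every_reaction_conserves_carbon(self, network):
        for rxn in network.reactions.values():
            total_sub = sum(
                network.metabolite(s).carbon_count for s in rxn.substrates
            )
            assert len(rxn.mapping) + len(rxn.lost) == total_sub

    def test_pdh_loses_pyruvate_c1_and_yields_two_carbon_acetyl(self, network):
        pdh = network.reaction("pdh")
        assert pdh.lost == (("PYR", 1),)
        assert network.metabolite("ACCOA").carbon_count == 2

    def test_only_succinate_and_fumarate_are_symmetric(self, network):
        symmetric = {m.id for m in network.metabolites.values() if m.symmetric}
        assert symmetric == {"SUC", "FUM"}


class TestApplyReaction:
    def test_u13c_pyruvate_gives_fully_labeled_acetyl(self, network):
        pyr = IsotopomerPool.pure("PYR", (1, 1, 1))
        out = apply_reaction({"PYR": pyr}, network.reaction("pdh"), network)
        assert out.pools["ACCOA"].members == {(1, 1): 1.0}
        assert out.labeled_co2 == 1.0

    @pytest.mark.parametrize("rxn_name", ["hk", "ald", "pdh", "cs", "idh", "ogdh"])
    def test_unlabeled_substrates_give_unlabeled_products(self, network, rxn_name):
        rxn = network.reaction(rxn_name)
        pools = {
            s: IsotopomerPool.unlabeled(s, network.metabolite(s).carbon_count)
            for s in rxn.substrates
        }
        out = apply_reaction(pools, rxn, network)
        assert out.labeled_co2 == 0.0
        for pool in out.pools.values():
            assert isotopologue_distribution(pool) == {0: 1.0}

    def test_acetyl_labeled_citrate_reaches_2og_without_labeled_co2(self, network):
        """First-turn M+2 citrate keeps both acetyl carbons through
        aconitase and IDH: 2-oxoglutarate stays entirely M+2."""
        cit = IsotopomerPool.pure("CIT", (1, 1, 0, 0, 0, 0))
        aco = apply_reaction({"CIT": cit}, network.reaction("acn"), network)
        og = apply_reaction(aco.pools, network.reaction("idh"), network)
        assert aco.labeled_co2 == 0.0 and og.labeled_co2 == 0.0
        assert isotopologue_distribution(og.pools["OG2"]) == {2: 1.0}

    def test_mismatched_pool_rejected(self, network):
        bad = IsotopomerPool.pure("PYR", (1, 1))  # wrong mask length
        with pytest.raises(ValueError):
            apply_reaction({"PYR": bad}, network.reaction("pdh"), network)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(mask=mask_strategy(3))
    def test_label_conservation_through_pdh(self, network, mask):
        pyr = IsotopomerPool.pure("PYR", mask)
        out = apply_reaction({"PYR": pyr}, network.reaction("pdh"), network)
        retained = sum(
            sum(m) * w for m, w in out.pools["ACCOA"].members.items()
        )
        assert retained + out.labeled_co2 == pytest.approx(sum(mask))


class TestScrambling:
    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(mask=mask_strategy(4))
    def test_scramble_is_idempotent_and_weight_preserving(self, mask):
        pool = IsotopomerPool.pure("SUC", mask)
        once = scramble(pool)
        twice = scramble(once)
        assert {m: pytest.approx(w) for m, w in twice.members.items()} == once.members
        assert sum(once.members.values()) == pytest.approx(1.0)


class TestPropagate:
    def test_u13c_glucose_first_turn(self, u13c_result):
        """Uniformly labeled glucose: all glycolytic intermediates fully
        labeled, all first-turn TCA intermediates M+2."""
        res = u13c_result
        for met in ("G6P", "F6P", "F16BP", "DHAP", "PG23", "PEP", "PYR"):
            n = res.pool(met).carbon_count
            assert isotopologue_distribution(res.pool(met)) == {n: 1.0}
        for met in ("CIT", "ACO", "OG2", "SUC", "FUM", "MAL", "OAA"):
            assert isotopologue_distribution(res.pool(met, 1)) == {2: 1.0}

    def test_u13c_glucose_second_turn(self, u13c_result):
        res = u13c_result
        assert isotopologue_distribution(res.pool("CIT", 2)) == {4: 1.0}
        og2 = isotopologue_distribution(res.pool("OG2", 2))
        assert og2 == {3: pytest.approx(0.5), 4: pytest.approx(0.5)}
        for met in ("SUC", "FUM", "MAL"):
            assert isotopologue_distribution(res.pool(met, 2)) == {3: 1.0}

    def test_oaa_between_turns_is_50_50_positional(self, u13c_result):
        oaa = u13c_result.pool("OAA", 1)
        assert oaa.members == {
            (1, 1, 0, 0): pytest.approx(0.5),
            (0, 0, 1, 1): pytest.approx(0.5),
        }

    def test_12_labeled_glucose_pyruvate_splits_half_half(self, network):
        res = propagate(network, (1, 1, 0, 0, 0, 0), 1)
        assert isotopologue_distribution(res.pool("PYR")) == {
            0: pytest.approx(0.5),
            2: pytest.approx(0.5),
        }

    def test_unlabeled_tracer_gives_unlabeled_everything(self, network):
        res = propagate(network, (0,) * 6, 2)
        for met in ("G6P", "PYR"):
            assert isotopologue_distribution(res.pool(met)) == {0: 1.0}
        for turn in (1, 2):
            for met in ("CIT", "OG2", "SUC", "MAL"):
                assert isotopologue_distribution(res.pool(met, turn)) == {0: 1.0}

    def test_invalid_inputs_rejected(self, network):
        with pytest.raises(ValueError):
            propagate(network, (1, 1, 1), 1)
        with pytest.raises(ValueError):
            propagate(network, U13C, 3)

    @pytest.mark.parametrize(
        "mask",
        [(1, 0, 0, 0, 0, 0), (0, 0, 1, 1, 0, 0), (1, 0, 1, 0, 1, 0), U13C],
        ids=["1-13C", "3,4-13C", "alternating", "U-13C"],
    )
    def test_matches_exhaustive_path_oracle(self, network, mask):
        res = propagate(network, mask, 2)
        expected = oracle_pools(mask, 2)
        for met, pool in expected["gly"].items():
            assert res.pool(met).members == {
                m: pytest.approx(w) for m, w in pool.items()
            }, met
        for turn in (1, 2):
            for met, pool in expected[turn].items():
                assert res.pool(met, turn).members == {
                    m: pytest.approx(w) for m, w in pool.items()
                }, (met, turn)

    def test_pool_weights_sum_to_one_everywhere(self, u13c_result):
        res = u13c_result
        pools = list(res.glycolytic.values()) + [res.acetyl]
        for turn in res.tca.values():
            pools += list(turn.values())
        for pool in pools:
            assert sum(pool.members.values()) == pytest.approx(1.0)
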