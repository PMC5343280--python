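"""Independent brute-force oracle for positional label propagation.

Enumerates every per-molecule path a glucose tracer can take through
glycolysis and up to two TCA-cycle turns, carrying explicit carbon tuples
and branching exhaustively at every stochastic choice (which triose half,
triose-phosphate equilibration, symmetric-orientation scrambling, and the
independent second acetyl draw).  Deliberately written against hardcoded
carbon index shuffles — not the packaged atom-map tables — so it is an
independent check of the pool-based implementation.
"""

from __future__ import annotations

from itertools import product


def _glycolysis_molecules(glc: tuple[int, ...]):
    """Yield (weight, dhap, ga3p) molecule states after complete triose
    equilibration; each triose pool is a 50/50 mix of the two halves."""
    upper = (glc[0], glc[1], glc[2])  # F16BP C1-C3, DHAP numbering
    lower = (glc[3], glc[4], glc[5])  # F16BP C4-C6, GA3P numbering
    # TPI interconversion reverses the carbon order.
    dhap_pool = [(0.5, upper), (0.5, lower[::-1])]
    ga3p_pool = [(0.5, lower), (0.5, upper[::-1])]
    return dhap_pool, ga3p_pool


def _acetyl_pool(glc: tuple[int, ...]):
    _, ga3p_pool = _glycolysis_molecules(glc)
    # GA3P -> PG23 -> PEP -> PYR keep carbon order; PDH drops pyruvate C1.
    return [(w, (pyr[1], pyr[2])) for w, pyr in ga3p_pool]


def _turn(acetyl: tuple[int, int], oaa: tuple[int, ...]):
    """One TCA turn for a single acetyl + oxaloacetate pair; yields
    (weight, met -> mask) over all scrambling orientations."""
    cit = (acetyl[0], acetyl[1], oaa[1], oaa[2], oaa[3], oaa[0])
    aco = cit
    og2 = (cit[4], cit[3], cit[2], cit[1], cit[0])  # IDH drops cit C6
    suc = (og2[1], og2[2], og2[3], og2[4])  # OGDH drops og2 C1
    for flip_suc, flip_fum in product((False, True), repeat=2):
        s = suc[::-1] if flip_suc else suc
        fum = s[::-1] if flip_fum else s
        mal = fum
        yield 0.25, {"CIT": cit, "ACO": aco, "OG2": og2, "SUC": s,
                     "FUM": fum, "MAL": mal, "OAA": mal}


def oracle_pools(glc: tuple[int, ...], n_turns: int = 2):
    """Exhaustive-path pools: {"gly": {met: {mask: w}}, 1: {...}, 2: {...}}."""
    dhap_pool, ga3p_pool = _glycolysis_molecules(glc)
    gly: dict[str, dict[tuple, float]] = {
        "GLC": {glc: 1.0}, "G6P": {glc: 1.0}, "F6P": {glc: 1.0}, "F16BP": {glc: 1.0},
    }
    for met, pool in (("DHAP", dhap_pool), ("GA3P", ga3p_pool)):
        gly[met] = {}
        for w, m in pool:
            gly[met][m] = gly[met].get(m, 0.0) + w
    for met in ("PG23", "PEP", "PYR"):
        gly[met] = dict(gly["GA3P"])

    out: dict = {"gly": gly, 1: {}, 2: {}}
    acetyl = _acetyl_pool(glc)
    oaa0 = (0, 0, 0, 0)

    def add(turn: int, w: float, mets: dict[str, tuple]) -> None:
        for met, mask in mets.items():
            pool = out[turn].setdefault(met, {})
            pool[mask] = pool.get(mask, 0.0) + w

    for w1, ac1 in acetyl:
        for wt, mets in _turn(ac1, oaa0):
            add(1, w1 * wt, mets)
            if n_turns == 2:
                # the second acetyl is an independent draw from the pool
                for w2, ac2 in acetyl:
                    for wt2, mets2 in _turn(ac2, mets["OAA"]):
                        add(2, w1 * wt * w2 * wt2, mets2)
    return out
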