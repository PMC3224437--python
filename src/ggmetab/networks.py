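"""Library of small reaction-network motifs.

These systems probe how well correlation-based reconstruction recovers known
topology: reversible vs irreversible chains, exchange reactions, branching,
end-product inhibition, cofactor coupling, and bimolecular kinetics.  All
internal rate constants default to 1 and enzymatic forward maximal rates are
twice the backward rates (a directed mass flow).
"""

from __future__ import annotations

from .kinetics import (
    MASS_ACTION,
    MIXED_INHIBITION,
    REVERSIBLE_MM,
    MMParams,
    Reaction,
    ReactionNetwork,
)

__all__ = ["make_network", "available_networks"]


def _ma(name: str, educts: dict, products: dict, k: float = 1.0) -> Reaction:
    return Reaction(name=name, educts=educts, products=products, law=MASS_ACTION, k=k)


def _input(met: str, k: float = 1.0) -> Reaction:
    """Zeroth-order input reaction (constant influx)."""
    return _ma(f"in_{met}", {}, {met: 1}, k)


def _output(met: str, k: float = 1.0) -> Reaction:
    """First-order output reaction (linear efflux)."""
    return _ma(f"out_{met}", {met: 1}, {}, k)


def _mm(name: str, s: str, p: str, inhibitor: str | None = None, ki: float = 1.0) -> Reaction:
    params = MMParams(
        vmax_fwd=2.0,
        vmax_bwd=1.0,
        km_s=1.0,
        km_p=1.0,
        inhibitor_id=inhibitor,
        ki=ki if inhibitor else None,
        kii=ki if inhibitor else None,
    )
    law = MIXED_INHIBITION if inhibitor else REVERSIBLE_MM
    return Reaction(name=name, educts={s: 1}, products={p: 1}, law=law, mm=params)


# Reversible intermediate reactions run an order of magnitude faster than the
# exchange fluxes: the near-equilibrium regime these motifs represent
# (metabolites in mutual equilibrium through fast reversible reactions).
_K_FAST = 10.0


def _chain_reversible() -> ReactionNetwork:
    # A <-> B <-> C with input to A and output from C.
    return ReactionNetwork(
        ["A", "B", "C"],
        [
            _input("A"),
            _ma("AB_f", {"A": 1}, {"B": 1}, _K_FAST),
            _ma("AB_b", {"B": 1}, {"A": 1}, _K_FAST),
            _ma("BC_f", {"B": 1}, {"C": 1}, _K_FAST),
            _ma("BC_b", {"C": 1}, {"B": 1}, _K_FAST),
            _output("C"),
        ],
    )


def _chain_irreversible() -> ReactionNetwork:
    # A -> B -> C; A is the sole input and determines everything downstream.
    return ReactionNetwork(
        ["A", "B", "C"],
        [
            _input("A"),
            _ma("AB", {"A": 1}, {"B": 1}),
            _ma("BC", {"B": 1}, {"C": 1}),
            _output("C"),
        ],
    )


def _chain_irreversible_exchange() -> ReactionNetwork:
    # Irreversible chain, but every metabolite exchanges with the environment.
    return ReactionNetwork(
        ["A", "B", "C"],
        [
            _ma("AB", {"A": 1}, {"B": 1}),
            _ma("BC", {"B": 1}, {"C": 1}),
            _input("A"),
            _output("A"),
            _input("B"),
            _output("B"),
            _input("C"),
            _output("C"),
        ],
    )


def _branched() -> ReactionNetwork:
    # Diamond A -> {B, C} -> D with reversible internal reactions.
    rx = [_input("A")]
    for a, b in [("A", "B"), ("A", "C"), ("B", "D"), ("C", "D")]:
        rx.append(_ma(f"{a}{b}_f", {a: 1}, {b: 1}, _K_FAST))
        rx.append(_ma(f"{a}{b}_b", {b: 1}, {a: 1}, _K_FAST))
    rx.append(_output("D"))
    return ReactionNetwork(["A", "B", "C", "D"], rx)


def _end_product_inhibition(open_system: bool, ki: float = 1.0) -> ReactionNetwork:
    # A -> B -> C -> D enzymatic chain; D inhibits the first reaction.
    # Input flux stays well below the enzymes' maximal rates so that every
    # parameter draw admits a steady state; the margin is wider here because
    # end-product inhibition further reduces the first enzyme's capacity.
    rx = [
        _input("A", k=0.25),
        _mm("AB", "A", "B", inhibitor="D", ki=ki),
        _mm("BC", "B", "C"),
        _mm("CD", "C", "D"),
        _output("D"),
    ]
    if open_system:
        for met in ("B", "C"):
            rx.append(_input(met))
            rx.append(_output(met))
    return ReactionNetwork(["A", "B", "C", "D"], rx)


def _cofactor_glycolysis() -> ReactionNetwork:
    # Backbone G1 -> G2 <-> G3 -> G4 with two ATP-consuming phosphorylations,
    # mirroring the first reactions of glycolysis; cofactors exchange with the
    # surrounding metabolism.
    return ReactionNetwork(
        ["G1", "G2", "G3", "G4", "ATP", "ADP"],
        [
            _input("G1"),
            _ma("hexokinase", {"G1": 1, "ATP": 1}, {"G2": 1, "ADP": 1}),
            _ma("isomerase_f", {"G2": 1}, {"G3": 1}),
            _ma("isomerase_b", {"G3": 1}, {"G2": 1}),
            _ma("pfk", {"G3": 1, "ATP": 1}, {"G4": 1, "ADP": 1}),
            _output("G4"),
            # the hexose-phosphate intermediates branch into other pathways
            # (pentose-phosphate, glycogen, hexosamine): exchange reactions,
            # without which flux conservation ties G4 rigidly to the G1 input
            _input("G2"),
            _output("G2"),
            _input("G3"),
            _output("G3"),
            # cofactor supply must structurally exceed the two phosphorylation
            # fluxes (~2x the backbone input) or no positive steady state exists
            _input("ATP", k=10.0),
            _output("ATP"),
            _input("ADP"),
            _output("ADP"),
        ],
    )


def _bimolecular_split() -> ReactionNetwork:
    # A <-> B + C with isomerization B <-> C (aldolase-like split).
    return ReactionNetwork(
        ["A", "B", "C"],
        [
            _input("A"),
            _ma("split_f", {"A": 1}, {"B": 1, "C": 1}),
            _ma("split_b", {"B": 1, "C": 1}, {"A": 1}),
            _ma("iso_f", {"B": 1}, {"C": 1}),
            _ma("iso_b", {"C": 1}, {"B": 1}),
            _output("B"),
            _output("C"),
        ],
    )


def _mm_chain() -> ReactionNetwork:
    # Four-metabolite enzymatic chain, forward Vmax twice the backward Vmax;
    # input flux kept below enzyme capacity for steady-state feasibility.
    return ReactionNetwork(
        ["A", "B", "C", "D"],
        [
            _input("A", k=0.5),
            _mm("AB", "A", "B"),
            _mm("BC", "B", "C"),
            _mm("CD", "C", "D"),
            _output("D"),
        ],
    )


_LIBRARY = {
    "chain_reversible": _chain_reversible,
    "chain_irreversible": _chain_irreversible,
    "chain_irreversible_exchange": _chain_irreversible_exchange,
    "branched": _branched,
    "end_product_inhibition_closed": lambda: _end_product_inhibition(False),
    "end_product_inhibition_open": lambda: _end_product_inhibition(True),
    "cofactor_glycolysis": _cofactor_glycolysis,
    "bimolecular_split": _bimolecular_split,
    "mm_chain": _mm_chain,
}


def available_networks() -> list[str]:
    return sorted(_LIBRARY)


def make_network(name: str, **kwargs) -> ReactionNetwork:
    """Build a library network by name.

    ``end_product_inhibition_*`` accept ``ki`` to vary inhibition strength.
    """
    if name not in _LIBRARY:
        raise KeyError(f"unknown network {name!r}; available: {available_networks()}")
    if name.startswith("end_product_inhibition") and kwargs:
        return _end_product_inhibition(name.endswith("open"), **kwargs)
    return _LIBRARY[name]()
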