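"""Frozen SYBYL atom-type rule table for chemical feature perception.

This table is the single source of truth mapped onto structures by
:func:`igocsvm.structio.perceive_chemistry`. It is an explicit, documented
approximation: the upstream interaction-detection tool does not publish its
typing rules, so tests pin this table rather than an external reference.

Conventions
-----------
* A nitrogen or oxygen is a hydrogen-bond donor iff it carries at least one
  explicit hydrogen, or its type is in :data:`ALWAYS_DONOR_TYPES`.
* ``N.ar`` is an acceptor only without an attached hydrogen (pyridine vs
  pyrrole).
* Carboxylate oxygens (``O.co2``) are anionic; so are oxygens bonded to a
  phosphate- or sulfate-like centre.
* Every heavy carbon and sulfur atom is flagged hydrophobic here; the
  stricter environment rule lives in :mod:`igocsvm.interactions`.
"""

from __future__ import annotations

#: N/O types that count as donors even without an explicit hydrogen
#: (quaternary/protonated nitrogens are often written without H in MD dumps).
ALWAYS_DONOR_TYPES = frozenset({"N.4"})

#: Elements that may donate when carrying an explicit hydrogen.
DONOR_ELEMENTS = frozenset({"N", "O"})

#: Acceptor types. ``N.ar`` is additionally gated on having no hydrogen.
ACCEPTOR_TYPES = frozenset({"O.2", "O.3", "O.co2", "N.1", "N.2", "N.ar"})

#: Aromatic-N acceptor gate.
ACCEPTOR_TYPES_NO_H = frozenset({"N.ar"})

#: Cationic nitrogen types.
CATION_TYPES = frozenset({"N.4"})

#: A nitrogen bonded to one of these carbon types is cationic
#: (guanidinium / amidinium).
CATION_NEIGHBOUR_TYPES = frozenset({"C.cat"})

#: Intrinsically anionic types.
ANION_TYPES = frozenset({"O.co2"})

#: Oxygen bonded to one of these types is anionic (phosphate / sulfate).
ANION_NEIGHBOUR_TYPES = frozenset({"P.3", "S.o2", "S.O2", "S.o", "S.O"})

#: Elements treated as chelatable / chargeable metals.
METAL_ELEMENTS = frozenset(
    {"Li", "Na", "K", "Rb", "Cs", "Mg", "Ca", "Sr", "Ba",
     "Mn", "Fe", "Co", "Ni", "Cu", "Zn", "Cd", "Hg"}
)

#: Elements contributing hydrophobic contacts (environment rule applied later).
HYDROPHOBIC_ELEMENTS = frozenset({"C", "S"})

#: Types participating in aromatic ring perception.
AROMATIC_TYPES = frozenset({"C.ar", "N.ar"})

#: Ring sizes considered aromatic.
AROMATIC_RING_SIZES = (5, 6)


def element_of(sybyl_type: str) -> str:
    """Element symbol implied by a SYBYL atom type (``"N.3"`` -> ``"N"``)."""
    head = sybyl_type.split(".", 1)[0]
    return head.capitalize()


def is_charged_type(sybyl_type: str) -> bool:
    """True for types carrying an intrinsic formal charge."""
    return (
        sybyl_type in CATION_TYPES
        or sybyl_type in ANION_TYPES
        or sybyl_type in CATION_NEIGHBOUR_TYPES
        or element_of(sybyl_type) in METAL_ELEMENTS
    )
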