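"""Pilin subunit alphabet of the E. coli P pilus.

The six pilins PapG, PapF, PapE, PapK, PapA and PapH are referred to by their
single-letter symbols throughout.  The canonical order ``G, F, E, K, A, H`` is
the natural order of the subunits along a mature pilus (adhesin tip to
membrane anchor) and is used for every table, matrix and output file.
"""

from __future__ import annotations

SUBUNITS: tuple[str, ...] = ("G", "F", "E", "K", "A", "H")
"""Canonical subunit order: adhesin PapG first, terminator PapH last."""

TRANSIENT: tuple[str, ...] = SUBUNITS[:5]
"""Acceptor states that can still grow (PapH never accepts a donor strand)."""

INDEX: dict[str, int] = {s: i for i, s in enumerate(SUBUNITS)}

#: Row labels of the rate-table CSV dialect (chaperone:subunit complexes).
ROW_LABELS: tuple[str, ...] = tuple(f"Pap{s}" for s in SUBUNITS)

#: Column labels of the rate-table CSV dialect (N-terminal-extension donors).
NTE_LABELS: tuple[str, ...] = tuple(f"{s}_Nte" for s in SUBUNITS)

#: Donor/acceptor pairs adjacent in the natural pilus order.  These are the
#: cells of the hypothetical fast/slow rate scheme that carry the fast rate:
#: (acceptor, donor) with the donor extending a pilus ending in the acceptor.
COGNATE_PAIRS: frozenset[tuple[str, str]] = frozenset(
    {("G", "F"), ("F", "E"), ("E", "E"), ("E", "K"), ("K", "A"), ("A", "A")}
)


def check_symbol(symbol: str) -> str:
    """Validate a subunit symbol, returning it unchanged."""
    if symbol not in INDEX:
        raise ValueError(
            f"unknown subunit {symbol!r}; expected one of {', '.join(SUBUNITS)}"
        )
    return symbol
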