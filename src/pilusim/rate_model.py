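"""Pairwise donor-strand-exchange (DSE) rate tables and pilin concentrations.

A :class:`RateTable` holds the 6x6 matrix of apparent pseudo-first-order DSE
rate constants ``k[acceptor][donor]`` in units of 1e-3 / h, i.e. the printed
unit of the published in vitro measurements (an entry of 5.5 means
5.5e-3 h^-1).  Rows are chaperone:pilin acceptor complexes, columns are
N-terminal-extension donors.  Two structural zeros are enforced:

* the PapG donor column is zero (PapG's Nte is part of its lectin domain and
  never donates), and
* the PapH acceptor row is zero (PapH's P5 pocket is obstructed, so it never
  undergoes DSE — it terminates growth).

A :class:`ConcentrationProfile` carries the relative abundance of each pilin
at the assembly site.  Only ratios matter downstream; profiles are therefore
never normalised.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .subunits import (
    COGNATE_PAIRS,
    INDEX,
    NTE_LABELS,
    ROW_LABELS,
    SUBUNITS,
    check_symbol,
)

__all__ = [
    "RateTable",
    "ConcentrationProfile",
    "RateTableError",
    "builtin_table",
    "read_rate_table",
    "write_rate_table",
    "read_concentration",
    "write_concentration",
    "uniform_profile",
    "scaled_profile",
    "BUILTIN_NAMES",
]


class RateTableError(ValueError):
    """Raised when a rate table violates the model's structural invariants."""


# In vitro apparent pseudo-first-order DSE rate constants, 1e-3 / h, measured
# by non-covalent electrospray MS with Nte peptide mimetics in excess.  The
# two "~" entries of the published table (~0.7 and ~1) are taken at face
# value; no error model is attached to them.
_IN_VITRO = np.array(
    [
        # donor:  G     F      E      K      A      H
        [0.0, 5.5, 0.7, 0.7, 0.7, 0.7],  # acceptor PapD-PapG
        [0.0, 2.7, 9.4, 4.7, 2.8, 2.5],  # PapD-PapF
        [0.0, 65.7, 190.2, 210.8, 39.9, 48.6],  # PapD-PapE
        [0.0, 1.0, 1.0, 1.6, 53.6, 26.6],  # PapD-PapK
        [0.0, 2.9, 3.3, 9.0, 45.8, 22.9],  # PapD-PapA
        [0.0, 0.0, 0.0, 0.0, 0.0, 0.0],  # PapD-PapH (never accepts)
    ]
)

BUILTIN_NAMES = ("in_vitro", "hypothetical_R", "hypothetical_R_ratio", "equal")


@dataclass(frozen=True)
class RateTable:
    """6x6 acceptor x donor DSE rate matrix in units of 1e-3 / h."""

    k: pd.DataFrame
    name: str = "custom"

    def __post_init__(self) -> None:
        k = self.k
        if list(k.index) != list(SUBUNITS) or list(k.columns) != list(SUBUNITS):
            k = k.reindex(index=SUBUNITS, columns=SUBUNITS)
            object.__setattr__(self, "k", k)
        validate_rate_table(self)

    def rate(self, acceptor: str, donor: str) -> float:
        """Rate constant for ``donor`` extending a pilus ending in ``acceptor``."""
        return float(self.k.at[check_symbol(acceptor), check_symbol(donor)])

    def values(self) -> np.ndarray:
        return self.k.to_numpy(dtype=float)

    def row_sums(self) -> pd.Series:
        """Total DSE rate out of each acceptor state (1e-3 / h, uniform conc.)."""
        return self.k.sum(axis=1)

    def equals(self, other: "RateTable") -> bool:
        return np.array_equal(self.values(), other.values())


def validate_rate_table(table: RateTable) -> None:
    """Enforce nonnegativity, finiteness and the two structural zero patterns."""
    vals = table.k.to_numpy(dtype=float)
    if not np.all(np.isfinite(vals)):
        bad = np.argwhere(~np.isfinite(vals))[0]
        raise RateTableError(
            f"non-finite rate at ({ROW_LABELS[bad[0]]}, {NTE_LABELS[bad[1]]})"
        )
    if np.any(vals < 0):
        bad = np.argwhere(vals < 0)[0]
        raise RateTableError(
            f"negative rate at ({ROW_LABELS[bad[0]]}, {NTE_LABELS[bad[1]]})"
        )
    g = INDEX["G"]
    if np.any(vals[:, g] != 0):
        bad = int(np.argwhere(vals[:, g] != 0)[0][0])
        raise RateTableError(
            f"PapG never donates: column G_Nte must be zero, found "
            f"{vals[bad, g]} at ({ROW_LABELS[bad]}, G_Nte)"
        )
    h = INDEX["H"]
    if np.any(vals[h, :] != 0):
        bad = int(np.argwhere(vals[h, :] != 0)[0][0])
        raise RateTableError(
            f"PapH never accepts: row PapH must be zero, found "
            f"{vals[h, bad]} at (PapH, {NTE_LABELS[bad]})"
        )


@dataclass(frozen=True)
class ConcentrationProfile:
    """Relative pilin abundances (dimensionless; only ratios matter)."""

    weight: pd.Series

    def __post_init__(self) -> None:
        w = self.weight.reindex(SUBUNITS).astype(float)
        object.__setattr__(self, "weight", w)
        vals = w.to_numpy()
        if np.any(~np.isfinite(vals)) or np.any(vals < 0):
            raise ValueError("concentration weights must be finite and >= 0")
        if not np.any(vals > 0):
            raise ValueError("at least one concentration weight must be positive")

    def of(self, subunit: str) -> float:
        return float(self.weight[check_symbol(subunit)])

    def values(self) -> np.ndarray:
        return self.weight.to_numpy(dtype=float)


def uniform_profile() -> ConcentrationProfile:
    """Equal relative concentration of all six pilins (the default)."""
    return ConcentrationProfile(pd.Series(1.0, index=list(SUBUNITS)))


def scaled_profile(
    base: ConcentrationProfile, subunit: str, factor: float
) -> ConcentrationProfile:
    """Return ``base`` with one pilin's relative concentration multiplied.

    This is the elementary move of the concentration sweeps: e.g. raising
    [PapA] 200-fold or depleting [PapH] 10-fold.  ``base`` is not modified.
    """
    if not factor > 0:
        raise ValueError(f"scale factor must be > 0, got {factor}")
    w = base.weight.copy()
    w[check_symbol(subunit)] *= factor
    return ConcentrationProfile(w)


def _fast_slow_table(k_fast: float, ratio: float, name: str) -> RateTable:
    """Fast/slow rate pattern: cognate pairs fast, all other permitted
    donor/acceptor pairs slower by ``ratio`` (structural zeros kept)."""
    if not ratio >= 1:
        raise ValueError(f"fast/slow ratio must be >= 1, got {ratio}")
    if not k_fast > 0:
        raise ValueError(f"k_fast must be > 0, got {k_fast}")
    vals = np.full((6, 6), k_fast / ratio)
    for acc, don in COGNATE_PAIRS:
        vals[INDEX[acc], INDEX[don]] = k_fast
    vals[:, INDEX["G"]] = 0.0
    vals[INDEX["H"], :] = 0.0
    frame = pd.DataFrame(vals, index=list(SUBUNITS), columns=list(SUBUNITS))
    return RateTable(frame, name=name)


def builtin_table(name: str, ratio: float | None = None) -> RateTable:
    """Return one of the built-in DSE rate tables.

    Parameters
    ----------
    name
        ``"in_vitro"``
            The published apparent pseudo-first-order rates (1e-3 / h).
        ``"hypothetical_R"``
            The hypothetical scheme that warrants growth: cognate pairs at
            1000, every other permitted pair at 1 (i.e. 1000-fold slower).
        ``"hypothetical_R_ratio"``
            Same pattern with slow = 1000 / ``ratio``; requires ``ratio``.
        ``"equal"``
            Every permitted entry equal to 1 (completely random growth).
    ratio
        Fast/slow rate ratio, only for ``"hypothetical_R_ratio"``.
    """
    if name == "in_vitro":
        frame = pd.DataFrame(
            _IN_VITRO.copy(), index=list(SUBUNITS), columns=list(SUBUNITS)
        )
        return RateTable(frame, name="in_vitro")
    if name == "hypothetical_R":
        return _fast_slow_table(1000.0, 1000.0, "hypothetical_R")
    if name == "hypothetical_R_ratio":
        if ratio is None:
            raise ValueError("hypothetical_R_ratio requires a ratio argument")
        return _fast_slow_table(1000.0, float(ratio), f"hypothetical_R_ratio_{ratio:g}")
    if name == "equal":
        return _fast_slow_table(1.0, 1.0, "equal")
    raise ValueError(
        f"unknown built-in table {name!r}; valid names: {', '.join(BUILTIN_NAMES)}"
    )


# ---------------------------------------------------------------------------
# CSV I/O.  Dialect: header `acceptor,G_Nte,F_Nte,E_Nte,K_Nte,A_Nte,H_Nte`,
# six rows labelled PapG..PapH in canonical order, plain decimal floats.
# ---------------------------------------------------------------------------

def write_rate_table(table: RateTable, path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["acceptor", *NTE_LABELS])
        for row_label, acc in zip(ROW_LABELS, SUBUNITS):
            writer.writerow(
                [row_label, *(repr(float(v)) for v in table.k.loc[acc])]
            )


def read_rate_table(path, name: str | None = None) -> RateTable:
    with open(path, newline="") as fh:
        rows = list(csv.reader(fh))
    if not rows or rows[0] != ["acceptor", *NTE_LABELS]:
        raise RateTableError(
            f"bad header in {path}: expected 'acceptor,{','.join(NTE_LABELS)}'"
        )
    body = [r for r in rows[1:] if r]
    labels = [r[0] for r in body]
    if labels != list(ROW_LABELS):
        missing = sorted(set(ROW_LABELS) - set(labels))
        raise RateTableError(
            f"rate table must have rows {', '.join(ROW_LABELS)} in order; "
            + (f"missing {', '.join(missing)}" if missing else f"found {labels}")
        )
    vals = np.zeros((6, 6))
    for i, row in enumerate(body):
        if len(row) != 7:
            raise RateTableError(f"row {row[0]} has {len(row) - 1} cells, expected 6")
        for j, cell in enumerate(row[1:]):
            try:
                vals[i, j] = float(cell)
            except ValueError:
                raise RateTableError(
                    f"parse error at ({ROW_LABELS[i]}, {NTE_LABELS[j]}): "
                    f"non-numeric cell {cell!r}"
                ) from None
    frame = pd.DataFrame(vals, index=list(SUBUNITS), columns=list(SUBUNITS))
    return RateTable(frame, name=name or "custom")


def write_concentration(profile: ConcentrationProfile, path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["subunit", "weight"])
        for s in SUBUNITS:
            writer.writerow([s, repr(float(profile.weight[s]))])


def read_concentration(path) -> ConcentrationProfile:
    with open(path, newline="") as fh:
        rows = list(csv.reader(fh))
    if not rows or rows[0] != ["subunit", "weight"]:
        raise ValueError(f"bad header in {path}: expected 'subunit,weight'")
    weights: dict[str, float] = {}
    for row in rows[1:]:
        if not row:
            continue
        sym = check_symbol(row[0])
        try:
            weights[sym] = float(row[1])
        except (IndexError, ValueError):
            raise ValueError(f"parse error at subunit {sym}: {row[1:]}") from None
    missing = [s for s in SUBUNITS if s not in weights]
    if missing:
        raise ValueError(f"concentration file missing subunits {', '.join(missing)}")
    return ConcentrationProfile(pd.Series(weights))
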