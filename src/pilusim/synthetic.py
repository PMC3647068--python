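"""Synthetic rate tables, concentration profiles and ensemble fixtures.

Real DSE rate measurements have a cognate-fast / non-cognate-slow structure;
the generator reproduces exactly that: cognate cells (the fast cells of the
hypothetical growth-warranting scheme: G->F, F->E, E->E, E->K, K->A, A->A)
at ``k_fast``, every other permitted cell at ``k_fast / ratio``, structural
zeros kept.  Optional multiplicative lognormal noise (mean 1, coefficient of
variation ``noise_cv``) emulates measurement scatter while keeping every
entry positive, so generated tables always pass validation.

Concentration patterns mirror the study conditions: uniform, PapA-dominant
(the main-rod subunit in excess) or PapH-depleted (terminator scarce).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import chain, growth
from .rate_model import (
    ConcentrationProfile,
    RateTable,
    scaled_profile,
    uniform_profile,
    validate_rate_table,
)
from .subunits import COGNATE_PAIRS, INDEX, SUBUNITS

__all__ = ["SyntheticSpec", "make_rate_table", "make_concentration", "make_ensemble_fixture"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of a synthetic fast/slow DSE rate scheme."""

    ratio: float = 1000.0  # k_fast / k_slow
    k_fast: float = 1000.0  # 1e-3 / h
    noise_cv: float = 0.0  # multiplicative lognormal CV per entry
    conc_pattern: str = "uniform"  # uniform | A_dominant | H_depleted
    conc_factor: float = 1.0  # fold-change for the non-uniform patterns
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.ratio >= 1:
            raise ValueError(f"ratio must be >= 1, got {self.ratio}")
        if not self.k_fast > 0:
            raise ValueError(f"k_fast must be > 0, got {self.k_fast}")
        if self.noise_cv < 0:
            raise ValueError(f"noise_cv must be >= 0, got {self.noise_cv}")
        if self.conc_pattern not in ("uniform", "A_dominant", "H_depleted"):
            raise ValueError(f"unknown conc_pattern {self.conc_pattern!r}")


def make_rate_table(spec: SyntheticSpec) -> RateTable:
    """Generate a fast/slow rate table, optionally with lognormal noise.

    With ``noise_cv == 0`` the output is a deterministic function of
    (ratio, k_fast); ``spec(ratio=1000, k_fast=1000)`` reproduces the
    hypothetical growth-warranting table exactly and ``ratio=1`` erases the
    cognate/non-cognate distinction.
    """
    vals = np.full((6, 6), spec.k_fast / spec.ratio)
    for acc, don in COGNATE_PAIRS:
        vals[INDEX[acc], INDEX[don]] = spec.k_fast
    vals[:, INDEX["G"]] = 0.0
    vals[INDEX["H"], :] = 0.0
    if spec.noise_cv > 0:
        rng = np.random.default_rng(spec.seed)
        sigma2 = np.log1p(spec.noise_cv**2)
        noise = rng.lognormal(mean=-sigma2 / 2, sigma=np.sqrt(sigma2), size=(6, 6))
        mask = vals > 0
        vals[mask] *= noise[mask]
    table = RateTable(
        pd.DataFrame(vals, index=list(SUBUNITS), columns=list(SUBUNITS)),
        name=f"synthetic_r{spec.ratio:g}_cv{spec.noise_cv:g}",
    )
    validate_rate_table(table)
    return table


def make_concentration(spec: SyntheticSpec) -> ConcentrationProfile:
    """Concentration profile matching the spec's pattern."""
    profile = uniform_profile()
    if spec.conc_pattern == "A_dominant":
        profile = scaled_profile(profile, "A", spec.conc_factor)
    elif spec.conc_pattern == "H_depleted":
        profile = scaled_profile(profile, "H", 1.0 / spec.conc_factor)
    return profile


def make_ensemble_fixture(
    model: chain.TransitionModel,
    n_pili: int,
    seed: int,
    path,
    length_cap: int = growth.DEFAULT_LENGTH_CAP,
) -> list[growth.PilusRecord]:
    """Write a deterministic sequence-level ensemble TSV for fitting tests."""
    records = growth.simulate_records(model, n_pili, seed, length_cap)
    growth.write_ensemble_tsv(records, path)
    return records
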