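"""Bundled population-parameter sets.

Two published summary-parameter blocks for fish-abundance survey populations
(N = 69 lake-survey units; the auxiliary variable is the catch of an earlier
year, its ranks the second auxiliary variable).  These ship with the package
so the numerical comparisons run without any external data.

Note the block carries the sampling factor as printed (0.0521739, rounded
from 1/15 - 1/69); the published result tables were computed with the rounded
value, so the fixtures preserve it.
"""

from __future__ import annotations

from .moments import DesignSpec, MomentSet

__all__ = ["FISH_POPULATION_1", "FISH_POPULATION_2", "builtin_params", "load_fixture"]

# Study variable: fish caught in 1995.  Auxiliary: fish caught in 1994.
FISH_POPULATION_1 = {
    "N": 69,
    "n": 15,
    "lam": 0.0521739,
    "mean_y": 4514.899,
    "mean_x": 4954.435,
    "mean_rx": 35.0,
    "Sy2": 37199578.0,
    "Sx2": 49829270.0,
    "Srx2": 402.5,
    "rho_yx": 0.9601401,
    "rho_yrx": 0.7688589,
    "rho_xrx": 0.7543462,
    "lam400s": 6.544991,
    "lam040s": 8.69773,
    "lam004s": 0.747145,
    "lam220s": 7.053057,
    "lam202s": 1.159139,
    "lam022s": 1.298094,
}

# Same study variable; auxiliary: fish caught in 1993.
FISH_POPULATION_2 = {
    "N": 69,
    "n": 15,
    "lam": 0.0521739,
    "mean_y": 4514.899,
    "mean_x": 4591.072,
    "mean_rx": 35.0,
    "Sy2": 37199578.0,
    "Sx2": 39881874.0,
    "Srx2": 402.5,
    "rho_yx": 0.9564207,
    "rho_yrx": 0.7539346,
    "rho_xrx": 0.7593837,
    "lam400s": 6.544991,
    "lam040s": 8.698631,
    "lam004s": 0.747145,
    "lam220s": 7.190264,
    "lam202s": 1.157465,
    "lam022s": 1.303701,
}

_BUILTIN = {
    "population1": FISH_POPULATION_1,
    "population2": FISH_POPULATION_2,
}


def builtin_params(name: str) -> dict:
    """Return a copy of a bundled parameter block by name."""
    try:
        return dict(_BUILTIN[name])
    except KeyError:
        raise KeyError(
            f"unknown builtin parameter set {name!r}; available: {sorted(_BUILTIN)}"
        ) from None


def load_fixture(name: str) -> tuple[MomentSet, DesignSpec]:
    """Bundled parameter block as ready-to-use (MomentSet, DesignSpec)."""
    from .io_cli import load_table1_params

    return load_table1_params(builtin_params(name))
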