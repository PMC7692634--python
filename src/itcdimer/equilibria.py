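"""Coupled mass-action equilibria of the ligand-bridged dimerization scheme.

The scheme is two sequential equilibria:

    P + L  <=>  PL     (dissociation constant Kd1)
    PL + P <=>  P2L    (dissociation constant Kd2)

A ligand L binds one receptor chain P; the 1:1 complex PL presents a
surface that recruits a second receptor chain, forming the 2:1 sandwich
P2L.  Because every sandwich consumes a PL complex, raising the ligand
concentration far above the receptor concentration converts all receptor
into PL and starves the second equilibrium: sandwich abundance is
bell-shaped ("hook" or prozone effect) in the ligand:receptor molar ratio.

All concentrations are molar.  Helper constructors :func:`uM` and
:func:`mM` convert the bench units that protocols are usually written in.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from scipy.optimize import brentq

__all__ = [
    "uM",
    "mM",
    "BindingParameters",
    "Composition",
    "SpeciesState",
    "solve_species",
    "dimer_fraction",
    "speciation_profile",
]


def uM(x: float) -> float:
    """Convert micromolar to molar."""
    return float(x) * 1e-6


def mM(x: float) -> float:
    """Convert millimolar to molar."""
    return float(x) * 1e-3


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ValueError(msg)


@dataclass(frozen=True)
class BindingParameters:
    """Thermodynamic state of the two-event binding scheme.

    Parameters
    ----------
    kd1 : float
        Dissociation constant of P + L <=> PL, molar. Must be finite and > 0.
    kd2 : float
        Dissociation constant of PL + P <=> P2L, molar. Must be > 0;
        ``math.inf`` is accepted and means the second event is absent
        (exact single-site limit).
    dh1, dh2 : float
        Molar enthalpies of the two events, cal/mol. Any sign.
    q_dil : float
        Per-injection dilution-heat offset, µcal. Any sign.
    """

    kd1: float
    kd2: float
    dh1: float = 0.0
    dh2: float = 0.0
    q_dil: float = 0.0

    def __post_init__(self) -> None:
        _require(math.isfinite(self.kd1) and self.kd1 > 0, f"kd1 must be finite and > 0, got {self.kd1}")
        _require(self.kd2 > 0 and not math.isnan(self.kd2), f"kd2 must be > 0, got {self.kd2}")
        for name in ("dh1", "dh2", "q_dil"):
            _require(not math.isnan(getattr(self, name)), f"{name} must not be NaN")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "BindingParameters":
        return cls(**d)


@dataclass(frozen=True)
class Composition:
    """Total receptor and ligand concentrations (molar) at one point."""

    p_total: float
    l_total: float

    def __post_init__(self) -> None:
        for name in ("p_total", "l_total"):
            v = getattr(self, name)
            _require(math.isfinite(v) and v >= 0, f"{name} must be finite and >= 0, got {v}")


@dataclass(frozen=True)
class SpeciesState:
    """Equilibrium concentrations (molar) of the four species."""

    p_free: float
    l_free: float
    pl: float
    p2l: float

    @property
    def p_total(self) -> float:
        return self.p_free + self.pl + 2.0 * self.p2l

    @property
    def l_total(self) -> float:
        return self.l_free + self.pl + self.p2l


def _solve_raw(p_tot: float, l_tot: float, kd1: float, kd2: float):
    """Core root solve; returns (p_free, l_free, pl, p2l) as plain floats.

    Shared by :func:`solve_species` and the ITC heat bookkeeping, which
    calls it in a tight per-injection loop.
    """
    if p_tot == 0.0 and l_tot == 0.0:
        return 0.0, 0.0, 0.0, 0.0
    if l_tot == 0.0:
        return p_tot, 0.0, 0.0, 0.0
    if p_tot == 0.0:
        return 0.0, l_tot, 0.0, 0.0

    c2 = 1.0 / (kd1 * kd2) if math.isfinite(kd2) else 0.0

    def l_free_of(p: float) -> float:
        # ligand balance: l_tot = l*(1 + p/kd1 + p^2/(kd1*kd2))
        return l_tot / (1.0 + p / kd1 + p * p * c2)

    def resid(p: float) -> float:
        # receptor balance: p + [PL] + 2[P2L] - p_tot, monotone increasing in p
        l = l_free_of(p)
        return p * (1.0 + l / kd1 + 2.0 * p * l * c2) - p_tot

    # resid(0) = -p_tot < 0, resid(p_tot) >= 0: bracket always exists
    r_hi = resid(p_tot)
    assert r_hi >= 0.0, "failed to bracket the equilibrium root"
    if r_hi == 0.0:
        p = p_tot
    else:
        p = brentq(resid, 0.0, p_tot, xtol=1e-30, rtol=1e-14, maxiter=200)

    l = l_free_of(p)
    pl = p * l / kd1
    p2l = pl * p / kd2 if math.isfinite(kd2) else 0.0
    return p, l, pl, p2l


def solve_species(comp: Composition, params: BindingParameters,
                  active_fraction: float = 1.0) -> SpeciesState:
    """Solve the coupled equilibria for one composition.

    Eliminates the free-ligand concentration through the ligand mass
    balance, leaving a single monotone scalar equation in the free
    receptor concentration on [0, p_total], which is solved by bracketed
    Brent root-finding.  The bracket is guaranteed for valid inputs, so
    the physical root is unique.

    Parameters
    ----------
    comp : Composition
        Total concentrations.
    params : BindingParameters
        kd1/kd2 are used; enthalpies are ignored here.
    active_fraction : float
        Multiplier on p_total for binding-incompetent receptor
        preparations; default 1.0 (all receptor competent).

    Returns
    -------
    SpeciesState
        Satisfies both mass balances and both mass-action laws to
        relative tolerance well below 1e-9.
    """
    _require(0 < active_fraction <= 1.0, f"active_fraction must be in (0, 1], got {active_fraction}")
    p, l, pl, p2l = _solve_raw(comp.p_total * active_fraction, comp.l_total,
                               params.kd1, params.kd2)
    return SpeciesState(p, l, pl, p2l)


def dimer_fraction(comp: Composition, params: BindingParameters,
                   active_fraction: float = 1.0) -> float:
    """Fraction of receptor chains resident in the 2:1 sandwich.

    Returns ``2*[P2L]/p_total`` in [0, 1].  Raises for ``p_total == 0``.
    """
    if comp.p_total == 0:
        raise ValueError("dimer_fraction undefined for p_total = 0")
    st = solve_species(comp, params, active_fraction=active_fraction)
    return 2.0 * st.p2l / (comp.p_total * active_fraction)


def speciation_profile(p_total: float, ratio_grid, params: BindingParameters,
                       active_fraction: float = 1.0) -> pd.DataFrame:
    """Speciation as a function of the ligand:receptor molar ratio.

    Row i is the equilibrium at ``l_total = ratio_grid[i] * p_total``.
    The dimer_fraction column is unimodal in the ratio whenever kd2 is
    finite: it rises while added ligand creates bridging PL complexes
    and falls once ligand excess saturates every chain as 1:1 complex.

    Returns a DataFrame with columns
    ``ratio, p_free, pl, p2l, dimer_fraction``.
    """
    ratios = np.asarray(ratio_grid, dtype=float)
    _require(ratios.size > 0, "ratio_grid must be nonempty")
    _require(np.all(ratios >= 0), "ratios must be nonnegative")
    _require(np.all(np.diff(ratios) > 0) if ratios.size > 1 else True,
             "ratio_grid must be strictly increasing")
    rows = []
    for r in ratios:
        comp = Composition(p_total, r * p_total)
        st = solve_species(comp, params, active_fraction=active_fraction)
        rows.append({
            "ratio": r,
            "p_free": st.p_free,
            "pl": st.pl,
            "p2l": st.p2l,
            "dimer_fraction": 2.0 * st.p2l / (p_total * active_fraction),
        })
    return pd.DataFrame(rows)
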