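"""Grand-canonical ensemble of chemoreceptor complexes.

The membrane is modelled as a collection of sites, each either empty or
occupied by one receptor complex.  A complex of size ``x`` contains
``3x`` receptor dimers (x trimers of dimers, TDs) connected by ``x - 1``
linkers, and is decorated by ``x + 2`` identical peripheral rest groups
(partially developed linkers: nothing, a CheW, or a CheW plus a CheA2
dimer).  All dimers in a complex share one conformational state (the
Monod-Wyman-Changeux assumption), so a complex is a two-state unit whose
active/inactive free energies follow from the single-dimer energies, the
linker incorporation energies and the coupling energy J awarded per
linker in the active state.

The observable activity is the expected number of CheA2 dimers residing
in active complexes, which is what a FRET kinase-activity measurement
reports up to an unknown multiplicative scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd
from scipy.special import expit

from .params import (
    EnsembleParameters,
    ExpressionCondition,
    LigandBinding,
    LinkerScheme,
    ModificationState,
)

__all__ = [
    "RestGroup",
    "ComplexSpecies",
    "EnsembleState",
    "EnsembleSystem",
    "dimer_free_energies",
    "linker_potentials",
    "enumerate_species",
    "ensemble_state",
    "species_table",
]


class RestGroup(str, Enum):
    """Decoration of the x + 2 peripheral sites of a complex.

    R1: bare site; R2: one CheW per site; R3: one CheW and one CheA2
    dimer per site.  All rest groups of a complex are identical.
    """

    R1 = "R1"
    R2 = "R2"
    R3 = "R3"


@dataclass(frozen=True)
class ComplexSpecies:
    """One enumerated complex type.

    ``n_linkers_a`` counts full -CheW-CheA2-CheW- linkers,
    ``n_linkers_w`` counts CheW-only linkers; together they fill the
    x - 1 linker slots, and ``multiplicity`` counts the distinct
    arrangements of the two types along those slots.
    """

    x: int
    rest: RestGroup
    n_linkers_a: int
    n_linkers_w: int

    def __post_init__(self) -> None:
        if self.n_linkers_a + self.n_linkers_w != self.x - 1:
            raise ValueError("linker counts must fill the x - 1 linker slots")

    @property
    def multiplicity(self) -> int:
        return math.comb(self.x - 1, self.n_linkers_a)

    @property
    def n_dimers(self) -> int:
        return 3 * self.x

    @property
    def n_a2(self) -> int:
        """CheA2 dimers in the complex (linkers plus rest groups)."""
        return self.n_linkers_a + ((self.x + 2) if self.rest is RestGroup.R3 else 0)

    @property
    def n_w(self) -> int:
        """CheW monomers: 2 per full linker, 4 per CheW-only linker,
        one per rest site for R2/R3."""
        rest_w = (self.x + 2) if self.rest is not RestGroup.R1 else 0
        return 2 * self.n_linkers_a + 4 * self.n_linkers_w + rest_w


@dataclass(frozen=True)
class EnsembleState:
    """The equilibrium ensemble at one ligand concentration.

    ``p_species[k]`` is the occupation probability of species
    ``species[k]`` (active and inactive summed), ``p_on[k]`` the
    conditional probability that it is active, ``p_empty`` the
    probability of an empty membrane site.  ``activity`` is the expected
    number of CheA2 dimers in active complexes per site; ``rho`` the mean
    number of receptor dimers per site.
    """

    c: float
    mu: float
    species: tuple[ComplexSpecies, ...]
    p_species: np.ndarray
    p_on: np.ndarray
    p_empty: float
    activity: float
    rho: float


def dimer_free_energies(
    c: float | np.ndarray,
    mod: ModificationState,
    binding: LigandBinding,
    mu: float,
) -> tuple[np.ndarray | float, np.ndarray | float]:
    """Free energies (kT) of a single receptor dimer in each conformation.

    ``f_on = delta_eps - ln(1 + c/kd_on) + mu`` and
    ``f_off = -ln(1 + c/kd_off) + mu``; the inactive state gains more
    from ligand binding because ``kd_off < kd_on``.
    """
    c = np.asarray(c, dtype=float) if np.ndim(c) else float(c)
    if np.any(np.asarray(c) < 0):
        raise ValueError("ligand concentration must be nonnegative")
    f_on = mod.delta_eps - np.log1p(c / binding.kd_on) + mu
    f_off = -np.log1p(c / binding.kd_off) + mu
    return f_on, f_off


def linker_potentials(
    cond: ExpressionCondition, params: EnsembleParameters
) -> tuple[float, float, float | None]:
    """Expression-scaled incorporation potentials (mu_w, mu_a2, mu_w2).

    Each potential derives from a dissociation equilibrium,
    ``mu = ln(K / concentration)``, so an n-fold expression change shifts
    it by ``-ln n`` per monomer contained in the unit.  ``a_mult = 0``
    returns ``mu_a2 = +inf`` (CheA-containing species get zero weight).
    Under symmetric schemes ``mu_a2`` is the CheA monomer potential.
    The CheW2 unit of a CheW-only linker holds two CheW monomers, hence
    the ``-2 ln i`` scaling of ``mu_w2``; for symmetric schemes a missing
    ``mu_w2_0`` defaults to ``2 * mu_w0``.
    """
    if not cond.w_mult > 0:
        raise ValueError("w_mult must be positive")
    mu_w = params.mu_w0 - math.log(cond.w_mult)
    if cond.a_mult == 0:
        mu_a2 = math.inf
    else:
        mu_a2 = params.mu_a2_0 - math.log(cond.a_mult)
    mu_w2_0 = params.mu_w2_0
    if mu_w2_0 is None and params.scheme.symmetric:
        mu_w2_0 = 2.0 * params.mu_w0
    mu_w2 = None if mu_w2_0 is None else mu_w2_0 - 2.0 * math.log(cond.w_mult)
    return mu_w, mu_a2, mu_w2


def enumerate_species(
    x_max: int, scheme: LinkerScheme = LinkerScheme.BRIDGED
) -> list[ComplexSpecies]:
    """Enumerate all complex types up to ``x_max`` trimers.

    The empty membrane site is not a species; it enters the partition
    function as the constant term 1.  Schemes without CheW-only linkers
    yield ``3 * x_max`` species; with them, each split of the x - 1
    linker slots between the two linker types is one species with
    binomial positional multiplicity.
    """
    if x_max < 1:
        raise ValueError("x_max must be at least 1")
    species: list[ComplexSpecies] = []
    for x in range(1, x_max + 1):
        if scheme.has_wonly:
            splits = [(k, x - 1 - k) for k in range(x)]
        else:
            splits = [(x - 1, 0)]
        for rest in RestGroup:
            for n_a, n_w in splits:
                species.append(
                    ComplexSpecies(x=x, rest=rest, n_linkers_a=n_a, n_linkers_w=n_w)
                )
    return species


def _rest_energy(sp: ComplexSpecies, mu_w: float, mu_a: float, symmetric: bool) -> float:
    """Rest-group energy: R1 = 0, R2 = (x+2) mu_w, R3 adds one CheA2 per
    site (2 mu_a per site under symmetric schemes)."""
    if sp.rest is RestGroup.R1:
        return 0.0
    n_sites = sp.x + 2
    if sp.rest is RestGroup.R2:
        return n_sites * mu_w
    a_term = 2.0 * mu_a if symmetric else mu_a
    return n_sites * (mu_w + a_term)


class EnsembleSystem:
    """Pre-compiled species table for fast repeated evaluation.

    Building the species list and the concentration-independent parts of
    the complex free energies once makes the inner loop of the
    chemical-potential root search a handful of vector operations.
    """

    def __init__(self, params: EnsembleParameters, cond: ExpressionCondition):
        self.params = params
        self.cond = cond
        self.species = tuple(enumerate_species(params.x_max, params.scheme))
        mu_w, mu_a, mu_w2 = linker_potentials(cond, params)

        sym = params.scheme.symmetric
        e_link_a = (2.0 * mu_a if sym else mu_a) + 2.0 * mu_w
        e_link_w = math.inf if mu_w2 is None else mu_w2 + 2.0 * mu_w

        off_const, n_link = [], []
        for sp in self.species:
            e = _rest_energy(sp, mu_w, mu_a, sym)
            # guard n * inf with n == 0 (0 * inf is nan)
            if sp.n_linkers_a:
                e += sp.n_linkers_a * e_link_a
            if sp.n_linkers_w:
                e += sp.n_linkers_w * e_link_w
            off_const.append(e)
            n_link.append(sp.x - 1)

        self.off_const = np.array(off_const)
        self.n_link = np.array(n_link, dtype=float)
        self.on_const = self.off_const + self.n_link * params.j_coupling
        self.x3 = np.array([3.0 * sp.x for sp in self.species])
        self.log_mult = np.log([sp.multiplicity for sp in self.species])
        self.n_a2 = np.array([float(sp.n_a2) for sp in self.species])
        self.n_linkers_a = np.array([float(sp.n_linkers_a) for sp in self.species])

    def free_energies(self, c: float, mu: float) -> tuple[np.ndarray, np.ndarray]:
        """Complex free energies F_on, F_off (kT) for every species."""
        f_on, f_off = dimer_free_energies(
            c, self.params.mod, self.params.binding, mu
        )
        return self.x3 * f_on + self.on_const, self.x3 * f_off + self.off_const

    def _weights(self, c: float, mu: float):
        """Species Boltzmann weights and partition function, evaluated in
        log space relative to the lowest free energy so that arbitrarily
        negative energies do not overflow."""
        F_on, F_off = self.free_energies(c, mu)
        log_w_on = self.log_mult - F_on
        log_w_off = self.log_mult - F_off
        ref = max(np.max(log_w_on), np.max(log_w_off), 0.0)
        w = np.exp(log_w_on - ref) + np.exp(log_w_off - ref)
        z = math.exp(-ref) + float(w.sum())  # exp(-ref) is the empty site
        return w, z, F_on, F_off

    def rho(self, c: float, mu: float) -> float:
        """Mean receptor dimers per site at fixed chemical potential."""
        w, z, _, _ = self._weights(c, mu)
        return float(np.dot(self.x3, w) / z)

    def state(self, c: float, mu: float) -> EnsembleState:
        w, z, F_on, F_off = self._weights(c, mu)
        p = w / z
        # F_on - F_off is finite even when both energies are +inf
        # (zero-weight CheA species at a_mult = 0): compute it directly.
        f_on, f_off = dimer_free_energies(c, self.params.mod, self.params.binding, 0.0)
        dF = self.x3 * (f_on - f_off) + self.n_link * self.params.j_coupling
        p_on = expit(-dF)
        activity = float(np.dot(p * p_on, self.n_a2))
        rho = float(np.dot(self.x3, p))
        return EnsembleState(
            c=float(c),
            mu=float(mu),
            species=self.species,
            p_species=p,
            p_on=p_on,
            p_empty=max(0.0, 1.0 - float(p.sum())),
            activity=activity,
            rho=rho,
        )


def ensemble_state(
    params: EnsembleParameters,
    cond: ExpressionCondition,
    c: float,
    mu: float,
) -> EnsembleState:
    """Evaluate the equilibrium ensemble at fixed chemical potential.

    Convenience wrapper constructing a fresh :class:`EnsembleSystem`;
    for sweeps build the system once and call :meth:`EnsembleSystem.state`.
    """
    return EnsembleSystem(params, cond).state(c, mu)


def species_table(species: list[ComplexSpecies] | tuple[ComplexSpecies, ...]) -> pd.DataFrame:
    """Species list as a data frame (the CSV export schema)."""
    return pd.DataFrame(
        {
            "x": [sp.x for sp in species],
            "rest": [sp.rest.value for sp in species],
            "n_linkers_a": [sp.n_linkers_a for sp in species],
            "n_linkers_w": [sp.n_linkers_w for sp in species],
            "multiplicity": [sp.multiplicity for sp in species],
            "n_w": [sp.n_w for sp in species],
            "n_a2": [sp.n_a2 for sp in species],
        }
    )
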