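"""Chemical-potential adjustment enforcing constant receptor density.

The mean dimer density rho(mu) is strictly decreasing in the chemical
potential mu (raising the per-dimer insertion cost depletes every
occupied-site weight by a factor exp(-3x mu) that falls fastest for the
largest complexes).  The density constraint rho(mu) = rho_target
therefore has a unique root, found with Brent's bracketing method.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import brentq

from .ensemble import EnsembleState, EnsembleSystem
from .params import EnsembleParameters, ExpressionCondition

__all__ = ["MuSolution", "solve_mu", "solve_mu_sweep", "constant_mu_state"]

#: absolute tolerance on the achieved density
RHO_TOL = 1e-10
#: initial bracket half-width (kT) and hard expansion limit
_MU_BRACKET = 50.0
_MU_LIMIT = 500.0


class DensityBracketError(RuntimeError):
    """Raised when no chemical potential within the search limits
    achieves the target density."""


@dataclass(frozen=True)
class MuSolution:
    """Outcome of one density-constrained chemical-potential solve."""

    mu: float
    rho_achieved: float
    iterations: int
    converged: bool


def _solve_on_system(
    system: EnsembleSystem,
    c: float,
    rho_target: float,
    mu_guess: float | None = None,
) -> MuSolution:
    x_max = system.params.x_max
    if not (0 < rho_target < 3 * x_max):
        raise ValueError(f"rho_target must lie in (0, {3 * x_max})")

    g = lambda mu: system.rho(c, mu) - rho_target

    if mu_guess is not None and math.isfinite(mu_guess):
        lo, hi = mu_guess - 1.0, mu_guess + 1.0
    else:
        lo, hi = -_MU_BRACKET, _MU_BRACKET
    # rho is decreasing: root bracketed once g(lo) > 0 > g(hi)
    g_lo, g_hi = g(lo), g(hi)
    while g_lo < 0 and lo > -_MU_LIMIT:
        hi, g_hi = lo, g_lo
        lo = max(2 * lo if lo < 0 else -_MU_BRACKET, -_MU_LIMIT)
        g_lo = g(lo)
    while g_hi > 0 and hi < _MU_LIMIT:
        lo, g_lo = hi, g_hi
        hi = min(2 * hi if hi > 0 else _MU_BRACKET, _MU_LIMIT)
        g_hi = g(hi)
    if g_lo < 0 or g_hi > 0:
        raise DensityBracketError(
            f"density {rho_target} not bracketable for c={c}: "
            f"rho({lo})={g_lo + rho_target:.3e}, rho({hi})={g_hi + rho_target:.3e}"
        )
    mu, res = brentq(g, lo, hi, xtol=1e-14, rtol=8.9e-16, full_output=True)
    rho_achieved = system.rho(c, mu)
    return MuSolution(
        mu=float(mu),
        rho_achieved=rho_achieved,
        iterations=res.iterations,
        converged=abs(rho_achieved - rho_target) <= RHO_TOL,
    )


def solve_mu(
    params: EnsembleParameters,
    cond: ExpressionCondition,
    c: float,
    rho_target: float | None = None,
    mu_guess: float | None = None,
) -> MuSolution:
    """Solve rho(mu) = rho_target at one ligand concentration.

    ``rho_target`` defaults to ``params.rho_target``.  ``mu_guess``
    (e.g. the solution at a neighbouring concentration) warm-starts the
    bracket.
    """
    if rho_target is None:
        rho_target = params.rho_target
    return _solve_on_system(EnsembleSystem(params, cond), c, rho_target, mu_guess)


def solve_mu_sweep(
    params: EnsembleParameters,
    cond: ExpressionCondition,
    concentrations: Sequence[float] | np.ndarray,
    rho_target: float | None = None,
) -> list[tuple[MuSolution, EnsembleState]]:
    """Density-constrained states along a concentration sweep.

    The system is compiled once and each solve warm-starts from the
    previous chemical potential (mu varies smoothly with c).
    """
    if rho_target is None:
        rho_target = params.rho_target
    system = EnsembleSystem(params, cond)
    out: list[tuple[MuSolution, EnsembleState]] = []
    guess: float | None = None
    for c in np.asarray(concentrations, dtype=float):
        sol = _solve_on_system(system, float(c), rho_target, guess)
        out.append((sol, system.state(float(c), sol.mu)))
        guess = sol.mu
    return out


def constant_mu_state(
    params: EnsembleParameters,
    cond: ExpressionCondition,
    c: float,
    mu: float,
) -> EnsembleState:
    """Ensemble at fixed chemical potential: the density is free and
    grows with ligand concentration (larger complexes gain the most
    binding energy), approaching 3 * x_max dimers per site."""
    if not math.isfinite(mu):
        raise ValueError("mu must be finite")
    return EnsembleSystem(params, cond).state(c, mu)
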