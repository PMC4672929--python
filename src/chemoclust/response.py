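"""Dose-response curves, Hill analysis, and expression-level scans.

Cooperativity is quantified by fitting the decreasing Hill function

    A(c) = A0 / (1 + (c / c_H)^n_H)

to model activities evaluated on a log-spaced concentration grid
(by default 50 points between 1e-3 and 1 mM, matching the grid used for
all caption-number reproductions).  The Hill coefficient n_H measures
the steepness of the response and is distinct from the complex size N:
the two agree for the classical single-complex MWC model only in the
regime c << K_on.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .density import solve_mu_sweep
from .ensemble import EnsembleState, EnsembleSystem
from .params import (
    EnsembleParameters,
    ExpressionCondition,
    LigandBinding,
    ModificationState,
)

__all__ = [
    "ResponseMode",
    "DoseResponse",
    "HillFit",
    "standard_grid",
    "dose_response",
    "hill_fit",
    "classical_mwc_activity",
    "scan_expression",
    "chea_per_linker",
]


class ResponseMode(str, Enum):
    CONSTANT_RHO = "CONSTANT_RHO"
    CONSTANT_MU = "CONSTANT_MU"


def standard_grid(
    n: int = 50, c_min: float = 1e-3, c_max: float = 1.0
) -> np.ndarray:
    """Log-spaced concentration grid (mM) used for Hill analysis."""
    return np.logspace(math.log10(c_min), math.log10(c_max), n)


@dataclass(frozen=True)
class DoseResponse:
    """Activity versus ligand concentration for one condition."""

    concentrations: np.ndarray
    activities: np.ndarray
    mode: ResponseMode
    condition: ExpressionCondition
    mus: np.ndarray | None = None
    rhos: np.ndarray | None = None

    def __post_init__(self) -> None:
        c = np.asarray(self.concentrations, dtype=float)
        a = np.asarray(self.activities, dtype=float)
        if c.shape != a.shape:
            raise ValueError("concentrations and activities must match in length")
        if len(c) > 1 and not np.all(np.diff(c) > 0):
            raise ValueError("concentrations must be strictly increasing")

    def scaled(self, s: float) -> "DoseResponse":
        """The same curve with activities multiplied by ``s`` (an overall
        signal scale, e.g. a FRET calibration factor)."""
        return DoseResponse(
            concentrations=self.concentrations,
            activities=s * np.asarray(self.activities),
            mode=self.mode,
            condition=self.condition,
            mus=self.mus,
            rhos=self.rhos,
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {"c_mM": self.concentrations, "activity": self.activities}
        )
        if self.mus is not None:
            df["mu"] = self.mus
        if self.rhos is not None:
            df["rho"] = self.rhos
        return df

    def plot(self, ax=None, normalize: bool = False, **kwargs):
        """Plot activity vs concentration on a log-x axis."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        a = np.asarray(self.activities, dtype=float)
        if normalize and a.max() > 0:
            a = a / a.max()
        ax.semilogx(self.concentrations, a, **kwargs)
        ax.set_xlabel("ligand concentration (mM)")
        ax.set_ylabel("kinase activity" + (" (normalized)" if normalize else ""))
        return ax


@dataclass(frozen=True)
class HillFit:
    """Fitted Hill parameters of a decreasing dose-response curve."""

    amplitude: float
    c_half: float
    n_hill: float
    rss: float
    converged: bool = True
    message: str = ""

    def predict(self, c: np.ndarray | float) -> np.ndarray | float:
        return self.amplitude / (1.0 + (np.asarray(c, dtype=float) / self.c_half) ** self.n_hill)


def dose_response(
    params: EnsembleParameters,
    cond: ExpressionCondition,
    grid: Sequence[float] | np.ndarray | None = None,
    mode: ResponseMode = ResponseMode.CONSTANT_RHO,
    mu: float | None = None,
) -> DoseResponse:
    """Model dose-response curve for one expression condition.

    In CONSTANT_RHO mode the chemical potential is re-solved at every
    concentration so the receptor density stays at
    ``params.rho_target``; in CONSTANT_MU mode the potential is held at
    ``mu`` and the density is free.
    """
    grid = standard_grid() if grid is None else np.asarray(grid, dtype=float)
    if grid.ndim != 1 or len(grid) == 0 or (len(grid) > 1 and not np.all(np.diff(grid) > 0)):
        raise ValueError("grid must be a strictly increasing 1-D array")
    if mode is ResponseMode.CONSTANT_RHO:
        states = [s for _, s in solve_mu_sweep(params, cond, grid)]
    else:
        if mu is None:
            raise ValueError("CONSTANT_MU mode requires mu")
        system = EnsembleSystem(params, cond)
        states = [system.state(float(c), mu) for c in grid]
    return DoseResponse(
        concentrations=grid,
        activities=np.array([s.activity for s in states]),
        mode=mode,
        condition=cond,
        mus=np.array([s.mu for s in states]),
        rhos=np.array([s.rho for s in states]),
    )


def _hill(c, a0, c_half, n):
    return a0 / (1.0 + (c / c_half) ** n)


def hill_fit(curve: DoseResponse | tuple[np.ndarray, np.ndarray]) -> HillFit:
    """Nonlinear least-squares fit of the decreasing Hill function.

    Initialization: amplitude at the maximal activity, c_half at the
    grid point nearest half-maximum, Hill coefficient 2.  All three
    parameters are constrained positive.
    """
    if isinstance(curve, DoseResponse):
        c = np.asarray(curve.concentrations, dtype=float)
        a = np.asarray(curve.activities, dtype=float)
    else:
        c, a = (np.asarray(v, dtype=float) for v in curve)
    if len(c) < 4:
        raise ValueError("need at least 4 points for a Hill fit")
    a_max = float(a.max())
    if a_max <= 0:
        raise ValueError("cannot fit a Hill function to an all-zero curve")
    c0 = float(c[np.argmin(np.abs(a - a_max / 2.0))])
    try:
        popt, _ = curve_fit(
            _hill,
            c,
            a,
            p0=[a_max, c0, 2.0],
            bounds=(0.0, np.inf),
            maxfev=20000,
        )
    except RuntimeError as err:  # pragma: no cover - hard to trigger on model curves
        return HillFit(
            amplitude=math.nan,
            c_half=math.nan,
            n_hill=math.nan,
            rss=math.nan,
            converged=False,
            message=str(err),
        )
    rss = float(np.sum((_hill(c, *popt) - a) ** 2))
    return HillFit(amplitude=float(popt[0]), c_half=float(popt[1]),
                   n_hill=float(popt[2]), rss=rss)


def classical_mwc_activity(
    n: int,
    mod: ModificationState,
    binding: LigandBinding,
    c: float | np.ndarray,
) -> float | np.ndarray:
    """Activity of a single all-or-none complex of N trimers of dimers.

    The comparator model without explicit protein connectivity:
    ``A = 1 / (1 + exp[N (delta_eps + ln((1 + c/kd_off)/(1 + c/kd_on)))])``.
    """
    if n < 1:
        raise ValueError("complex size n must be at least 1")
    c = np.asarray(c, dtype=float) if np.ndim(c) else float(c)
    f = mod.delta_eps + np.log1p(c / binding.kd_off) - np.log1p(c / binding.kd_on)
    return 1.0 / (1.0 + np.exp(n * f))


def scan_expression(
    params: EnsembleParameters,
    w_grid: Iterable[float],
    a_grid: Iterable[float],
    grid: Sequence[float] | np.ndarray | None = None,
) -> pd.DataFrame:
    """Hill amplitude/coefficient over a grid of expression levels.

    Returns one row per (w_mult, a_mult) with columns
    ``w_mult, a_mult, amplitude, c_half, n_hill``; conditions whose
    curve cannot be fitted (e.g. zero activity) get NaN entries.
    """
    rows = []
    for i in w_grid:
        for j in a_grid:
            cond = ExpressionCondition(w_mult=float(i), a_mult=float(j))
            try:
                fit = hill_fit(dose_response(params, cond, grid=grid))
                if not fit.converged:
                    raise ValueError(fit.message)
                rows.append((i, j, fit.amplitude, fit.c_half, fit.n_hill))
            except (ValueError, RuntimeError):
                rows.append((i, j, math.nan, math.nan, math.nan))
    return pd.DataFrame(
        rows, columns=["w_mult", "a_mult", "amplitude", "c_half", "n_hill"]
    )


def chea_per_linker(state: EnsembleState) -> float:
    """Expected CheA-containing linkers per linker of any type.

    Identically 1 for schemes without CheW-only linkers; below 1 when
    CheW-only linkers displace CheA2 bridges from the complexes.
    """
    n_all = np.array([float(sp.x - 1) for sp in state.species])
    n_a = np.array([float(sp.n_linkers_a) for sp in state.species])
    denom = float(np.dot(state.p_species, n_all))
    if denom <= 0:
        raise ValueError("no linkers in expectation: ratio undefined")
    return float(np.dot(state.p_species, n_a)) / denom
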