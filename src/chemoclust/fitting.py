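"""Parameter estimation from FRET-like dose-response data.

The estimation problem: given per-condition dose-response tables
(signal vs ligand concentration at known CheW/CheA expression multiples)
find the thermodynamic parameters minimising the squared deviation
between scaled model activities and the signals,

    chi2 = sum_records (s_family * A_model(c) - signal)^2 ,

where one unknown multiplicative signal scale s is shared by all
conditions of a family (FRET reports activity only up to calibration).
The scales enter the residuals linearly, so they are profiled out in
closed form at every objective evaluation.  The remaining nonconvex
problem is attacked by multi-start local minimisation: space-filling
(Latin hypercube) start points ranked by objective value, with bounded
local refinement of the best few.

The user-facing surface follows the model/results idiom:
``FretFitModel(dataset, template).fit()`` returns a
:class:`FretFitResults` carrying the estimates and a ``summary()``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.stats import qmc

from .density import solve_mu_sweep
from .params import EnsembleParameters, ExpressionCondition

__all__ = [
    "FretDataset",
    "FretFitModel",
    "FretFitResults",
    "chi_square",
    "profile_scales",
    "fit_global",
    "DEFAULT_BOUNDS",
]

_CSV_COLUMNS = ["condition", "w_mult", "a_mult", "mod", "c_mM", "signal"]

#: generous default box constraints per fittable parameter
DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "delta_eps": (-6.0, -0.1),
    "J": (-8.0, -0.1),
    "rho": (0.3, 11.0),
    "mu_w0": (-5.0, 3.0),
    "mu_a2_0": (-5.0, 3.0),
    "mu_w2_0": (-8.0, 3.0),
    "kd_on": (0.1, 50.0),
    "kd_off": (1e-4, 0.1),
}


@dataclass(frozen=True)
class FretDataset:
    """Table of (condition, concentration, signal) records.

    Required columns: ``condition`` (label), ``w_mult``, ``a_mult``,
    ``mod`` (modification label), ``c_mM``, ``signal``; optional
    ``family`` (scale-sharing group, defaults to a single family) and
    ``noise_sd``.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in _CSV_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError("dataset missing column(s): " + ", ".join(missing))
        if "family" not in self.df.columns:
            object.__setattr__(
                self, "df", self.df.assign(family="all")
            )
        if (self.df["c_mM"] <= 0).any():
            raise ValueError("all concentrations must be positive")
        counts = self.df.groupby("condition").size()
        if (counts < 4).any():
            bad = ", ".join(counts[counts < 4].index.astype(str))
            raise ValueError(f"conditions with fewer than 4 points: {bad}")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def families(self) -> list[str]:
        return sorted(self.df["family"].unique())

    def groups(self):
        """Yield (condition label, family, ExpressionCondition, sub-frame)."""
        for label, sub in self.df.groupby("condition", sort=True):
            cond = ExpressionCondition(
                w_mult=float(sub["w_mult"].iloc[0]),
                a_mult=float(sub["a_mult"].iloc[0]),
                label=str(label),
            )
            yield str(label), str(sub["family"].iloc[0]), cond, sub

    @classmethod
    def from_csv(cls, path: str | Path) -> "FretDataset":
        return cls(pd.read_csv(path))

    def to_csv(self, path: str | Path) -> None:
        cols = _CSV_COLUMNS + [
            c for c in ("family", "noise_sd") if c in self.df.columns
        ]
        self.df[cols].to_csv(path, index=False)


def model_activities(
    params: EnsembleParameters,
    data: FretDataset,
    rho_by_family: Mapping[str, float] | None = None,
) -> np.ndarray:
    """Constant-density model activity at every record, aligned with
    ``data.df`` rows."""
    out = np.empty(len(data.df))
    for _, family, cond, sub in data.groups():
        rho = None if rho_by_family is None else rho_by_family[family]
        cs = np.asarray(sub["c_mM"], dtype=float)
        order = np.argsort(cs)
        states = solve_mu_sweep(params, cond, cs[order], rho_target=rho)
        acts = np.empty(len(cs))
        acts[order] = [s.activity for _, s in states]
        out[sub.index.to_numpy()] = acts
    return out


def profile_scales(
    activities: np.ndarray, data: FretDataset
) -> dict[str, float]:
    """Closed-form least-squares signal scale per family:
    ``s = sum(A y) / sum(A^2)`` (clipped at zero; scales are physical)."""
    scales = {}
    fam = data.df["family"].to_numpy()
    y = data.df["signal"].to_numpy(dtype=float)
    for f in data.families:
        m = fam == f
        denom = float(np.dot(activities[m], activities[m]))
        scales[f] = max(0.0, float(np.dot(activities[m], y[m])) / denom) if denom > 0 else 0.0
    return scales


def chi_square(
    params: EnsembleParameters,
    scales: Mapping[str, float] | float,
    data: FretDataset,
    rho_by_family: Mapping[str, float] | None = None,
) -> float:
    """Sum of squared deviations of scaled model activities from signals."""
    acts = model_activities(params, data, rho_by_family)
    if not isinstance(scales, Mapping):
        scales = {f: float(scales) for f in data.families}
    s = data.df["family"].map(scales).to_numpy(dtype=float)
    resid = s * acts - data.df["signal"].to_numpy(dtype=float)
    return float(np.dot(resid, resid))


class FretFitModel:
    """Multi-start estimator of ensemble parameters from dose-response data.

    Parameters
    ----------
    data : FretDataset
        Observed signals.  All records must share one modification label
        (multi-state joint fits are handled by fitting states separately
        with shared starting values).
    template : EnsembleParameters
        Supplies the fixed parameters and the scheme/x_max; free
        parameters override its values during fitting.
    free : sequence of str
        Flat parameter keys to estimate (subset of
        ``delta_eps, kd_on, kd_off, J, mu_w0, mu_a2_0, mu_w2_0, rho``).
    bounds : mapping, optional
        Box constraints per free parameter; missing entries fall back to
        :data:`DEFAULT_BOUNDS`.
    per_family_rho : bool
        If true and ``rho`` is free, estimate one receptor density per
        scale family instead of a shared one.
    """

    def __init__(
        self,
        data: FretDataset,
        template: EnsembleParameters,
        free: Sequence[str] = ("delta_eps", "J", "rho"),
        bounds: Mapping[str, tuple[float, float]] | None = None,
        per_family_rho: bool = False,
    ):
        mods = data.df["mod"].unique()
        if len(mods) > 1:
            raise ValueError(
                "dataset mixes modification states; fit one state at a time"
            )
        self.data = data
        self.template = template
        self.per_family_rho = per_family_rho and "rho" in free
        names: list[str] = []
        for name in free:
            if name == "rho" and self.per_family_rho:
                names.extend(f"rho@{f}" for f in data.families)
            else:
                names.append(name)
        self.param_names = names
        bounds = dict(bounds or {})
        self.bounds = []
        for name in names:
            base = name.split("@")[0]
            if name in bounds:
                self.bounds.append(tuple(bounds[name]))
            elif base in bounds:
                self.bounds.append(tuple(bounds[base]))
            else:
                self.bounds.append(DEFAULT_BOUNDS[base])
        self.bounds = [tuple(map(float, b)) for b in self.bounds]
        if any(not (math.isfinite(lo) and math.isfinite(hi) and lo < hi)
               for lo, hi in self.bounds):
            raise ValueError("bounds must be finite with lo < hi")

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, template: EnsembleParameters, **kwargs
    ) -> "FretFitModel":
        return cls(FretDataset(df), template, **kwargs)

    # -- theta <-> parameters -------------------------------------------------

    def build_params(
        self, theta: np.ndarray
    ) -> tuple[EnsembleParameters, dict[str, float] | None]:
        """Translate a parameter vector into ensemble parameters plus the
        optional per-family densities."""
        changes: dict[str, float] = {}
        rho_by_family: dict[str, float] = {}
        for name, value in zip(self.param_names, theta):
            if name.startswith("rho@"):
                rho_by_family[name.split("@", 1)[1]] = float(value)
            else:
                changes[name] = float(value)
        if rho_by_family:
            # keep the shared rho_target valid; per-family values rule
            changes["rho"] = float(np.mean(list(rho_by_family.values())))
        params = self.template.replace(**changes)
        return params, (rho_by_family or None)

    def objective(self, theta: np.ndarray) -> float:
        """Profiled chi-square at one parameter vector (scales solved in
        closed form); infeasible vectors score +inf."""
        try:
            params, rho_fam = self.build_params(theta)
            acts = model_activities(params, self.data, rho_fam)
        except (ValueError, RuntimeError, ArithmeticError):
            return math.inf
        scales = profile_scales(acts, self.data)
        s = self.data.df["family"].map(scales).to_numpy(dtype=float)
        resid = s * acts - self.data.df["signal"].to_numpy(dtype=float)
        chi2 = float(np.dot(resid, resid))
        return chi2 if math.isfinite(chi2) else math.inf

    # -- fitting --------------------------------------------------------------

    def fit(
        self,
        n_starts: int = 50,
        seed: int = 0,
        n_refine: int | None = None,
        include: Sequence[np.ndarray] | None = None,
    ) -> "FretFitResults":
        """Multi-start bounded minimisation of the profiled chi-square.

        ``n_starts`` Latin-hypercube start points are ranked by objective
        value and the best ``n_refine`` (default: up to 6) are refined
        with L-BFGS-B.  Deterministic for a given seed.  ``include`` adds
        explicit start vectors (e.g. a warm start) to the pool.
        """
        if n_starts < 1:
            raise ValueError("n_starts must be at least 1")
        d = len(self.param_names)
        lo = np.array([b[0] for b in self.bounds])
        hi = np.array([b[1] for b in self.bounds])
        sampler = qmc.LatinHypercube(d=d, seed=seed)
        starts = qmc.scale(sampler.random(n_starts), lo, hi)
        if include is not None:
            extra = np.atleast_2d(np.asarray(include, dtype=float))
            starts = np.vstack([np.clip(extra, lo, hi), starts])

        start_vals = np.array([self.objective(t) for t in starts])
        order = np.argsort(start_vals)
        if n_refine is None:
            n_refine = min(6, len(starts))
        n_refine = max(1, min(n_refine, int(np.isfinite(start_vals).sum()) or 1))

        rows = []
        best_theta, best_val = starts[order[0]], start_vals[order[0]]
        for rank, idx in enumerate(order):
            refined = rank < n_refine and math.isfinite(start_vals[idx])
            theta_r, val_r = starts[idx], start_vals[idx]
            if refined:
                res = minimize(
                    self.objective,
                    starts[idx],
                    method="L-BFGS-B",
                    bounds=self.bounds,
                    options={"maxiter": 200, "ftol": 1e-14, "gtol": 1e-10},
                )
                if math.isfinite(res.fun) and res.fun < val_r:
                    theta_r, val_r = np.clip(res.x, lo, hi), float(res.fun)
            if val_r < best_val:
                best_theta, best_val = theta_r, val_r
            rows.append(
                {
                    "start_index": int(idx),
                    "chi2_start": float(start_vals[idx]),
                    "chi2_refined": float(val_r),
                    "refined": refined,
                    **{f"theta_{n}": v for n, v in zip(self.param_names, theta_r)},
                }
            )
        if not math.isfinite(best_val):
            raise RuntimeError(
                "all starts failed; inspect bounds and data "
                f"(first start objective: {start_vals[0]!r})"
            )

        params, rho_fam = self.build_params(best_theta)
        acts = model_activities(params, self.data, rho_fam)
        scales = profile_scales(acts, self.data)
        return FretFitResults(
            model=self,
            params=params,
            rho_by_family=rho_fam,
            theta=np.asarray(best_theta, dtype=float),
            scales=scales,
            chi2=float(best_val),
            n_starts=int(n_starts),
            seed=int(seed),
            starts=pd.DataFrame(rows),
        )


@dataclass(frozen=True)
class FretFitResults:
    """Outcome of a multi-start fit."""

    model: FretFitModel
    params: EnsembleParameters
    rho_by_family: dict[str, float] | None
    theta: np.ndarray
    scales: dict[str, float]
    chi2: float
    n_starts: int
    seed: int
    starts: pd.DataFrame

    def predict(self) -> np.ndarray:
        """Scaled model signals aligned with the dataset rows."""
        acts = model_activities(self.params, self.model.data, self.rho_by_family)
        s = self.model.data.df["family"].map(self.scales).to_numpy(dtype=float)
        return s * acts

    def params_dict(self) -> dict[str, float]:
        d = {n: float(v) for n, v in zip(self.model.param_names, self.theta)}
        return d

    def to_json_dict(self) -> dict:
        return {
            "parameters": self.params.to_dict(),
            "free": self.params_dict(),
            "rho_by_family": self.rho_by_family,
            "scales": self.scales,
            "chi2": self.chi2,
            "n_starts": self.n_starts,
            "seed": self.seed,
        }

    def summary(self) -> str:
        lines = [
            "Fit of receptor-ensemble model to dose-response data",
            "=" * 55,
            f"records: {len(self.model.data)}   families: {', '.join(self.model.data.families)}",
            f"scheme: {self.params.scheme.value}   x_max: {self.params.x_max}",
            f"chi2: {self.chi2:.6g}   starts: {self.n_starts}   seed: {self.seed}",
            "-" * 55,
            f"{'parameter':<12}{'estimate':>14}{'lower':>10}{'upper':>10}",
        ]
        for name, value, (lo, hi) in zip(
            self.model.param_names, self.theta, self.model.bounds
        ):
            lines.append(f"{name:<12}{value:>14.5g}{lo:>10.4g}{hi:>10.4g}")
        for f, s in sorted(self.scales.items()):
            lines.append(f"{'scale ' + f:<12}{s:>14.5g}{'':>10}{'(profiled)':>10}")
        lines.append("-" * 55)
        return "\n".join(lines)

    def plot_fit(self, ax=None):
        """Data points and scaled model curves per condition."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        pred = self.predict()
        df = self.model.data.df
        for label, sub in df.groupby("condition"):
            order = np.argsort(sub["c_mM"].to_numpy())
            idx = sub.index.to_numpy()[order]
            ax.semilogx(df.loc[idx, "c_mM"], df.loc[idx, "signal"], "o", label=f"{label} data")
            ax.semilogx(df.loc[idx, "c_mM"], pred[idx], "-", label=f"{label} fit")
        ax.set_xlabel("ligand concentration (mM)")
        ax.set_ylabel("signal")
        ax.legend(fontsize="small")
        return ax


def fit_global(
    data: FretDataset,
    template: EnsembleParameters,
    free: Sequence[str] = ("delta_eps", "J", "rho"),
    bounds: Mapping[str, tuple[float, float]] | None = None,
    n_starts: int = 50,
    seed: int = 0,
    **kwargs,
) -> FretFitResults:
    """Functional wrapper around :class:`FretFitModel` + :meth:`fit`."""
    return FretFitModel(data, template, free=free, bounds=bounds).fit(
        n_starts=n_starts, seed=seed, **kwargs
    )
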