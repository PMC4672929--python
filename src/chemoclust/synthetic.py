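"""FRET-like synthetic dose-response data.

Emulates what an in vivo FRET kinase-activity experiment yields per
expression condition: a sigmoidal activity curve sampled on a log-spaced
concentration grid, multiplied by an unknown signal scale and corrupted
by additive homoscedastic Gaussian noise.  Photophysics and the
CheY-P/CheZ readout kinetics are not simulated.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .fitting import FretDataset
from .params import EnsembleParameters, ExpressionCondition
from .response import ResponseMode, dose_response, standard_grid

__all__ = ["generate_dataset"]


def generate_dataset(
    params: EnsembleParameters,
    conditions: Sequence[ExpressionCondition],
    grid: Sequence[float] | np.ndarray | None = None,
    scale: float = 1.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    families: Sequence[str] | None = None,
) -> FretDataset:
    """Generate signals ``scale * A_model(c) + N(0, noise_sd)``.

    One record per (condition, grid point); reproducible for a given
    seed.  ``families`` optionally assigns each condition to a signal
    scale family (default: a single family, matching a single unknown
    calibration).
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be nonnegative")
    if scale <= 0:
        raise ValueError("scale must be positive")
    grid = standard_grid() if grid is None else np.asarray(grid, dtype=float)
    if grid.ndim != 1 or len(grid) == 0 or np.any(grid <= 0):
        raise ValueError("grid must be a 1-D array of positive concentrations")
    if families is not None and len(families) != len(conditions):
        raise ValueError("families must match conditions in length")

    rng = np.random.default_rng(seed)
    frames = []
    for k, cond in enumerate(conditions):
        curve = dose_response(params, cond, grid=grid, mode=ResponseMode.CONSTANT_RHO)
        signal = scale * curve.activities + rng.normal(0.0, noise_sd, size=len(grid))
        label = cond.label or f"i={cond.w_mult:g},j={cond.a_mult:g}"
        frames.append(
            pd.DataFrame(
                {
                    "condition": label,
                    "w_mult": cond.w_mult,
                    "a_mult": cond.a_mult,
                    "mod": params.mod.label,
                    "c_mM": grid,
                    "signal": signal,
                    "family": "all" if families is None else families[k],
                    "noise_sd": noise_sd,
                }
            )
        )
    return FretDataset(pd.concat(frames, ignore_index=True))
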