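"""Log2 transforms with optimized pseudocounts, and the rankit (normal-scores) transform.

Chromatin signal densities are heavy-tailed and contain exact zeros, so the
modeling pipeline works on ``log2(x + a)`` where the pseudocount ``a`` is chosen
per feature to maximize the Pearson correlation between the transformed signal
and log-scale expression.  The rankit transform is the distribution-free
alternative: values are mapped onto standard-normal quantiles at the plotting
positions ``(rank - 0.375) / (n + 0.25)``, which sidesteps pseudocounts
entirely.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "PseudocountSpec",
    "optimize_pseudocount",
    "log2_with_pseudocount",
    "rankit",
    "pearson_r",
]

#: relative floor used both for the smallest grid candidate and for the
#: provisional transform applied before a pseudocount has been optimized
GRID_FLOOR_FRACTION = 1e-6
#: the pseudocount search extends to this fraction of the maximal signal
GRID_MAX_FRACTION = 0.2


def pearson_r(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson correlation that returns 0.0 for zero-variance input.

    The bin-selection and pseudocount scans treat degenerate (constant)
    candidates as uninformative rather than erroring out.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.std() == 0.0 or y.std() == 0.0:
        return 0.0
    return float(np.corrcoef(x, y)[0, 1])


@dataclass
class PseudocountSpec:
    """Optimized pseudocount for one chromatin feature.

    Attributes
    ----------
    feature_name : name of the chromatin feature the spec belongs to.
    a : the selected pseudocount, in the signal units of the input track.
    grid : candidate values scanned (log-spaced between ``1e-6 * max(x)``
        and ``0.2 * max(x)``).
    achieved_r : Pearson r between ``log2(x + a)`` and log2 expression on the
        selection set at the optimum.
    """

    feature_name: str
    a: float
    grid: np.ndarray = field(repr=False)
    achieved_r: float = float("nan")


def optimize_pseudocount(
    x: np.ndarray,
    y_log: np.ndarray,
    grid_size: int = 50,
    feature_name: str = "",
) -> PseudocountSpec:
    """Pick the pseudocount maximizing ``r(log2(x + a), y_log)`` over a log grid.

    The grid spans ``[1e-6 * max(x), 0.2 * max(x)]`` with ``grid_size``
    log-spaced points; exact zero is excluded so the transform is always
    defined.  Ties are broken toward the smallest candidate.  If the feature is
    identically zero the pseudocount defaults to 1.0 with a warning.

    Parameters
    ----------
    x : nonnegative per-gene signal values on the selection set (D1).
    y_log : log2 expression of the same genes (positive expression only).
    """
    x = np.asarray(x, dtype=float)
    y_log = np.asarray(y_log, dtype=float)
    if x.shape != y_log.shape:
        raise ValueError("x and y_log must have the same length")
    if np.any(x < 0):
        raise ValueError("signal values must be nonnegative")
    if x.size < 3:
        raise ValueError("need at least 3 genes to optimize a pseudocount")

    xmax = float(x.max())
    if xmax == 0.0:
        warnings.warn(
            f"feature {feature_name or '<unnamed>'} has no signal anywhere; "
            "pseudocount defaults to 1.0",
            stacklevel=2,
        )
        grid = np.array([1.0])
        return PseudocountSpec(feature_name, 1.0, grid, 0.0)

    grid = np.geomspace(GRID_FLOOR_FRACTION * xmax, GRID_MAX_FRACTION * xmax, grid_size)
    best_a = grid[0]
    best_r = -np.inf
    for a in grid:  # ascending, so strict improvement keeps the smallest tie
        r = pearson_r(np.log2(x + a), y_log)
        if r > best_r:
            best_r = r
            best_a = float(a)
    return PseudocountSpec(feature_name, best_a, grid, best_r)


def log2_with_pseudocount(x: np.ndarray, a: float) -> np.ndarray:
    """Elementwise ``log2(x + a)``, guarding against non-positive arguments."""
    x = np.asarray(x, dtype=float)
    shifted = x + a
    if np.any(shifted <= 0):
        raise ValueError("log2(x + a) undefined: x + a <= 0 for some values")
    return np.log2(shifted)


def rankit(values: np.ndarray) -> np.ndarray:
    """Normal scores at plotting positions ``(rank - 0.375) / (n + 0.25)``.

    Ties receive average ranks; NaNs are preserved in place and excluded from
    ``n``.  Equivalent to the R expression
    ``qnorm((rank(x) - 0.375) / (sum(!is.na(x)) + 0.25))``.
    """
    values = np.asarray(values, dtype=float)
    out = np.full(values.shape, np.nan)
    mask = np.isfinite(values)
    n = int(mask.sum())
    if n == 0:
        raise ValueError("rankit requires at least one finite value")
    ranks = stats.rankdata(values[mask], method="average")
    out[mask] = stats.norm.ppf((ranks - 0.375) / (n + 0.25))
    return out
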