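"""Subject-level bootstrap machinery shared by the three tests.

Subjects are resampled with replacement (each subject carries its replicate
block), the regression of interest is refit on every resample, and the 95%
pointwise envelope of the refitted lines forms the graphical confidence band.
The cloud of bootstrap (slope, intercept) pairs additionally yields an
empirical 95% prediction ellipse for joint slope/intercept decisions.

Both geometric decisions are automated here: whether a line of given slope
(with its intercept restricted to an interval, e.g. a bias confidence
interval for "translated" decisions) fits inside a band, and whether a point
lies inside an ellipse.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import DegenerateDataError
from .model import MeasurementSet

logger = logging.getLogger(__name__)

__all__ = ["BootstrapConfig", "BootstrapBand", "PredictionEllipse",
           "bootstrap_lines", "build_ellipse", "band_admits_line",
           "point_in_ellipse"]


@dataclass(frozen=True)
class BootstrapConfig:
    """Resampling settings used across all tests of one analysis."""

    n_boot: int = 2000
    seed: int = 0
    grid_size: int = 100
    level: float = 0.95


@dataclass(frozen=True)
class BootstrapBand:
    """Pointwise envelope containing ``level`` of all resampled lines."""

    grid: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    n_boot: int
    level: float
    seed: int

    def __post_init__(self) -> None:
        grid = np.asarray(self.grid, dtype=float)
        lower = np.asarray(self.lower, dtype=float)
        upper = np.asarray(self.upper, dtype=float)
        if not (grid.shape == lower.shape == upper.shape):
            raise ValueError("grid/lower/upper shape mismatch")
        if grid.size >= 2 and not np.all(np.diff(grid) > 0):
            raise ValueError("grid must be strictly increasing")
        if np.any(lower > upper + 1e-12):
            raise ValueError("band lower envelope exceeds upper envelope")
        object.__setattr__(self, "grid", grid)
        object.__setattr__(self, "lower", lower)
        object.__setattr__(self, "upper", upper)


@dataclass(frozen=True)
class PredictionEllipse:
    """Empirical 95% region of bootstrap (slope, intercept) pairs.

    ``radius2`` is the squared Mahalanobis radius at the coverage level,
    taken from the empirical distribution of the generating pairs rather
    than a χ² quantile, keeping the region nonparametric.
    """

    center: np.ndarray          # (mean slope, mean intercept)
    shape: np.ndarray           # 2×2 scatter matrix of the pairs
    radius2: float
    level: float = 0.95

    def __post_init__(self) -> None:
        center = np.asarray(self.center, dtype=float)
        shape = np.asarray(self.shape, dtype=float)
        if center.shape != (2,) or shape.shape != (2, 2):
            raise ValueError("ellipse must live in (slope, intercept) space")
        if not np.allclose(shape, shape.T):
            raise ValueError("shape matrix must be symmetric")
        if not self.radius2 > 0:
            raise ValueError("radius2 must be positive")
        object.__setattr__(self, "center", center)
        object.__setattr__(self, "shape", shape)


def bootstrap_lines(ms: MeasurementSet, fitter, n_boot: int, seed: int,
                    grid_size: int = 100, abscissa=None,
                    level: float = 0.95):
    """Bootstrap a straight-line fit over subjects.

    Parameters
    ----------
    fitter : callable
        ``fitter(ms) -> (slope, intercept)``; must be deterministic.  A
        `DegenerateDataError` from the fitter triggers a redraw of that
        resample (counted; a warning is logged past 10% redraws).
    abscissa : callable, optional
        ``abscissa(ms) -> array`` giving the regression's x-axis values; the
        band grid spans its observed range.  Defaults to the collapsed
        reference measurements.

    Returns
    -------
    (BootstrapBand, ndarray of shape (n_boot, 2))
        The band and the (slope, intercept) pairs that generated it.
    """
    if n_boot < 200:
        raise ValueError("n_boot must be at least 200 for a stable envelope")
    if abscissa is None:
        abscissa = lambda m: m.x
    a = np.asarray(abscissa(ms), dtype=float)
    lo, hi = float(a.min()), float(a.max())
    if hi <= lo:
        raise DegenerateDataError("degenerate abscissa range for band grid")
    grid = np.linspace(lo, hi, grid_size)

    rng = np.random.default_rng(seed)
    n = ms.n
    pairs = np.empty((n_boot, 2))
    redraws = 0
    max_attempts = 50 * n_boot
    b = 0
    attempts = 0
    while b < n_boot:
        attempts += 1
        if attempts > max_attempts:
            raise DegenerateDataError(
                "bootstrap could not find enough non-degenerate resamples"
            )
        idx = rng.integers(0, n, size=n)
        try:
            slope, intercept = fitter(ms.subset(idx))
        except DegenerateDataError:
            redraws += 1
            continue
        pairs[b] = (slope, intercept)
        b += 1
    if redraws > 0.10 * n_boot:
        logger.warning("bootstrap redrew %d of %d resamples (degenerate fits)",
                       redraws, n_boot)

    lines = pairs[:, 1:2] + pairs[:, 0:1] * grid[None, :]
    alpha = (1.0 - level) / 2.0
    lower = np.quantile(lines, alpha, axis=0)
    upper = np.quantile(lines, 1.0 - alpha, axis=0)
    band = BootstrapBand(grid=grid, lower=lower, upper=upper,
                         n_boot=n_boot, level=level, seed=seed)
    return band, pairs


def build_ellipse(pairs: np.ndarray, level: float = 0.95) -> PredictionEllipse:
    """Fit the empirical prediction ellipse to bootstrap (slope, intercept) pairs."""
    pairs = np.asarray(pairs, dtype=float)
    center = pairs.mean(axis=0)
    shape = np.cov(pairs.T, ddof=1)
    det = np.linalg.det(shape)
    if not np.isfinite(det) or det <= 0:
        raise DegenerateDataError(
            "bootstrap (slope, intercept) scatter is singular; "
            "ellipse undefined"
        )
    inv = np.linalg.inv(shape)
    dev = pairs - center
    d2 = np.einsum("ij,jk,ik->i", dev, inv, dev)
    radius2 = float(np.quantile(d2, level))
    if not np.isfinite(radius2) or radius2 <= 0:
        raise DegenerateDataError(
            "bootstrap (slope, intercept) pairs are (numerically) identical; "
            "ellipse undefined"
        )
    return PredictionEllipse(center=center, shape=shape, radius2=radius2,
                             level=level)


def band_admits_line(band: BootstrapBand, slope: float,
                     intercept_range: tuple[float, float] = (-np.inf, np.inf)):
    """Can a line of the given slope fit inside the band at every grid point?

    The intercept may be restricted to an interval (the bias CI for
    translated decisions, the single point 0 for the strict identity line).

    Returns ``(feasible, witness)`` where the witness is the midpoint of the
    feasible intercept interval, or ``None`` when infeasible.
    """
    lo = float(np.max(band.lower - slope * band.grid))
    hi = float(np.min(band.upper - slope * band.grid))
    left = max(lo, float(intercept_range[0]))
    right = min(hi, float(intercept_range[1]))
    if left > right:
        return False, None
    return True, 0.5 * (left + right)


def point_in_ellipse(ellipse: PredictionEllipse,
                     point: tuple[float, float]) -> bool:
    """Closed-region membership test via the squared Mahalanobis distance."""
    p = np.asarray(point, dtype=float)
    dev = p - ellipse.center
    inv = np.linalg.inv(ellipse.shape)
    d2 = float(dev @ inv @ dev)
    return d2 <= ellipse.radius2
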