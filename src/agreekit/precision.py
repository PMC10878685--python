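"""Test 2 — precision (equality of error variances).

The differences y − x are regressed on the sums x + y.  Under the structural
model the slope is zero exactly when λ = V[δ]/V[ϵ] = 1, so the slope t-test
is a test of equal precisions; it is algebraically the Pitman–Morgan
correlation test of ρ(x − y, x + y) = 0.  These axes are the same as the
classic Bland–Altman difference plot, which is why that plot — at best —
speaks to precision, not to full equivalence.

The graphical decision asks whether any horizontal line fits inside the
bootstrap 95% band of the difference-on-sum regression; the translated
decision restricts that line's height to the accuracy test's bias confidence
interval, judging precision net of a mean offset.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm

from .errors import DegenerateDataError
from .model import MeasurementSet
from .resampling import (BootstrapBand, BootstrapConfig, band_admits_line,
                         bootstrap_lines)

__all__ = ["PrecisionResult", "precision_test"]


_DEFAULT_BOOT = BootstrapConfig()


@dataclass(frozen=True)
class PrecisionResult:
    slope_hat: float              # slope of (y − x) on (x + y)
    intercept_hat: float
    p_slope: float                # H0: slope = 0  (≡ Pitman–Morgan)
    corr_ds: float                # sample ρ(x − y, x + y)
    band: BootstrapBand | None
    analytic_reject: bool
    graphical_reject: bool | None
    graphical_reject_translated: bool | None
    level: float
    n: int


def _fit_diff_on_sum(ms: MeasurementSet) -> tuple[float, float]:
    x, y = ms.x, ms.y
    u = x + y
    uc = u - u.mean()
    suu = float(np.sum(uc * uc))
    if suu == 0.0:
        raise DegenerateDataError("x + y has zero variance; precision "
                                  "regression undefined")
    d = y - x
    slope = float(np.sum(uc * d) / suu)
    return slope, float(d.mean() - slope * u.mean())


def precision_test(ms: MeasurementSet, level: float = 0.05,
                   boot: BootstrapConfig | None = _DEFAULT_BOOT,
                   bias_ci: tuple[float, float] | None = None
                   ) -> PrecisionResult:
    """Run the precision test at the given significance level.

    ``bias_ci`` is the analytic confidence interval of the bias from the
    accuracy test; when given, the translated graphical decision restricts
    the candidate horizontal line to heights inside it.  ``boot=None`` skips
    the bootstrap band (graphical fields become None).
    """
    x, y = ms.x, ms.y
    u = x + y
    if np.var(u) == 0.0:
        raise DegenerateDataError("x + y has zero variance; precision test "
                                  "degenerate")
    d = y - x
    fit = sm.OLS(d, sm.add_constant(u)).fit()
    slope_hat = float(fit.params[1])
    p_slope = float(fit.pvalues[1])
    if np.var(d) == 0.0:
        # identical differences everywhere: no association, nothing to reject
        slope_hat, p_slope, corr_ds = 0.0, 1.0, 0.0
    else:
        corr_ds = float(np.corrcoef(x - y, u)[0, 1])
        if not np.isfinite(p_slope):
            p_slope = 1.0

    if boot is not None:
        band, _ = bootstrap_lines(
            ms, _fit_diff_on_sum, n_boot=boot.n_boot, seed=boot.seed,
            grid_size=boot.grid_size, abscissa=lambda m: m.x + m.y,
            level=boot.level,
        )
        feasible, _ = band_admits_line(band, 0.0)
        if bias_ci is not None:
            feasible_tr, _ = band_admits_line(band, 0.0,
                                              intercept_range=bias_ci)
        else:
            feasible_tr = feasible
        graphical_reject = not feasible
        graphical_reject_translated = not feasible_tr
    else:
        band = None
        graphical_reject = graphical_reject_translated = None

    return PrecisionResult(
        slope_hat=slope_hat,
        intercept_hat=float(fit.params[0]),
        p_slope=p_slope,
        corr_ds=corr_ds,
        band=band,
        analytic_reject=bool(p_slope < level),
        graphical_reject=graphical_reject,
        graphical_reject_translated=graphical_reject_translated,
        level=level,
        n=ms.n,
    )
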