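"""Test 1 — accuracy (equality of structural means).

The within-subject differences dᵢ = yᵢ − xᵢ are regressed on the mean-centered
reference measurement xᵢ − x̄ (the covariate-with-measurement-error trick for
repeated-measure designs).  Centering makes the intercept α equal the raw mean
difference — the structural bias — so H₀: α = 0 tests equal structural means.

The analytic decision uses the OLS t-based confidence interval of the
intercept; the graphical decision asks whether 0 lies in the bootstrap
percentile interval of the resampled intercepts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm

from .errors import DegenerateDataError
from .model import MeasurementSet
from .resampling import BootstrapConfig, bootstrap_lines

__all__ = ["AccuracyResult", "accuracy_test"]


_DEFAULT_BOOT = BootstrapConfig()


@dataclass(frozen=True)
class AccuracyResult:
    alpha_hat: float                  # intercept = mean difference = bias estimate
    beta_hat: float                   # slope on the centered covariate
    se_alpha: float
    ci_alpha: tuple[float, float]     # analytic two-sided CI for α
    p_alpha: float                    # H0: α = 0
    bias_ci_boot: tuple[float, float] | None  # bootstrap percentile CI of the bias
    analytic_reject: bool
    graphical_reject: bool | None
    level: float
    n: int


def _fit_centered(ms: MeasurementSet) -> tuple[float, float]:
    """OLS of y − x on x − x̄; returns (slope, intercept)."""
    x, y = ms.x, ms.y
    xc = x - x.mean()
    sxx = float(np.sum(xc * xc))
    if sxx == 0.0:
        raise DegenerateDataError(
            "reference measurements have zero variance; the centered-covariate "
            "regression is undefined"
        )
    d = y - x
    slope = float(np.sum(xc * d) / sxx)
    return slope, float(d.mean())


def accuracy_test(ms: MeasurementSet, level: float = 0.05,
                  boot: BootstrapConfig | None = _DEFAULT_BOOT
                  ) -> AccuracyResult:
    """Run the accuracy test at the given significance level.

    Replicates are collapsed to per-subject means.  Passing ``boot=None``
    skips the bootstrap (graphical fields become None) — useful in large
    simulation loops.  Raises `DegenerateDataError` when the reference
    measurements are constant (no silent fallback to a paired mean test).
    """
    x, y = ms.x, ms.y
    if np.var(x) == 0.0:
        raise DegenerateDataError(
            "reference measurements have zero variance; accuracy covariate "
            "degenerate"
        )
    d = y - x
    design = sm.add_constant(x - x.mean())
    fit = sm.OLS(d, design).fit()
    alpha_hat = float(fit.params[0])
    beta_hat = float(fit.params[1])
    ci = fit.conf_int(alpha=level)
    ci_alpha = (float(ci[0][0]), float(ci[0][1]))
    p_alpha = float(fit.pvalues[0])

    if boot is not None:
        _, pairs = bootstrap_lines(
            ms, _fit_centered, n_boot=boot.n_boot, seed=boot.seed,
            grid_size=boot.grid_size,
            abscissa=lambda m: m.x - m.x.mean(), level=boot.level,
        )
        half = (1.0 - boot.level) / 2.0
        bias_ci_boot = (float(np.quantile(pairs[:, 1], half)),
                        float(np.quantile(pairs[:, 1], 1.0 - half)))
        graphical_reject = not (bias_ci_boot[0] <= 0.0 <= bias_ci_boot[1])
    else:
        bias_ci_boot = None
        graphical_reject = None

    return AccuracyResult(
        alpha_hat=alpha_hat,
        beta_hat=beta_hat,
        se_alpha=float(fit.bse[0]),
        ci_alpha=ci_alpha,
        p_alpha=p_alpha,
        bias_ci_boot=bias_ci_boot,
        analytic_reject=bool(p_alpha < level),
        graphical_reject=graphical_reject,
        level=level,
        n=ms.n,
    )
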