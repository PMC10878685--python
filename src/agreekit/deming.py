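"""Test 3 — bisector agreement via Deming errors-in-variables regression.

Both techniques measure with error, so the line relating them is fit by
Deming regression, which weights departures in the two coordinates by the
error-variance ratio λ = V[δ]/V[ϵ].  The closed-form slope is

    β̂ = [ (s_yy − λ s_xx) + √((s_yy − λ s_xx)² + 4 λ s_xy²) ] / (2 s_xy),

the root whose sign matches s_xy; as λ → ∞ it tends to the OLS slope of y on
x, and as λ → 0 to the reciprocal of the OLS slope of x on y.  The line
always passes through (x̄, ȳ), giving α̂ = ȳ − β̂ x̄.

Agreement means the fitted line is the bisector y = x, a joint null
H₀: α = 0 and β = 1.  Analytically each parameter is tested with a
leave-one-subject-out jackknife standard error and a t reference with n − 2
degrees of freedom, at level/2 each (Bonferroni, so the family level is
preserved).  Graphically, the joint null is the point (β, α) = (1, 0) judged
against the bootstrap 95% prediction ellipse, and the identity line judged
against the bootstrap band of Deming lines (optionally translated through the
bias confidence interval).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import DegenerateDataError
from .model import LambdaEstimate, MeasurementSet, PairedSummary, summarize
from .resampling import (BootstrapBand, BootstrapConfig, PredictionEllipse,
                         band_admits_line, bootstrap_lines, build_ellipse,
                         point_in_ellipse)

__all__ = ["DemingFit", "BisectorResult", "fit_deming", "jackknife_se",
           "bisector_test"]


@dataclass(frozen=True)
class DemingFit:
    beta_hat: float
    alpha_hat: float
    lambda_used: LambdaEstimate
    se_beta: float | None = None
    se_alpha: float | None = None
    p_beta: float | None = None       # H0: β = 1
    p_alpha: float | None = None      # H0: α = 0


_DEFAULT_BOOT = BootstrapConfig()


@dataclass(frozen=True)
class BisectorResult:
    fit: DemingFit
    analytic_reject: bool
    ellipse: PredictionEllipse | None
    band: BootstrapBand | None
    ellipse_reject: bool | None
    band_reject: bool | None
    band_reject_translated: bool | None
    level: float
    n: int


def _deming_slope(s_xx: float, s_yy: float, s_xy: float, lam: float) -> float:
    if s_xy == 0.0:
        if np.isclose(s_yy, lam * s_xx):
            raise DegenerateDataError(
                "no association between techniques (s_xy = 0 and "
                "s_yy = λ·s_xx); Deming slope undefined"
            )
        raise DegenerateDataError(
            "zero covariance between techniques; Deming fit degenerate"
        )
    disc = (s_yy - lam * s_xx) ** 2 + 4.0 * lam * s_xy ** 2
    # '+' root: numerator keeps the sign of s_xy, the physically meaningful line
    return float(((s_yy - lam * s_xx) + np.sqrt(disc)) / (2.0 * s_xy))


def fit_deming(summary: PairedSummary, lam: LambdaEstimate) -> DemingFit:
    """Closed-form Deming point estimates (no standard errors)."""
    beta = _deming_slope(summary.s_xx, summary.s_yy, summary.s_xy, lam.value)
    alpha = summary.y_bar - beta * summary.x_bar
    return DemingFit(beta_hat=beta, alpha_hat=alpha, lambda_used=lam)


def jackknife_se(ms: MeasurementSet,
                 lam: LambdaEstimate) -> tuple[float, float]:
    """Leave-one-subject-out jackknife SEs of (α̂, β̂).

    Returns ``(se_alpha, se_beta)``.  Requires n ≥ 4 so that every
    leave-one-out fit keeps at least 3 subjects.  Implemented with vectorised
    moment downdates rather than n refits.
    """
    n = ms.n
    if n < 4:
        raise DegenerateDataError("jackknife needs at least 4 subjects")
    x, y = ms.x, ms.y
    xb, yb = x.mean(), y.mean()
    Sxx = np.sum((x - xb) ** 2)
    Syy = np.sum((y - yb) ** 2)
    Sxy = np.sum((x - xb) * (y - yb))
    f = n / (n - 1.0)
    # leave-one-out centered sums of squares/products
    Sxx_i = Sxx - f * (x - xb) ** 2
    Syy_i = Syy - f * (y - yb) ** 2
    Sxy_i = Sxy - f * (x - xb) * (y - yb)
    xb_i = (n * xb - x) / (n - 1.0)
    yb_i = (n * yb - y) / (n - 1.0)
    ddof = n - 2.0
    s_xx_i, s_yy_i, s_xy_i = Sxx_i / ddof, Syy_i / ddof, Sxy_i / ddof
    if np.any(s_xy_i == 0.0):
        raise DegenerateDataError(
            "a leave-one-out sample has zero covariance; jackknife SE "
            "unavailable"
        )
    lamv = lam.value
    diff = s_yy_i - lamv * s_xx_i
    disc = diff ** 2 + 4.0 * lamv * s_xy_i ** 2
    beta_i = (diff + np.sqrt(disc)) / (2.0 * s_xy_i)
    alpha_i = yb_i - beta_i * xb_i
    se_beta = float(np.sqrt((n - 1.0) / n * np.sum((beta_i - beta_i.mean()) ** 2)))
    se_alpha = float(np.sqrt((n - 1.0) / n * np.sum((alpha_i - alpha_i.mean()) ** 2)))
    return se_alpha, se_beta


def _deming_fitter(lam_value: float):
    def fitter(ms: MeasurementSet) -> tuple[float, float]:
        x, y = ms.x, ms.y
        cov = np.cov(x, y, ddof=1)
        beta = _deming_slope(cov[0, 0], cov[1, 1], cov[0, 1], lam_value)
        return beta, float(y.mean() - beta * x.mean())
    return fitter


def bisector_test(ms: MeasurementSet, lam: LambdaEstimate,
                  level: float = 0.05,
                  boot: BootstrapConfig | None = _DEFAULT_BOOT,
                  bias_ci: tuple[float, float] | None = None
                  ) -> BisectorResult:
    """Joint test of agreement with the identity line, three ways.

    Bonferroni analytic decision (each parameter at level/2), bootstrap
    prediction-ellipse decision on (β, α) against (1, 0), and bootstrap band
    decision on whether y = x (+ a bias translation when ``bias_ci`` is
    given) fits inside the envelope of resampled Deming lines.  ``boot=None``
    skips the bootstrap (graphical fields become None).
    """
    summary = summarize(ms)
    fit0 = fit_deming(summary, lam)

    se_alpha = se_beta = p_alpha = p_beta = None
    analytic_available = True
    try:
        se_alpha, se_beta = jackknife_se(ms, lam)
        df = ms.n - 2

        def _t_p(estimate: float, null: float, se: float) -> float:
            if se == 0.0:
                # exact-line data: the estimate is the population value
                return 1.0 if estimate == null else 0.0
            return float(2.0 * stats.t.sf(abs(estimate - null) / se, df))

        p_beta = _t_p(fit0.beta_hat, 1.0, se_beta)
        p_alpha = _t_p(fit0.alpha_hat, 0.0, se_alpha)
    except DegenerateDataError:
        analytic_available = False

    fit = DemingFit(beta_hat=fit0.beta_hat, alpha_hat=fit0.alpha_hat,
                    lambda_used=lam, se_beta=se_beta, se_alpha=se_alpha,
                    p_beta=p_beta, p_alpha=p_alpha)

    if boot is not None:
        band, pairs = bootstrap_lines(
            ms, _deming_fitter(lam.value), n_boot=boot.n_boot,
            seed=boot.seed, grid_size=boot.grid_size,
            abscissa=lambda m: m.x, level=boot.level,
        )
        try:
            ellipse = build_ellipse(pairs, level=boot.level)
            ellipse_reject = not point_in_ellipse(ellipse, (1.0, 0.0))
        except DegenerateDataError:
            ellipse = None
            ellipse_reject = None
        feasible, _ = band_admits_line(band, 1.0, intercept_range=(0.0, 0.0))
        if bias_ci is not None:
            feasible_tr, _ = band_admits_line(band, 1.0,
                                              intercept_range=bias_ci)
        else:
            feasible_tr = feasible
        band_reject = not feasible
        band_reject_translated = not feasible_tr
    else:
        band = ellipse = None
        ellipse_reject = band_reject = band_reject_translated = None

    if analytic_available:
        analytic_reject = bool(p_alpha < level / 2.0 or p_beta < level / 2.0)
    elif ellipse_reject is not None:
        # analytic path unavailable: defer to the graphical (ellipse) decision
        analytic_reject = bool(ellipse_reject)
    elif band_reject is not None:
        analytic_reject = bool(band_reject)
    else:
        raise DegenerateDataError(
            "neither analytic nor graphical bisector decision is available"
        )

    return BisectorResult(
        fit=fit,
        analytic_reject=analytic_reject,
        ellipse=ellipse,
        band=band,
        ellipse_reject=ellipse_reject,
        band_reject=band_reject,
        band_reject_translated=band_reject_translated,
        level=level,
        n=ms.n,
    )
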