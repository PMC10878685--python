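"""Figure panels accompanying the equivalence report.

Four panels, mirroring how the tests are usually communicated:

* accuracy — the bias estimate as a diamond with its 95% CI whisker, the
  centered-covariate regression line and a reference line at zero;
* precision — scatter of (x + y, y − x), the difference-on-sum fit with its
  bootstrap band, and the candidate horizontal line(s);
* classic difference plot — the same axes with the Bland–Altman limits of
  agreement, for comparison only;
* bisector — the (x, y) scatter with the Deming line, its bootstrap band,
  the dashed identity line, and an inset (slope, intercept) ellipse with the
  null point (1, 0).
"""

from __future__ import annotations

import numpy as np

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
from matplotlib.patches import Ellipse as MplEllipse


def _draw_band(ax, band, **kwargs):
    ax.fill_between(band.grid, band.lower, band.upper, alpha=0.25, **kwargs)


def panel_accuracy(ax, ms, acc):
    x = ms.x
    xc = x - x.mean()
    d = ms.y - x
    ax.scatter(xc, d, s=18, alpha=0.7, color="tab:blue")
    gx = np.linspace(xc.min(), xc.max(), 50)
    ax.plot(gx, acc.alpha_hat + acc.beta_hat * gx, color="tab:blue")
    ax.axhline(0.0, color="grey", lw=0.8)
    ax.errorbar([0.0], [acc.alpha_hat],
                yerr=[[acc.alpha_hat - acc.ci_alpha[0]],
                      [acc.ci_alpha[1] - acc.alpha_hat]],
                fmt="D", color="tab:red", capsize=4, ms=8)
    ax.set_xlabel("x − x̄ (centered reference)")
    ax.set_ylabel("y − x")
    ax.set_title("Test 1: accuracy (bias)")


def panel_precision(ax, ms, prec, bias_ci=None):
    u = ms.x + ms.y
    d = ms.y - ms.x
    ax.scatter(u, d, s=18, alpha=0.7, color="tab:blue")
    _draw_band(ax, prec.band, color="tab:blue")
    ax.plot(prec.band.grid,
            prec.intercept_hat + prec.slope_hat * prec.band.grid,
            color="tab:blue")
    ax.axhline(float(d.mean()), color="tab:green", ls="--", lw=1.0,
               label="mean difference")
    if bias_ci is not None:
        for c in bias_ci:
            ax.axhline(c, color="tab:green", ls=":", lw=0.8)
    ax.set_xlabel("x + y")
    ax.set_ylabel("y − x")
    ax.set_title("Test 2: precision")


def panel_classic_ba(ax, ms, loa):
    u = ms.x + ms.y
    d = ms.y - ms.x
    d_bar, lower, upper = loa
    ax.scatter(u, d, s=18, alpha=0.7, color="tab:blue")
    ax.axhline(d_bar, color="tab:red")
    ax.axhline(lower, color="tab:red", ls="--")
    ax.axhline(upper, color="tab:red", ls="--")
    ax.set_xlabel("x + y")
    ax.set_ylabel("y − x")
    ax.set_title("Classic limits of agreement (comparison only)")


def panel_bisector(ax, ms, bis):
    x, y = ms.x, ms.y
    ax.scatter(x, y, s=18, alpha=0.7, color="tab:blue")
    _draw_band(ax, bis.band, color="tab:blue")
    fit = bis.fit
    ax.plot(bis.band.grid, fit.alpha_hat + fit.beta_hat * bis.band.grid,
            color="tab:blue", label="Deming fit")
    lims = [min(x.min(), y.min()), max(x.max(), y.max())]
    ax.plot(lims, lims, color="grey", ls="--", lw=1.0, label="identity")
    ax.set_xlabel("reference technique (x)")
    ax.set_ylabel("candidate technique (y)")
    ax.set_title("Test 3: bisector agreement")
    ax.legend(loc="upper left", fontsize=8)
    if bis.ellipse is not None:
        inset = ax.inset_axes([0.62, 0.06, 0.36, 0.36])
        _draw_ellipse(inset, bis.ellipse, fit)


def _draw_ellipse(ax, ellipse, fit):
    vals, vecs = np.linalg.eigh(ellipse.shape)
    angle = float(np.degrees(np.arctan2(vecs[1, -1], vecs[0, -1])))
    width, height = 2.0 * np.sqrt(vals[-1] * ellipse.radius2), \
        2.0 * np.sqrt(vals[0] * ellipse.radius2)
    patch = MplEllipse(xy=ellipse.center, width=width, height=height,
                       angle=angle, alpha=0.25, color="tab:blue")
    ax.add_patch(patch)
    ax.plot(*ellipse.center, "b.", ms=4)
    ax.plot([1.0], [0.0], "r+", ms=8)
    ax.plot([fit.beta_hat], [fit.alpha_hat], "bx", ms=5)
    pad_w, pad_h = max(width, 0.01), max(height, 0.01)
    ax.set_xlim(min(ellipse.center[0] - pad_w, 0.95),
                max(ellipse.center[0] + pad_w, 1.05))
    ax.set_ylim(min(ellipse.center[1] - pad_h, -0.05),
                max(ellipse.center[1] + pad_h, 0.05))
    ax.set_xlabel("β", fontsize=7)
    ax.set_ylabel("α", fontsize=7)
    ax.tick_params(labelsize=6)


def make_figure(ms, report):
    """The 2×2 panel figure for one analysis; returns the matplotlib figure."""
    fig, axes = plt.subplots(2, 2, figsize=(11, 9))
    panel_accuracy(axes[0, 0], ms, report.accuracy)
    panel_precision(axes[0, 1], ms, report.precision,
                    bias_ci=report.accuracy.ci_alpha)
    panel_classic_ba(axes[1, 0], ms, report.loa)
    panel_bisector(axes[1, 1], ms, report.bisector)
    fig.tight_layout()
    return fig
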