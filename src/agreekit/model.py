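"""Structural measurement model and the error-variance ratio λ.

Two techniques measure the same subjects.  The reference technique A reports
``x = X + ϵ`` and the candidate technique B reports ``y = Y + δ``, where X and
Y are the unobservable true values and ϵ, δ are independent, zero-mean
measurement errors.  Because the errors average out, observed means estimate
structural means, and the observed mean difference ``ȳ − x̄`` estimates the
structural bias — the identity all three equivalence tests rest on.

λ = V[δ]/V[ϵ] is the candidate-over-reference error-variance ratio.  It is 1
under equal precision and is the shape parameter of the Deming regression.
With replicate measurements per technique it is estimated from pooled
within-subject variances; otherwise it defaults to 1 (with a warning) or is
supplied by the user.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateDataError, InsufficientDataError

logger = logging.getLogger(__name__)

__all__ = ["MeasurementSet", "PairedSummary", "LambdaEstimate", "summarize",
           "estimate_lambda"]


@dataclass(frozen=True)
class MeasurementSet:
    """Paired observed measurements, one row per subject.

    ``x_reps`` and ``y_reps`` are (n, r) arrays of replicate readings from the
    reference (A) and candidate (B) techniques, aligned by subject.  Replicate
    counts may differ between techniques but are constant within one.
    """

    x_reps: np.ndarray
    y_reps: np.ndarray
    subject_ids: np.ndarray | None = None
    x_names: tuple[str, ...] | None = None
    y_names: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        x = np.atleast_2d(np.asarray(self.x_reps, dtype=float))
        y = np.atleast_2d(np.asarray(self.y_reps, dtype=float))
        if x.shape[0] == 1 and x.shape[1] > 1 and y.shape[0] != 1:
            raise ValueError("x_reps must be (n, r_x) with one row per subject")
        object.__setattr__(self, "x_reps", x)
        object.__setattr__(self, "y_reps", y)
        if x.shape[0] != y.shape[0]:
            raise ValueError(
                f"subject misalignment: {x.shape[0]} x-rows vs {y.shape[0]} y-rows"
            )
        if x.shape[0] < 3:
            raise InsufficientDataError(
                f"need at least 3 subjects, got {x.shape[0]}"
            )
        if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
            raise ValueError("all measurements must be finite")
        ids = self.subject_ids
        if ids is None:
            ids = np.arange(x.shape[0])
        ids = np.asarray(ids)
        if ids.shape[0] != x.shape[0]:
            raise ValueError("subject_ids length mismatch")
        object.__setattr__(self, "subject_ids", ids)

    @property
    def n(self) -> int:
        return self.x_reps.shape[0]

    @property
    def r_x(self) -> int:
        return self.x_reps.shape[1]

    @property
    def r_y(self) -> int:
        return self.y_reps.shape[1]

    @property
    def x(self) -> np.ndarray:
        """Per-subject reference values (replicates collapsed by mean)."""
        return self.x_reps.mean(axis=1)

    @property
    def y(self) -> np.ndarray:
        """Per-subject candidate values (replicates collapsed by mean)."""
        return self.y_reps.mean(axis=1)

    def subset(self, indices) -> "MeasurementSet":
        """A new set keeping the given subject rows (replicate blocks intact).

        Used by the subject-level bootstrap and jackknife; indices may repeat.
        """
        idx = np.asarray(indices)
        return MeasurementSet(
            x_reps=self.x_reps[idx],
            y_reps=self.y_reps[idx],
            subject_ids=self.subject_ids[idx],
            x_names=self.x_names,
            y_names=self.y_names,
        )

    def swapped(self) -> "MeasurementSet":
        """Exchange the roles of the two techniques (x ↔ y)."""
        return MeasurementSet(
            x_reps=self.y_reps, y_reps=self.x_reps,
            subject_ids=self.subject_ids,
            x_names=self.y_names, y_names=self.x_names,
        )


@dataclass(frozen=True)
class PairedSummary:
    """First and second moments of the collapsed paired measurements."""

    x_bar: float
    y_bar: float
    d_bar: float          # ȳ − x̄, the structural bias estimate
    s_xx: float
    s_yy: float
    s_xy: float
    n: int


@dataclass(frozen=True)
class LambdaEstimate:
    """λ = V[δ]/V[ϵ] with its provenance.

    ``df_x`` / ``df_y`` are the degrees of freedom of the pooled
    within-subject variances (zero unless estimated from replicates).
    """

    value: float
    source: str = "assumed_default"   # assumed_default | user_supplied | replicate_estimated
    df_x: int = 0
    df_y: int = 0

    def __post_init__(self) -> None:
        if not self.value > 0:
            raise ValueError(f"lambda must be positive, got {self.value}")
        if self.source not in ("assumed_default", "user_supplied",
                               "replicate_estimated"):
            raise ValueError(f"unknown lambda source {self.source!r}")


def summarize(ms: MeasurementSet) -> PairedSummary:
    """Paired means, variances and covariance (denominator n − 1).

    Replicates are collapsed to per-subject means first, so the summary always
    refers to one value per subject per technique.
    """
    x, y = ms.x, ms.y
    cov = np.cov(x, y, ddof=1)
    return PairedSummary(
        x_bar=float(x.mean()),
        y_bar=float(y.mean()),
        d_bar=float(y.mean() - x.mean()),
        s_xx=float(cov[0, 0]),
        s_yy=float(cov[1, 1]),
        s_xy=float(cov[0, 1]),
        n=ms.n,
    )


def _pooled_within_variance(reps: np.ndarray) -> tuple[float, int]:
    """Pooled within-subject variance Σᵢⱼ(vᵢⱼ − v̄ᵢ)² / Σᵢ(rᵢ − 1)."""
    n, r = reps.shape
    df = n * (r - 1)
    if df == 0:
        return 0.0, 0
    dev = reps - reps.mean(axis=1, keepdims=True)
    return float(np.sum(dev * dev) / df), df


def estimate_lambda(ms: MeasurementSet,
                    user_lambda: float | None = None) -> LambdaEstimate:
    """Estimate λ from replicates, or fall back to a supplied/default value.

    With at least two replicates per technique, λ is the ratio of pooled
    within-subject variances (candidate over reference) — the repeated-measures
    correction.  Without replicates the equal-precision default λ = 1 is used
    and a warning is logged; a user-supplied value always wins.
    """
    if user_lambda is not None:
        if not user_lambda > 0:
            raise ValueError(f"user lambda must be positive, got {user_lambda}")
        return LambdaEstimate(value=float(user_lambda), source="user_supplied")

    if ms.r_x >= 2 and ms.r_y >= 2:
        wx, df_x = _pooled_within_variance(ms.x_reps)
        wy, df_y = _pooled_within_variance(ms.y_reps)
        if wx == 0.0 and wy == 0.0:
            logger.warning(
                "all replicates identical within subjects; lambda undefined, "
                "falling back to 1"
            )
            return LambdaEstimate(value=1.0, source="assumed_default",
                                  df_x=df_x, df_y=df_y)
        if wx == 0.0:
            raise DegenerateDataError(
                "reference replicates show zero within-subject variance while "
                "candidate variance is positive; lambda is undefined"
            )
        return LambdaEstimate(value=wy / wx, source="replicate_estimated",
                              df_x=df_x, df_y=df_y)

    logger.warning(
        "no replicates available to estimate lambda; assuming equal "
        "precision (lambda = 1)"
    )
    return LambdaEstimate(value=1.0, source="assumed_default")
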