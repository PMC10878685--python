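"""Synthetic paired-measurement generator with known structural truth.

Draws true values X, maps them through a linear calibration Y = a + b·X
(additive bias ``bias_a``, proportional bias ``prop_b``), and observes each
with independent zero-mean Gaussian errors: replicate readings
x = X + ϵ (SD ``sd_eps``) and y = Y + δ (SD ``sd_delta``).  The implied
error-variance ratio is λ = sd_delta²/sd_eps².

Besides the default normal distribution of true values, a uniform and a
symmetric two-point-mass option are provided; the latter is the adversarial
shape for Chebyshev-bound properties of limits-of-agreement plots.

The truth record travels separately from the MeasurementSet so production
code paths never see it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import MeasurementSet

__all__ = ["SimulationSpec", "TruthRecord", "generate"]


@dataclass(frozen=True)
class SimulationSpec:
    """Structural-model scenario; defaults give a null (equivalent) pair.

    The default true-value distribution, Normal(100, 15), with measurement
    error SDs of 5 on both techniques, mimics a physiological quantity
    measured with roughly 5% relative error.
    """

    n: int = 50
    true_mean: float = 100.0
    true_sd: float = 15.0
    bias_a: float = 0.0
    prop_b: float = 1.0
    sd_eps: float = 5.0
    sd_delta: float = 5.0
    r_x: int = 1
    r_y: int = 1
    seed: int = 0
    x_dist: str = "normal"       # normal | uniform | two_point

    def __post_init__(self) -> None:
        if self.n < 3:
            raise ValueError("need n >= 3 subjects")
        if self.sd_eps < 0 or self.sd_delta < 0:
            raise ValueError("error SDs must be non-negative")
        if self.r_x < 1 or self.r_y < 1:
            raise ValueError("replicate counts must be >= 1")
        if self.x_dist not in ("normal", "uniform", "two_point"):
            raise ValueError(f"unknown x_dist {self.x_dist!r}")

    @property
    def true_lambda(self) -> float | None:
        """λ = V[δ]/V[ϵ] implied by the error SDs (None when sd_eps = 0)."""
        if self.sd_eps == 0:
            return None
        return (self.sd_delta / self.sd_eps) ** 2


@dataclass(frozen=True)
class TruthRecord:
    """Latent quantities of one generated dataset."""

    X: np.ndarray
    Y: np.ndarray
    spec: SimulationSpec

    @property
    def true_lambda(self) -> float | None:
        return self.spec.true_lambda


def _draw_true(rng: np.random.Generator, spec: SimulationSpec) -> np.ndarray:
    if spec.x_dist == "normal":
        return rng.normal(spec.true_mean, spec.true_sd, size=spec.n)
    if spec.x_dist == "uniform":
        half = spec.true_sd * np.sqrt(3.0)   # matches the requested SD
        return rng.uniform(spec.true_mean - half, spec.true_mean + half,
                           size=spec.n)
    signs = rng.choice([-1.0, 1.0], size=spec.n)
    return spec.true_mean + signs * spec.true_sd


def generate(spec: SimulationSpec) -> tuple[MeasurementSet, TruthRecord]:
    """Generate one MeasurementSet plus its truth record, reproducibly."""
    rng = np.random.default_rng(spec.seed)
    X = _draw_true(rng, spec)
    Y = spec.bias_a + spec.prop_b * X
    x_reps = X[:, None] + rng.normal(0.0, spec.sd_eps, size=(spec.n, spec.r_x))
    y_reps = Y[:, None] + rng.normal(0.0, spec.sd_delta, size=(spec.n, spec.r_y))
    ms = MeasurementSet(
        x_reps=x_reps, y_reps=y_reps,
        subject_ids=np.arange(1, spec.n + 1),
        x_names=tuple(f"A{j + 1}" for j in range(spec.r_x)),
        y_names=tuple(f"B{j + 1}" for j in range(spec.r_y)),
    )
    return ms, TruthRecord(X=X, Y=Y, spec=spec)
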