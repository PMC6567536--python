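"""Synthetic population model for the non-response simulation study.

Two risk factors (``x1``, ``x2``) predict a continuous latent health
outcome ``y``; a third covariate ``x3`` predicts nothing in the outcome
model but is weakly correlated with ``x1`` and later serves as an
auxiliary variable for missing-data methods.  All study variables are
normal with mean 0 and a common variance of 1.15, chosen so that the
residual variance of the outcome is exactly 1:

    y = b1*x1 + b2*x2 + b3*x3 + e,   e ~ N(0, 1)

with defaults b1 = 0.20, b2 = 0.30, b3 = 0.00, giving
Var(y) = (b1^2 + b2^2) * 1.15 + 1 = 1.1495.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = ["PopulationParams", "CompleteSample", "generate_complete_sample"]


@dataclass(frozen=True)
class PopulationParams:
    """Parameters of the data-generating population.

    Parameters
    ----------
    b_pred1, b_pred2, b_pred3
        Regression coefficients of the continuous outcome on x1, x2, x3.
    var_x
        Common variance of the three predictors.
    resid_var_y
        Residual variance of the outcome.
    rho_x3
        Correlation between the auxiliary covariate x3 and the risk
        factor x1.  The study design only requires x3 to be "weakly"
        related to one risk factor, so this is exposed as a knob
        (default 0.10, set 0 for fully independent predictors).
    """

    b_pred1: float = 0.20
    b_pred2: float = 0.30
    b_pred3: float = 0.00
    var_x: float = 1.15
    resid_var_y: float = 1.0
    rho_x3: float = 0.10

    def __post_init__(self) -> None:
        if self.var_x <= 0:
            raise ValueError(f"var_x must be positive, got {self.var_x}")
        if self.resid_var_y <= 0:
            raise ValueError(
                f"resid_var_y must be positive, got {self.resid_var_y}"
            )
        if not -1.0 < self.rho_x3 < 1.0:
            raise ValueError(f"rho_x3 must lie in (-1, 1), got {self.rho_x3}")

    @property
    def b_pred(self) -> np.ndarray:
        """Outcome coefficients as a vector aligned with (x1, x2, x3)."""
        return np.array([self.b_pred1, self.b_pred2, self.b_pred3])

    def predictor_covariance(self) -> np.ndarray:
        """Theoretical 3x3 covariance matrix of (x1, x2, x3)."""
        cov = np.eye(3) * self.var_x
        cov[0, 2] = cov[2, 0] = self.rho_x3 * self.var_x
        return cov

    @property
    def var_y(self) -> float:
        """Theoretical variance of the continuous outcome."""
        b = self.b_pred
        return float(b @ self.predictor_covariance() @ b + self.resid_var_y)

    @property
    def sd_y(self) -> float:
        return float(np.sqrt(self.var_y))

    def cov_xy(self) -> np.ndarray:
        """Theoretical covariances Cov(x_j, y), j = 1..3."""
        return self.predictor_covariance() @ self.b_pred


@dataclass(frozen=True)
class CompleteSample:
    """One simulated sample before any missingness is imposed."""

    x1: np.ndarray
    x2: np.ndarray
    x3: np.ndarray
    y_cont: np.ndarray
    params: PopulationParams = field(default_factory=PopulationParams)

    def __post_init__(self) -> None:
        n = len(self.x1)
        for name in ("x2", "x3", "y_cont"):
            if len(getattr(self, name)) != n:
                raise ValueError("all sample columns must have equal length")
        if any(
            np.isnan(getattr(self, name)).any()
            for name in ("x1", "x2", "x3", "y_cont")
        ):
            raise ValueError("complete sample may not contain missing values")

    @property
    def n(self) -> int:
        return len(self.x1)

    def predictors(self) -> np.ndarray:
        """(n, 3) matrix of x1, x2, x3."""
        return np.column_stack([self.x1, self.x2, self.x3])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"x1": self.x1, "x2": self.x2, "x3": self.x3, "y_cont": self.y_cont}
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, params: PopulationParams | None = None) -> "CompleteSample":
        df = pd.read_csv(path)
        return cls(
            x1=df["x1"].to_numpy(),
            x2=df["x2"].to_numpy(),
            x3=df["x3"].to_numpy(),
            y_cont=df["y_cont"].to_numpy(),
            params=params or PopulationParams(),
        )

    def with_params(self, **kwargs) -> "CompleteSample":
        return replace(self, params=replace(self.params, **kwargs))


def generate_complete_sample(
    params: PopulationParams,
    n: int = 1000,
    seed: int | np.random.Generator | np.random.SeedSequence = 0,
) -> CompleteSample:
    """Draw one complete sample from the population model.

    Predictors are drawn jointly normal with the exact theoretical
    covariance (variances are population properties of the generator,
    not enforced per sample).  The outcome is built from the generating
    equation with an independent N(0, resid_var_y) residual.

    Parameters
    ----------
    params
        Population parameters.
    n
        Sample size (the study uses 1000 before non-response).
    seed
        Integer seed, SeedSequence or Generator; the same seed with the
        same parameters reproduces the sample bit for bit.
    """
    if n < 2:
        raise ValueError(f"sample size must be at least 2, got {n}")
    rng = np.random.default_rng(seed)
    x = rng.multivariate_normal(
        mean=np.zeros(3), cov=params.predictor_covariance(), size=n,
        method="cholesky",
    )
    e = rng.normal(0.0, np.sqrt(params.resid_var_y), size=n)
    y = x @ params.b_pred + e
    return CompleteSample(
        x1=x[:, 0], x2=x[:, 1], x3=x[:, 2], y_cont=y, params=params
    )
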