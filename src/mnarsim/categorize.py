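"""Ordinalization of the continuous outcome.

Survey instruments measure the latent continuous health trait on a
coarse ordered scale.  The simulated continuous outcome is cut at fixed
thresholds expressed in population-SD units of y (mean 0):

* 4 categories: cuts at -1, 0, +1 SD;
* 5 categories: cuts at -1, -0.5, +0.5, +1 SD;
* 2 categories: one cut at the mean.

A value exactly at a cut falls in the lower category ("one SD or more
below the mean" belongs to the bottom category), a measure-zero
convention fixed for determinism.  Thresholds are anchored to the
theoretical population moments, never to post-missingness sample
moments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["OrdinalSpec", "ordinalize", "DEFAULT_THRESHOLDS"]

DEFAULT_THRESHOLDS: dict[int, tuple[float, ...]] = {
    2: (0.0,),
    4: (-1.0, 0.0, 1.0),
    5: (-1.0, -0.5, 0.5, 1.0),
}


@dataclass(frozen=True)
class OrdinalSpec:
    """Observed-scale specification for the outcome.

    ``thresholds`` are in SD units of the continuous outcome.  With
    ``continuous_passthrough`` the outcome is analyzed untransformed
    (the linear-regression follow-up design).
    """

    n_categories: int = 4
    thresholds: tuple[float, ...] | None = None
    continuous_passthrough: bool = False

    def __post_init__(self) -> None:
        if self.continuous_passthrough:
            return
        if self.thresholds is None:
            if self.n_categories not in DEFAULT_THRESHOLDS:
                raise ValueError(
                    f"no default thresholds for {self.n_categories} categories; "
                    "pass thresholds explicitly"
                )
            object.__setattr__(
                self, "thresholds", DEFAULT_THRESHOLDS[self.n_categories]
            )
        t = np.asarray(self.thresholds, dtype=float)
        if len(t) != self.n_categories - 1:
            raise ValueError(
                f"{self.n_categories} categories require "
                f"{self.n_categories - 1} thresholds, got {len(t)}"
            )
        if not np.all(np.diff(t) > 0):
            raise ValueError(f"thresholds must be strictly increasing: {t}")

    @classmethod
    def continuous(cls) -> "OrdinalSpec":
        return cls(n_categories=0, thresholds=(), continuous_passthrough=True)

    def label(self) -> str:
        return "cont" if self.continuous_passthrough else f"{self.n_categories}cat"


def ordinalize(
    y: np.ndarray,
    spec: OrdinalSpec,
    sd: float = 1.0,
    mean: float = 0.0,
) -> np.ndarray:
    """Map a (possibly incomplete) continuous outcome to category codes.

    Category k (1..K) is assigned when theta_{k-1} < y <= theta_k with
    theta_0 = -inf and theta_K = +inf, after converting the SD-unit
    thresholds with the supplied population ``mean`` and ``sd``.  NaN
    entries (missing outcomes) pass through unchanged; the function
    never creates or destroys missingness.

    Returns a float array of codes (float so NaN can ride along).
    """
    y = np.asarray(y, dtype=float)
    if spec.continuous_passthrough:
        return y.copy()
    if sd <= 0:
        raise ValueError(f"sd must be positive, got {sd}")
    cuts = mean + sd * np.asarray(spec.thresholds, dtype=float)
    miss = np.isnan(y)
    # side='left': y equal to a cut maps to the lower category
    codes = np.searchsorted(cuts, y, side="left") + 1.0
    codes[miss] = np.nan
    return codes
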