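"""Shared result containers for simulator and coupon-collector routes."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["LibrarySizeEstimate", "CoverageCurve", "KnockoutCountDistribution"]


@dataclass(frozen=True)
class LibrarySizeEstimate:
    """Monte-Carlo estimate of the plant library size for full coverage.

    ``mean`` and ``std`` are the sample mean / sample standard deviation
    of the per-trial sizes ``trial_sizes`` (the number of plants at which
    every k-combination of gene knockouts had been observed at least
    once).
    """

    mean: float
    std: float
    n_trials: int
    trial_sizes: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"trial": np.arange(self.n_trials), "n_plants": self.trial_sizes}
        )


@dataclass(frozen=True)
class CoverageCurve:
    """Coverage statistics as a function of plant library size.

    ``gamma`` is the expected coverage E[gamma] at each size in
    ``n_grid``; ``p_full`` (optional) the probability of full coverage;
    ``gamma_sd`` (optional, simulated curves) the across-trial standard
    deviation of the coverage.
    """

    n_grid: np.ndarray
    gamma: np.ndarray
    p_full: np.ndarray | None = None
    gamma_sd: np.ndarray | None = None

    def to_frame(self) -> pd.DataFrame:
        data = {"n_plants": self.n_grid, "expected_coverage": self.gamma}
        if self.gamma_sd is not None:
            data["coverage_sd"] = self.gamma_sd
        if self.p_full is not None:
            data["success_probability"] = self.p_full
        return pd.DataFrame(data)


@dataclass(frozen=True)
class KnockoutCountDistribution:
    """Distribution of the number of gene knockouts per plant (0..r)."""

    probs: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "probs", np.asarray(self.probs, dtype=np.float64))
        if np.any(self.probs < 0) or abs(self.probs.sum() - 1.0) > 1e-9:
            raise ValueError("knockout-count probabilities must be >= 0 and sum to 1")

    @property
    def max_knockouts(self) -> int:
        return len(self.probs) - 1

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"n_knockouts": np.arange(len(self.probs)), "probability": self.probs}
        )
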