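"""Experiment configuration and reproducible random-stream derivation.

An :class:`ExperimentDesign` bundles every tunable of a multiplex
CRISPR/Cas knockout screen: the number of target genes ``x``, guides per
gene ``g``, the order of genetic interaction under study ``k`` (the size
of the gene-knockout combinations that must all be observed), the number
of gRNAs per construct ``r``, the skew ``rho`` of the guide abundance
distribution in the construct library, the bimodal editing-efficiency
parameters (``f_act``, ``eps_edit_act``, ``eps_edit_inact``) and the
global knockout efficiency ``eps_KO``.

All randomness flows through :func:`substream`: a named, indexed child
stream of a single master seed, so any part of a run (a particular
simulation trial, the frequency draw, ...) can be reproduced in
isolation and in any order.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

__all__ = ["ExperimentDesign", "InvalidDesignError", "substream"]


class InvalidDesignError(ValueError):
    """A design parameter violates its documented range."""


# Purpose tags for derived random streams. The stream for (seed, purpose,
# index) is numpy's Philox-seeded default generator initialised with
# SeedSequence((seed, purpose, index)); documented so runs can be
# reproduced piecewise.
STREAM_FREQUENCIES = 1
STREAM_EFFICIENCIES = 2
STREAM_TRIAL = 3
STREAM_SAMPLING = 4
STREAM_REPLICATE = 5


def substream(seed: int, purpose: int, index: int = 0) -> np.random.Generator:
    """Independent random stream derived from (master seed, purpose, index)."""
    return np.random.default_rng(np.random.SeedSequence((int(seed), int(purpose), int(index))))


@dataclass(frozen=True)
class ExperimentDesign:
    """Parameters of one multiplex CRISPR/Cas screen plus run controls.

    Defaults correspond to the reference design used throughout the
    package: 20 target genes, 6 guides per gene, abundance skew 2, 90 %
    active guides with editing efficiencies around 0.95 (inactive around
    0.1), and a global knockout efficiency of 0.8.
    """

    x: int = 20
    g: int = 6
    k: int = 1
    r: int | None = None  # defaults to k: one construct slot per interaction order
    rho: float = 2.0
    f_act: float = 0.9
    eps_edit_act: float = 0.95
    eps_edit_inact: float = 0.1
    eps_edit_sd: float = 0.01
    eps_KO: float = 0.8
    n_trials: int = 500
    seed: int = 0
    max_plants: int = 10_000_000

    def __post_init__(self) -> None:
        if self.r is None:
            object.__setattr__(self, "r", self.k)
        self.validate()

    def validate(self) -> None:
        if self.x < 1:
            raise InvalidDesignError(f"x must be >= 1, got {self.x}")
        if self.g < 1:
            raise InvalidDesignError(f"g must be >= 1, got {self.g}")
        if not 1 <= self.k <= self.x:
            raise InvalidDesignError(f"k must satisfy 1 <= k <= x, got k={self.k}, x={self.x}")
        if self.r < self.k:
            raise InvalidDesignError(f"r must be >= k, got r={self.r}, k={self.k}")
        if self.rho < 1:
            raise InvalidDesignError(f"rho must be >= 1, got {self.rho}")
        for name in ("f_act", "eps_edit_act", "eps_edit_inact", "eps_KO"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise InvalidDesignError(f"{name} must lie in [0, 1], got {value}")
        if self.eps_edit_sd < 0:
            raise InvalidDesignError(f"eps_edit_sd must be >= 0, got {self.eps_edit_sd}")
        if self.n_trials < 1:
            raise InvalidDesignError(f"n_trials must be >= 1, got {self.n_trials}")
        if self.max_plants < 1:
            raise InvalidDesignError(f"max_plants must be >= 1, got {self.max_plants}")

    def replace(self, **changes) -> "ExperimentDesign":
        """Return a copy with the given fields replaced (re-validated)."""
        if "k" in changes and "r" not in changes and self.r == self.k:
            changes.setdefault("r", changes["k"])
        return dataclasses.replace(self, **changes)

    @property
    def n_guides(self) -> int:
        return self.x * self.g
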