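"""Quantitative analysis of screen-design strategies and parameter sweeps.

Two strategies shrink the plant library required for full combinatorial
coverage:

* **Split–Select–Combine** — partition the x target genes into disjoint
  subsets and screen each subset's k-combinations in an independent
  experiment. The combination count C(x_subset, k) per screen collapses,
  and the total plant count (the sum over subsets) falls well below the
  single pooled screen.

* **Overshoot–Select–Purify** — put ``r > k`` guides on every construct
  so that a plant with j >= k knockouts covers C(j, k) combinations at
  once; full coverage is then reached with far fewer plants, at the cost
  of later purifying causative genotypes by segregation.

Parameter sweeps reproduce the sensitivity analyses over x, eps_KO, rho,
f_act and g, resampling guide libraries per replicate and averaging.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import ccp, simulator
from .design import STREAM_REPLICATE, STREAM_SAMPLING, ExperimentDesign, substream
from .guide_model import GuideLibrary, build_library
from .results import KnockoutCountDistribution

__all__ = [
    "SplitPlan",
    "SplitResult",
    "SweepResult",
    "split_total_size",
    "overshoot_sweep",
    "parameter_sweep",
    "knockout_distribution_panel",
]

_SWEEPABLE = ("x", "eps_KO", "rho", "f_act", "g")


@dataclass(frozen=True)
class SplitPlan:
    """Disjoint gene subsets covering all x genes of a design."""

    partition: tuple[tuple[str, ...], ...]

    @property
    def x_subset(self) -> tuple[int, ...]:
        return tuple(len(s) for s in self.partition)

    @property
    def f_subset(self) -> tuple[float, ...]:
        total = sum(self.x_subset)
        return tuple(size / total for size in self.x_subset)


@dataclass(frozen=True)
class SplitResult:
    """Total and per-subset library sizes for a Split screen."""

    plan: SplitPlan
    total_mean: float
    total_std: float
    subset_means: tuple[float, ...]
    subset_stds: tuple[float, ...]
    replicates: int
    method: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "subset": [f"subset_{i + 1}" for i in range(len(self.subset_means))],
                "x_subset": self.plan.x_subset,
                "mean_n": self.subset_means,
                "std_n": self.subset_stds,
            }
        )


@dataclass(frozen=True)
class SweepResult:
    """Mean/std of N_{x,k} along a parameter grid, averaged over replicates."""

    parameter: str
    grid: tuple
    mean: np.ndarray
    std: np.ndarray
    replicates: int
    method: str
    per_replicate: np.ndarray = field(repr=False, default=None)

    def to_frame(self) -> pd.DataFrame:
        """Tidy long-format table: (parameter, value, replicate, mean_n)."""
        rows = []
        for i, value in enumerate(self.grid):
            for rep in range(self.replicates):
                rows.append(
                    {
                        "parameter": self.parameter,
                        "value": value,
                        "replicate": rep,
                        "mean_n": self.per_replicate[i, rep],
                    }
                )
        return pd.DataFrame(rows)


def _estimate(
    design: ExperimentDesign, library: GuideLibrary, method: str
) -> tuple[float, float]:
    """(mean, std) of N for one concrete library, by either route."""
    if method == "ccp":
        mp = ccp.combination_probabilities(library, design.k, design.r, design.eps_KO)
        return ccp.expected_min_size(mp), ccp.std_min_size(mp)
    if method == "simulation":
        est = simulator.estimate_min_library_size(design, library=library)
        return est.mean, est.std
    raise ValueError(f"method must be 'simulation' or 'ccp', got {method!r}")


def split_total_size(
    design: ExperimentDesign,
    subset_sizes,
    method: str = "ccp",
    replicates: int = 5,
) -> SplitResult:
    """Total plant library size when genes are screened in disjoint subsets.

    Each subset of ``subset_sizes`` is an independent sub-experiment: its
    own pool of ``x_subset * g`` guides with freshly sampled frequencies
    and efficiencies, and the same k, r, rho and efficiency parameters.
    The total is the sum of per-subset expectations (subsets are separate
    transformations screened separately); per-subset variances add.
    """
    subset_sizes = tuple(int(s) for s in subset_sizes)
    if sum(subset_sizes) != design.x:
        raise ValueError(
            f"subset sizes {subset_sizes} must sum to x={design.x}"
        )
    if any(s < design.k for s in subset_sizes):
        raise ValueError(f"every subset must contain at least k={design.k} genes")

    genes = tuple(f"G{i + 1}" for i in range(design.x))
    bounds = np.cumsum((0,) + subset_sizes)
    plan = SplitPlan(
        partition=tuple(genes[bounds[i]: bounds[i + 1]] for i in range(len(subset_sizes)))
    )

    means = np.zeros((len(subset_sizes), replicates))
    variances = np.zeros_like(means)
    for rep in range(replicates):
        occurrences: dict[int, int] = {}
        for i, size in enumerate(subset_sizes):
            sub = design.replace(x=size)
            # stream index depends on (replicate, subset size, occurrence of
            # that size), not on list position: totals are permutation-invariant
            occ = occurrences.get(size, 0)
            occurrences[size] = occ + 1
            seed_stream = substream(
                design.seed, STREAM_REPLICATE, rep * 1_000_000 + size * 1_000 + occ
            )
            lib_seed = int(seed_stream.integers(0, 2**31))
            library = build_library(sub, seed=lib_seed)
            mean, std = _estimate(sub.replace(seed=lib_seed), library, method)
            means[i, rep] = mean
            variances[i, rep] = std**2

    subset_means = means.mean(axis=1)
    subset_stds = np.sqrt(variances.mean(axis=1))
    return SplitResult(
        plan=plan,
        total_mean=float(subset_means.sum()),
        total_std=float(np.sqrt((variances.mean(axis=1)).sum())),
        subset_means=tuple(subset_means),
        subset_stds=tuple(subset_stds),
        replicates=replicates,
        method=method,
    )


def overshoot_sweep(
    design: ExperimentDesign,
    r_values,
    method: str = "ccp",
    replicates: int = 5,
) -> SweepResult:
    """E[N_{x,k}] as a function of the number of guides per construct.

    Within a replicate the identical guide library is reused across all
    ``r`` values, so the sweep isolates the effect of r. Under the
    coupon-collector route the module probabilities are r-independent
    and only the modules-per-plant count m = C(r, k) changes.
    """
    r_values = tuple(int(r) for r in r_values)
    if any(r < design.k for r in r_values):
        raise ValueError(f"all r values must be >= k={design.k}")
    per_rep = np.zeros((len(r_values), replicates))
    for rep in range(replicates):
        lib_seed = int(substream(design.seed, STREAM_REPLICATE, rep).integers(0, 2**31))
        library = build_library(design, seed=lib_seed)
        for i, r in enumerate(r_values):
            d = design.replace(r=r, seed=lib_seed)
            per_rep[i, rep], _ = _estimate(d, library, method)
    return SweepResult(
        parameter="r",
        grid=r_values,
        mean=per_rep.mean(axis=1),
        std=per_rep.std(axis=1, ddof=1) if replicates > 1 else np.zeros(len(r_values)),
        replicates=replicates,
        method=method,
        per_replicate=per_rep,
    )


def parameter_sweep(
    design: ExperimentDesign,
    parameter: str,
    grid,
    replicates: int = 5,
    method: str = "ccp",
) -> SweepResult:
    """Sensitivity of E[N_{x,k}] to one design parameter.

    Guide libraries are resampled ``replicates`` times per grid value
    (the same replicate seeds across values, so only the swept parameter
    varies) and results are averaged. Two sweeps isolate a single noise
    source: for ``rho`` all editing efficiencies are forced to the ideal
    value of 1; for ``f_act`` the guide frequencies are forced uniform.
    """
    if parameter not in _SWEEPABLE:
        raise ValueError(f"unknown sweep parameter {parameter!r}; expected one of {_SWEEPABLE}")
    grid = tuple(grid)
    per_rep = np.zeros((len(grid), replicates))
    for i, value in enumerate(grid):
        d = design.replace(**{parameter: int(value) if parameter in ("x", "g") else float(value)})
        for rep in range(replicates):
            lib_seed = int(substream(design.seed, STREAM_REPLICATE, rep).integers(0, 2**31))
            library = build_library(d, seed=lib_seed)
            if parameter == "rho":
                library = GuideLibrary(
                    genes=library.genes,
                    guides=library.guides,
                    gene_of=library.gene_of,
                    freq=library.freq,
                    eps_edit=np.ones_like(library.eps_edit),
                )
            elif parameter == "f_act":
                library = GuideLibrary(
                    genes=library.genes,
                    guides=library.guides,
                    gene_of=library.gene_of,
                    freq=np.full(library.n_guides, 1.0 / library.n_guides),
                    eps_edit=library.eps_edit,
                )
            per_rep[i, rep], _ = _estimate(d.replace(seed=lib_seed), library, method)
    return SweepResult(
        parameter=parameter,
        grid=grid,
        mean=per_rep.mean(axis=1),
        std=per_rep.std(axis=1, ddof=1) if replicates > 1 else np.zeros(len(grid)),
        replicates=replicates,
        method=method,
        per_replicate=per_rep,
    )


def knockout_distribution_panel(
    design: ExperimentDesign,
    eps_KO_values,
    r_values,
    n_samples: int = 20_000,
) -> dict:
    """Knockout-count distributions over an (eps_KO, r) grid.

    One guide library is sampled from the design seed and shared across
    all cells, so only the varied parameters differ between cells.
    Returns a dict mapping (eps_KO, r) to a
    :class:`~crispr_coverage.results.KnockoutCountDistribution`.
    """
    library = build_library(design)
    panel: dict[tuple[float, int], KnockoutCountDistribution] = {}
    for i, eps_KO in enumerate(eps_KO_values):
        for j, r in enumerate(r_values):
            rng = substream(design.seed, STREAM_SAMPLING, i * len(tuple(r_values)) + j)
            panel[(float(eps_KO), int(r))] = simulator.knockout_count_distribution(
                library, int(r), float(eps_KO), n_samples, rng
            )
    return panel
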