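"""Monte-Carlo simulation of a multiplex CRISPR/Cas screen.

Each in-silico plant is produced by the pipeline the wet-lab experiment
follows: ``r`` guides are drawn with replacement into a construct
(multinomially, weighted by library frequency), each guide edits its
target with probability ``eps_edit``, each edit disrupts gene function
with probability ``eps_KO``, and the plant's genotype is the resulting
*set* of knocked-out genes. Plants are collected until every one of the
C(x, k) k-combinations of gene knockouts has been observed; the number
of plants at that point, N_{x,k}, is the quantity of interest,
summarised over repeated trials by its mean and standard deviation.

The public per-plant operations (:func:`assemble_construct`,
:func:`edit_plant`, :func:`covered_combinations`) are the readable,
scalar statement of the model; :func:`run_trial` and the estimators use
an equivalent vectorised engine that generates plants in chunks and
tracks, per combination, the first plant in which it appeared.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from math import comb

import numpy as np

from ._combinatorics import binom_table, colex_rank, colex_unrank
from .design import STREAM_TRIAL, ExperimentDesign, substream
from .guide_model import GuideLibrary, build_library
from .results import CoverageCurve, KnockoutCountDistribution, LibrarySizeEstimate

__all__ = [
    "PlantGenotype",
    "CoverageUnreachableError",
    "assemble_construct",
    "edit_plant",
    "covered_combinations",
    "compute_coverage",
    "run_trial",
    "estimate_min_library_size",
    "simulated_coverage_curve",
    "knockout_count_distribution",
]

_UNSEEN = np.iinfo(np.int64).max
_CHUNK_START = 2048
_CHUNK_MAX = 1 << 16


class CoverageUnreachableError(RuntimeError):
    """Full coverage was not reached within the plant cap."""

    def __init__(self, message: str, uncovered: list[tuple[str, ...]]):
        super().__init__(message)
        self.uncovered = uncovered


@dataclass(frozen=True)
class PlantGenotype:
    """The set of genes knocked out in one regenerated plant."""

    knocked_out: frozenset

    def __len__(self) -> int:
        return len(self.knocked_out)


def assemble_construct(library: GuideLibrary, r: int, rng: np.random.Generator) -> np.ndarray:
    """Draw the ``r`` guide indices of one construct (with replacement)."""
    if r < 1:
        raise ValueError(f"r must be >= 1, got {r}")
    cum = np.cumsum(library.freq)
    cum[-1] = 1.0
    return np.searchsorted(cum, rng.random(r), side="right")


def edit_plant(
    library: GuideLibrary,
    construct: np.ndarray,
    eps_KO: float,
    rng: np.random.Generator,
) -> PlantGenotype:
    """Simulate editing and knockout for one construct.

    Each guide slot independently induces a mutation with probability
    ``eps_edit`` of that guide and, given a mutation, a loss-of-function
    knockout with probability ``eps_KO``. Guides of the same gene
    collapse: the genotype is the set of genes with at least one
    successful knockout.
    """
    construct = np.asarray(construct)
    if construct.size == 0:
        raise ValueError("construct must contain at least one gRNA")
    knocked = set()
    for guide in construct:
        if rng.random() < library.eps_edit[guide] and rng.random() < eps_KO:
            knocked.add(library.genes[library.gene_of[guide]])
    return PlantGenotype(knocked_out=frozenset(knocked))


def covered_combinations(genotype: PlantGenotype, k: int) -> set:
    """All k-subsets of the genotype's knocked-out genes.

    A plant with fewer than ``k`` knockouts covers nothing; a plant with
    ``j > k`` knockouts covers all C(j, k) subsets — background
    knockouts beyond each subset are ignored.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    return {frozenset(c) for c in itertools.combinations(sorted(genotype.knocked_out), k)}


def compute_coverage(genotypes, x: int, k: int) -> float:
    """Fraction of the C(x, k) combinations present in a plant collection."""
    seen = set()
    for genotype in genotypes:
        seen |= covered_combinations(genotype, k)
    return len(seen) / comb(x, k)


def _plant_chunk(
    library: GuideLibrary,
    r: int,
    eps_KO: float,
    size: int,
    rng: np.random.Generator,
    cum: np.ndarray,
    p_hit: np.ndarray,
):
    """Vectorised generation of ``size`` plants.

    Returns (genes, mask, counts): ``genes`` is the row-sorted gene code
    matrix with failed slots set to the sentinel ``x``; ``mask`` selects
    the first occurrence of each knocked-out gene per row; ``counts`` is
    the number of distinct knockouts per plant.
    """
    x = library.n_genes
    idx = np.searchsorted(cum, rng.random((size, r)), side="right")
    hit = rng.random((size, r)) < p_hit[idx]
    genes = np.where(hit, library.gene_of[idx], x)
    genes.sort(axis=1)
    mask = np.empty((size, r), dtype=bool)
    mask[:, 0] = genes[:, 0] < x
    if r > 1:
        mask[:, 1:] = (genes[:, 1:] < x) & (genes[:, 1:] != genes[:, :-1])
    return genes, mask, mask.sum(axis=1)


def _trial_first_seen(
    library: GuideLibrary,
    design: ExperimentDesign,
    rng: np.random.Generator,
    n_max: int,
    stop_when_complete: bool = True,
):
    """Generate plants, recording per combination the first plant index.

    Returns ``(first_seen, n_generated)`` where ``first_seen[j]`` is the
    0-based index of the first plant covering combination *j* (colex
    order), or a sentinel if never covered within ``n_max`` plants.
    """
    x, k, r = library.n_genes, design.k, design.r
    table = binom_table(x, k)
    patterns = {j: list(itertools.combinations(range(j), k)) for j in range(k, r + 1)}
    first = np.full(comb(x, k), _UNSEEN, dtype=np.int64)
    cum = np.cumsum(library.freq)
    cum[-1] = 1.0
    p_hit = library.eps_edit * design.eps_KO

    produced = 0
    chunk = _CHUNK_START
    while produced < n_max:
        size = min(chunk, n_max - produced)
        genes, mask, counts = _plant_chunk(library, r, design.eps_KO, size, rng, cum, p_hit)
        for j, pats in patterns.items():
            rows = np.nonzero(counts == j)[0]
            if rows.size == 0:
                continue
            uniq = genes[rows][mask[rows]].reshape(rows.size, j)
            plant_idx = produced + rows
            for pattern in pats:
                ranks = colex_rank(uniq[:, pattern], table)
                np.minimum.at(first, ranks, plant_idx)
        produced += size
        if stop_when_complete and first.max() < _UNSEEN:
            break
        chunk = min(chunk * 2, _CHUNK_MAX)
    return first, produced


def run_trial(
    library: GuideLibrary,
    design: ExperimentDesign,
    rng: np.random.Generator,
) -> int:
    """Plants generated until every k-combination is covered once.

    Counts *all* plants, including wildtypes and plants contributing no
    new combination. Raises :class:`CoverageUnreachableError` if the cap
    ``design.max_plants`` is reached first.
    """
    first, _ = _trial_first_seen(library, design, rng, design.max_plants)
    if first.max() == _UNSEEN:
        uncovered = [
            tuple(library.genes[i] for i in colex_unrank(int(rank), library.n_genes, design.k))
            for rank in np.nonzero(first == _UNSEEN)[0][:20]
        ]
        raise CoverageUnreachableError(
            f"coverage not reached within max_plants={design.max_plants}; "
            f"{int((first == _UNSEEN).sum())} combination(s) uncovered, e.g. {uncovered[:5]}",
            uncovered,
        )
    # first_seen holds 0-based plant indices; the library size is 1-based
    return int(first.max()) + 1


def estimate_min_library_size(
    design: ExperimentDesign,
    library: GuideLibrary | None = None,
) -> LibrarySizeEstimate:
    """Mean and standard deviation of N_{x,k} over ``design.n_trials`` trials.

    One guide library (frequencies and efficiencies) is sampled from the
    design's seed and shared across all trials; each trial uses its own
    derived random stream, so trials are reproducible in isolation.
    """
    if library is None:
        library = build_library(design)
    sizes = np.empty(design.n_trials, dtype=np.int64)
    for t in range(design.n_trials):
        sizes[t] = run_trial(library, design, substream(design.seed, STREAM_TRIAL, t))
    std = float(sizes.std(ddof=1)) if design.n_trials > 1 else 0.0
    return LibrarySizeEstimate(
        mean=float(sizes.mean()), std=std, n_trials=design.n_trials, trial_sizes=sizes
    )


def simulated_coverage_curve(
    design: ExperimentDesign,
    n_grid,
    library: GuideLibrary | None = None,
) -> CoverageCurve:
    """Mean (over trials) coverage of the first N plants, per N in ``n_grid``."""
    n_grid = np.asarray(n_grid, dtype=np.int64)
    if np.any(np.diff(n_grid) < 0):
        raise ValueError("n_grid must be sorted ascending")
    if library is None:
        library = build_library(design)
    n_max = int(n_grid.max()) if n_grid.size else 0
    M = comb(library.n_genes, design.k)
    gammas = np.empty((design.n_trials, n_grid.size))
    for t in range(design.n_trials):
        rng = substream(design.seed, STREAM_TRIAL, t)
        first, _ = _trial_first_seen(library, design, rng, n_max, stop_when_complete=False)
        order = np.sort(first[first < _UNSEEN])
        # coverage after N plants = number of combinations first seen before index N
        gammas[t] = np.searchsorted(order, n_grid, side="left") / M
    sd = gammas.std(axis=0, ddof=1) if design.n_trials > 1 else np.zeros(n_grid.size)
    return CoverageCurve(n_grid=n_grid, gamma=gammas.mean(axis=0), gamma_sd=sd)


def knockout_count_distribution(
    library: GuideLibrary,
    r: int,
    eps_KO: float,
    n_samples: int,
    rng: np.random.Generator,
) -> KnockoutCountDistribution:
    """Empirical distribution of knockouts per plant over ``n_samples`` plants."""
    if n_samples < 1:
        raise ValueError(f"n_samples must be >= 1, got {n_samples}")
    cum = np.cumsum(library.freq)
    cum[-1] = 1.0
    p_hit = library.eps_edit * float(eps_KO)
    hist = np.zeros(r + 1, dtype=np.int64)
    remaining = n_samples
    while remaining > 0:
        size = min(remaining, _CHUNK_MAX)
        _, _, counts = _plant_chunk(library, r, eps_KO, size, rng, cum, p_hit)
        hist += np.bincount(counts, minlength=r + 1)
        remaining -= size
    return KnockoutCountDistribution(probs=hist / n_samples)
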