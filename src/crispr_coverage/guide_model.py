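"""The gRNA pool: abundances, editing efficiencies, calibrated libraries.

Guide abundances in the construct library are never uniform in practice
(synthesis, quantification and pooling biases); they are modelled here
by a double-truncated normal whose only consequential parameter is the
skew ``rho`` — the ratio of the most to the least abundant guide — since
the raw abundances are normalised into relative frequencies.  Editing
efficiencies follow a bimodal mixture: a fraction ``f_act`` of guides is
highly active (efficiency ~ N(eps_edit_act, sd)), the rest nearly dead
(~ N(eps_edit_inact, sd)), both clamped to [0, 1].

A :class:`GuideLibrary` can also be loaded from a calibration TSV
(columns ``grna_id  gene_id  abundance  eps_edit``) measured by
sequencing a real construct library.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .design import (
    STREAM_EFFICIENCIES,
    STREAM_FREQUENCIES,
    ExperimentDesign,
    InvalidDesignError,
    substream,
)

__all__ = [
    "FrequencyDistributionSpec",
    "GuideLibrary",
    "LibraryFormatError",
    "frequency_spec",
    "sample_frequencies",
    "sample_editing_efficiencies",
    "build_library",
    "load_calibrated_library",
]

_FREQ_TOL = 1e-12


class LibraryFormatError(ValueError):
    """A calibrated-library file violates the expected TSV format."""


@dataclass(frozen=True)
class FrequencyDistributionSpec:
    """Double-truncated normal for raw guide abundances.

    Truncation bounds ``l`` and ``u`` with ``u/l = rho``; the underlying
    normal has ``mu = (l+u)/2`` and ``sigma = (u-l)/2``. The absolute
    scale cancels under normalisation, only the ratio matters.
    """

    l: float
    u: float
    mu: float
    sigma: float


def frequency_spec(rho: float) -> FrequencyDistributionSpec:
    """Abundance-distribution parameters for a given skew ``rho >= 1``.

    The lower bound is fixed at 50 (arbitrary; the scale is immaterial),
    the upper bound at ``50 * rho``. ``rho = 1`` degenerates to a point
    mass, i.e. a uniform guide pool after normalisation.
    """
    if rho < 1:
        raise InvalidDesignError(f"rho must be >= 1, got {rho}")
    l = 50.0
    u = 50.0 * rho
    return FrequencyDistributionSpec(l=l, u=u, mu=(l + u) / 2.0, sigma=(u - l) / 2.0)


@dataclass(frozen=True)
class GuideLibrary:
    """A realised gRNA pool: gene mapping, frequencies, efficiencies.

    ``gene_of`` holds, per guide, the integer index of its target gene in
    ``genes``; ``freq`` the relative frequency of each guide in the
    construct library (sums to one); ``eps_edit`` its genome-editing
    efficiency.
    """

    genes: tuple[str, ...]
    guides: tuple[str, ...]
    gene_of: np.ndarray
    freq: np.ndarray
    eps_edit: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "gene_of", np.asarray(self.gene_of, dtype=np.int64))
        object.__setattr__(self, "freq", np.asarray(self.freq, dtype=np.float64))
        object.__setattr__(self, "eps_edit", np.asarray(self.eps_edit, dtype=np.float64))
        n = len(self.guides)
        if not (len(self.gene_of) == len(self.freq) == len(self.eps_edit) == n):
            raise LibraryFormatError("guides, gene_of, freq and eps_edit must have equal length")
        if n == 0:
            raise LibraryFormatError("library must contain at least one gRNA")
        if len(set(self.guides)) != n:
            raise LibraryFormatError("duplicate gRNA identifiers")
        if np.any(self.freq < 0) or abs(self.freq.sum() - 1.0) > _FREQ_TOL:
            raise LibraryFormatError("frequencies must be non-negative and sum to 1")
        if np.any((self.eps_edit < 0) | (self.eps_edit > 1)):
            raise LibraryFormatError("editing efficiencies must lie in [0, 1]")
        if self.gene_of.min() < 0 or self.gene_of.max() >= len(self.genes):
            raise LibraryFormatError("gene_of indices out of range")
        if len(np.unique(self.gene_of)) != len(self.genes):
            raise LibraryFormatError("every gene must have at least one gRNA")

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_guides(self) -> int:
        return len(self.guides)

    def gene_knockout_weights(self, eps_KO: float = 1.0) -> np.ndarray:
        """Per-gene probability that one construct slot knocks it out.

        For gene *i* this is ``sum over its guides of freq * eps_edit *
        eps_KO`` — the chance that a single guide drawn into a construct
        targets the gene, edits it, and the edit disrupts function.
        """
        w = np.bincount(self.gene_of, weights=self.freq * self.eps_edit, minlength=self.n_genes)
        return w * float(eps_KO)


def sample_frequencies(design: ExperimentDesign, rng: np.random.Generator) -> np.ndarray:
    """Draw normalised relative frequencies for all ``x * g`` guides.

    Raw abundances come from the truncated normal of
    :func:`frequency_spec`; truncation is exact (no leakage outside
    ``[l, u]``), so the realised max/min frequency ratio never exceeds
    ``rho``. With ``rho = 1`` every guide gets frequency ``1/(x*g)``.
    """
    spec = frequency_spec(design.rho)
    n = design.n_guides
    if spec.sigma == 0.0:
        return np.full(n, 1.0 / n)
    # standardised bounds are always (-1, 1) by construction of the spec
    raw = stats.truncnorm.rvs(-1.0, 1.0, loc=spec.mu, scale=spec.sigma, size=n, random_state=rng)
    return raw / raw.sum()


def sample_editing_efficiencies(design: ExperimentDesign, rng: np.random.Generator) -> np.ndarray:
    """Draw per-guide editing efficiencies from the bimodal mixture.

    Each guide is independently active with probability ``f_act``;
    active guides draw from N(eps_edit_act, sd), inactive ones from
    N(eps_edit_inact, sd); results are clamped to [0, 1] (inert at the
    default sd of 0.01).
    """
    n = design.n_guides
    active = rng.random(n) < design.f_act
    means = np.where(active, design.eps_edit_act, design.eps_edit_inact)
    eff = rng.normal(means, design.eps_edit_sd)
    return np.clip(eff, 0.0, 1.0)


def build_library(design: ExperimentDesign, seed: int | None = None) -> GuideLibrary:
    """Sample a complete guide library for a design, reproducibly.

    Guide *j* of gene *i* is named ``G{i}_g{j}`` (1-based). Frequencies
    and efficiencies come from dedicated substreams of ``seed`` (default:
    the design's master seed), so the same (design, seed) pair always
    yields a bit-identical library.
    """
    if seed is None:
        seed = design.seed
    genes = tuple(f"G{i + 1}" for i in range(design.x))
    guides = tuple(f"G{i + 1}_g{j + 1}" for i in range(design.x) for j in range(design.g))
    gene_of = np.repeat(np.arange(design.x), design.g)
    freq = sample_frequencies(design, substream(seed, STREAM_FREQUENCIES))
    eps_edit = sample_editing_efficiencies(design, substream(seed, STREAM_EFFICIENCIES))
    return GuideLibrary(genes=genes, guides=guides, gene_of=gene_of, freq=freq, eps_edit=eps_edit)


def load_calibrated_library(
    path,
    design: ExperimentDesign | None = None,
    seed: int | None = None,
) -> GuideLibrary:
    """Load a guide library from a calibration TSV.

    The file must be tab-separated with header columns ``grna_id``,
    ``gene_id``, ``abundance`` and (optionally) ``eps_edit``. Abundances
    are normalised into relative frequencies; arbitrary per-gene guide
    counts are accepted. If the ``eps_edit`` column is absent,
    efficiencies are sampled from the bimodal model of the supplied
    ``design`` (a message is emitted on the module logger).
    """
    table = pd.read_csv(path, sep="\t", dtype={"grna_id": str, "gene_id": str})
    missing = [c for c in ("grna_id", "gene_id", "abundance") if c not in table.columns]
    if missing:
        raise LibraryFormatError(f"calibrated library is missing column(s): {', '.join(missing)}")
    if table["grna_id"].duplicated().any():
        dupes = table.loc[table["grna_id"].duplicated(), "grna_id"].tolist()
        raise LibraryFormatError(f"duplicate grna_id entries: {dupes}")

    abundance = table["abundance"].to_numpy(dtype=np.float64)
    if np.any(abundance <= 0):
        raise LibraryFormatError("abundances must be strictly positive")

    genes = tuple(dict.fromkeys(table["gene_id"]))  # first-appearance order
    gene_index = {g: i for i, g in enumerate(genes)}
    gene_of = np.array([gene_index[g] for g in table["gene_id"]], dtype=np.int64)

    if "eps_edit" in table.columns:
        eps_edit = table["eps_edit"].to_numpy(dtype=np.float64)
        if np.any((eps_edit < 0) | (eps_edit > 1)):
            raise LibraryFormatError("eps_edit values must lie in [0, 1]")
    else:
        if design is None:
            raise LibraryFormatError(
                "file has no eps_edit column; pass a design to sample efficiencies from"
            )
        import logging

        logging.getLogger(__name__).info(
            "calibrated library %s lacks eps_edit; sampling efficiencies from the bimodal model",
            path,
        )
        n = len(table)
        rng = substream(design.seed if seed is None else seed, STREAM_EFFICIENCIES)
        active = rng.random(n) < design.f_act
        means = np.where(active, design.eps_edit_act, design.eps_edit_inact)
        eps_edit = np.clip(rng.normal(means, design.eps_edit_sd), 0.0, 1.0)

    freq = abundance / abundance.sum()
    return GuideLibrary(
        genes=genes,
        guides=tuple(table["grna_id"]),
        gene_of=gene_of,
        freq=freq,
        eps_edit=eps_edit,
    )
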