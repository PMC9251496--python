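"""Coupon-collector estimator of the plant library size for full coverage.

The screen is abstracted as a coupon-collector problem with unequal
probabilities: the "coupons" (modules) are the C(x, k) k-combinations
of gene knockouts, each plant performs ``m = C(r, k)`` module draws, and
a single draw yields combination *j* with probability ``q_j`` derived
from the guide library (frequencies, editing efficiencies, knockout
efficiency). Draws may also yield nothing — the mass ``1 - sum(q)``
covers constructs whose guides fail to edit or hit too few distinct
genes.

With T the number of module draws until every module has been seen,
Poissonization gives the exact expectation

    E[T] = integral_0^inf (1 - prod_j (1 - exp(-q_j t))) dt

and the second moment of the continuous completion time,
``E[T^2] = 2 * integral t * (1 - prod(...)) dt``. The draw count N
satisfies E[N] = E[T] and Var(N) = Var(T) - E[T] (the completion time is
a sum of N i.i.d. Exp(1) inter-arrival gaps independent of N). Plant
counts are module-draw counts divided by m.

Treating modules as independent also yields, per plant count N,
the probability of full coverage P = prod_j (1 - (1-q_j)^(N m)) and the
(exact, by linearity) expected coverage
E[gamma] = mean_j (1 - (1-q_j)^(N m)).
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb, factorial

import numpy as np
from scipy import integrate

from ._combinatorics import all_combinations
from .guide_model import GuideLibrary
from .results import CoverageCurve

__all__ = [
    "ModuleProbabilities",
    "UnreachableModuleError",
    "combination_probabilities",
    "expected_min_size",
    "std_min_size",
    "success_probability",
    "expected_coverage",
    "size_for_probability",
    "size_for_coverage",
    "coverage_curve",
]

_MAX_K = 4  # enumeration of combination probabilities is O(C(x,k))
_QUAD_RTOL = 1e-10


class UnreachableModuleError(ValueError):
    """Some combination has zero probability; full coverage is impossible."""

    def __init__(self, message: str, combos: list[tuple[str, ...]]):
        super().__init__(message)
        self.combos = combos


@dataclass(frozen=True)
class ModuleProbabilities:
    """Per-plant module probabilities of the coupon-collector abstraction.

    ``combos[j]`` names the j-th k-combination of genes (colex order),
    ``q[j]`` is the probability that one module draw yields it as an
    effective set of knockouts, and ``m`` is the number of module draws
    a single plant provides (C(r, k)). ``sum(q) <= 1``; the deficit is
    the per-draw probability of producing no effective k-combination.
    """

    combos: tuple
    q: np.ndarray
    m: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "q", np.asarray(self.q, dtype=np.float64))
        if len(self.combos) != len(self.q):
            raise ValueError("combos and q must have equal length")
        if self.m < 1:
            raise ValueError(f"m must be >= 1, got {self.m}")
        if np.any(self.q < 0) or self.q.sum() > 1.0 + 1e-9:
            raise ValueError("q entries must be >= 0 with sum <= 1")

    @property
    def M(self) -> int:
        return len(self.q)

    def _require_reachable(self) -> None:
        if np.any(self.q <= 0):
            bad = [self.combos[i] for i in np.nonzero(self.q <= 0)[0][:10]]
            raise UnreachableModuleError(
                f"{int((self.q <= 0).sum())} combination(s) have zero probability "
                f"(e.g. {bad[:5]}); the expected waiting time is infinite",
                bad,
            )


def combination_probabilities(
    library: GuideLibrary, k: int, r: int, eps_KO: float
) -> ModuleProbabilities:
    """Translate a guide library into module probabilities.

    For ``k = 1`` the probability of knocking out gene *i* in one module
    draw is the sum over its guides of ``freq * eps_edit * eps_KO``. For
    ``k > 1`` a module draw is a k-tuple of construct slots; the ordered
    tuples of k distinct guides hitting k distinct genes contribute
    ``k! * prod(freq) * prod(eps_edit) * eps_KO**k``, which summed over
    the guide choices factorises per gene. Tuples reusing a gene cannot
    produce k distinct knockouts and fall into the deficit mass.
    """
    if not 1 <= k <= library.n_genes:
        raise ValueError(f"k must satisfy 1 <= k <= number of genes, got k={k}")
    if r < k:
        raise ValueError(f"r must be >= k, got r={r}, k={k}")
    if k > _MAX_K:
        raise ValueError(
            f"k={k} exceeds the supported maximum of {_MAX_K}; the module "
            f"enumeration grows as C(x, k)"
        )
    w = library.gene_knockout_weights(eps_KO)  # per-slot knockout probability per gene
    idx = all_combinations(library.n_genes, k)
    q = factorial(k) * np.prod(w[idx], axis=1)
    combos = tuple(tuple(library.genes[i] for i in row) for row in idx)
    return ModuleProbabilities(combos=combos, q=q, m=comb(r, k))


def _survival(q: np.ndarray):
    """P(collection incomplete at Poissonized time t), vector-safe in t."""

    def surv(t: float) -> float:
        with np.errstate(over="ignore"):
            log_terms = np.log1p(-np.exp(-q * t))
        return -np.expm1(log_terms.sum())

    return surv


def _expected_draws(q: np.ndarray) -> float:
    surv = _survival(q)
    scale = 1.0 / q.min()
    value, _ = integrate.quad(
        lambda s: surv(s * scale), 0.0, np.inf, epsrel=_QUAD_RTOL, epsabs=0.0, limit=400
    )
    return value * scale


def expected_min_size(mp: ModuleProbabilities) -> float:
    """Expected number of plants until full coverage, E[N_{x,k}].

    Evaluates the Poissonized waiting-time integral for the module draws
    and divides by the ``m`` draws each plant contributes. Reported
    unrounded; presentation layers round up to whole plants.
    """
    mp._require_reachable()
    return _expected_draws(mp.q) / mp.m


def std_min_size(mp: ModuleProbabilities) -> float:
    """Standard deviation of the plant library size for full coverage.

    Uses the exact relation Var(draws) = Var(T) - E[T] between the
    discrete draw count and the Poissonized completion time T, whose
    moments are quadratures (see module docstring).
    """
    mp._require_reachable()
    q = mp.q
    surv = _survival(q)
    scale = 1.0 / q.min()
    e_t = _expected_draws(q)
    second, _ = integrate.quad(
        lambda s: s * surv(s * scale), 0.0, np.inf, epsrel=_QUAD_RTOL, epsabs=0.0, limit=400
    )
    e_t2 = 2.0 * second * scale**2
    var_draws = max(e_t2 - e_t**2 - e_t, 0.0)
    return float(np.sqrt(var_draws)) / mp.m


def success_probability(mp: ModuleProbabilities, N: int) -> float:
    """Probability that N plants cover every combination at least once.

    Modules are treated as independent: P = prod_j (1 - (1-q_j)^(N m)).
    Any zero-probability module simply pins the result at 0.
    """
    if N < 0:
        raise ValueError(f"N must be >= 0, got {N}")
    if N == 0:
        return 0.0 if mp.M >= 1 else 1.0
    with np.errstate(divide="ignore"):
        miss = np.exp(N * mp.m * np.log1p(-mp.q))  # (1-q)^(N m)
    if np.any(miss >= 1.0):
        return 0.0
    return float(np.exp(np.log1p(-miss).sum()))


def expected_coverage(mp: ModuleProbabilities, N: int) -> float:
    """Expected fraction of combinations covered by N plants (exact)."""
    if N < 0:
        raise ValueError(f"N must be >= 0, got {N}")
    if N == 0:
        return 0.0
    with np.errstate(divide="ignore"):
        gamma = -np.expm1(N * mp.m * np.log1p(-mp.q))
    return float(gamma.mean())


def _bisect_size(fn, mp: ModuleProbabilities, target: float) -> int:
    hi = 1
    while fn(mp, hi) < target:
        hi *= 2
        if hi > 1 << 62:  # pragma: no cover - guarded by q > 0 checks
            raise RuntimeError("target not reachable")
    lo = hi // 2  # fn(lo) < target for lo >= 1; lo = 0 always below target
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if fn(mp, mid) >= target:
            hi = mid
        else:
            lo = mid
    return hi


def size_for_probability(mp: ModuleProbabilities, target: float) -> int:
    """Smallest N with success_probability(N) >= target (0 < target < 1)."""
    if not 0.0 < target < 1.0:
        raise ValueError(f"target must lie strictly in (0, 1), got {target}")
    mp._require_reachable()
    return _bisect_size(success_probability, mp, target)


def size_for_coverage(mp: ModuleProbabilities, target: float) -> int:
    """Smallest N with expected_coverage(N) >= target (0 < target < 1).

    A target of exactly 1 is rejected: the expected coverage reaches 1
    only asymptotically.
    """
    if not 0.0 < target < 1.0:
        raise ValueError(
            f"target must lie strictly in (0, 1) (expected coverage reaches 1 "
            f"only as N -> infinity), got {target}"
        )
    mp._require_reachable()
    return _bisect_size(expected_coverage, mp, target)


def coverage_curve(mp: ModuleProbabilities, n_grid) -> CoverageCurve:
    """Expected coverage and full-coverage probability along a size grid."""
    n_grid = np.asarray(n_grid, dtype=np.int64)
    gamma = np.array([expected_coverage(mp, int(n)) for n in n_grid])
    p_full = np.array([success_probability(mp, int(n)) for n in n_grid])
    return CoverageCurve(n_grid=n_grid, gamma=gamma, p_full=p_full)
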