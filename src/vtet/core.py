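"""The variable threshold exact test (VTET).

Given per-subject CNV-evidence p-values p_1..p_{m+n} for m cases and n
controls, subjects with p_i <= q are tentative CNV carriers at threshold q.
Rather than committing to one q, a grid q_1 > ... > q_K is chosen so that
q_k = e_k / (m + n) yields e_k expected false carriers (default
e = (5, 2, 1, 0.5, 0.1)).  At each q_k a Fisher exact test compares carrier
counts a(q_k) cases vs b(q_k) controls, and the overall statistic is

    Q = min_k P(q_k).

Significance comes from permuting case-control labels.  Because the
evidence p-values do not depend on labels, the carrier set at each q_k is
fixed across permutations; a permutation only re-draws how many carriers
land in cases, so each permutation costs O(K) hypergeometric bookkeeping.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import hypergeom
from scipy.stats import fisher_exact as _sp_fisher

__all__ = [
    "VtetParams",
    "VtetResult",
    "thresholds_from_expected",
    "carrier_counts",
    "fisher_exact",
    "vtet_statistic",
    "permutation_test",
    "q_statistic_for_labels",
    "fast_q_for_labels",
]

DEFAULT_EXPECTED_FALSE = (5.0, 2.0, 1.0, 0.5, 0.1)


@dataclass(frozen=True)
class VtetParams:
    """Threshold grid and permutation-scheme configuration.

    expected_false
        Expected numbers of false tentative carriers among all m+n subjects;
        strictly decreasing.  q_k = expected_false[k] / (m + n).
    min_successes
        Sequential stopping: permutations run until this many exceedances
        (permuted Q <= observed Q) are seen, or max_permutations is reached.
    sided
        'one' tests case enrichment of carriers (the working hypothesis);
        'two' uses the two-sided Fisher test.
    """

    expected_false: tuple = DEFAULT_EXPECTED_FALSE
    min_successes: int = 10
    max_permutations: int = 10**6
    seed: int = 0
    sided: str = "one"

    def __post_init__(self):
        ef = np.asarray(self.expected_false, dtype=float)
        if ef.ndim != 1 or len(ef) < 1:
            raise ValueError("expected_false must be a non-empty vector")
        if np.any(ef <= 0) or np.any(np.diff(ef) >= 0):
            raise ValueError("expected_false must be strictly decreasing and positive")
        if self.sided not in ("one", "two"):
            raise ValueError("sided must be 'one' or 'two'")
        object.__setattr__(self, "expected_false", tuple(ef))

    @property
    def K(self) -> int:
        return len(self.expected_false)


@dataclass
class VtetResult:
    """VTET output for one region: thresholds, counts, Fisher p's, Q, perm p."""

    thresholds: np.ndarray
    count_cases: np.ndarray
    count_controls: np.ndarray
    fisher_p: np.ndarray
    Q: float
    perm_p: float = np.nan
    n_perm_used: int = 0
    seed: int | None = None
    m: int = 0
    n: int = 0


def thresholds_from_expected(m: int, n: int, expected_false=DEFAULT_EXPECTED_FALSE):
    """Carrier-calling thresholds q_k = expected_false_k / (m + n)."""
    if m < 1 or n < 1:
        raise ValueError("need at least one case and one control")
    ef = np.asarray(expected_false, dtype=float)
    return ef / (m + n)


def carrier_counts(pvals, case_mask, q: float):
    """Tentative-carrier counts (a, b) in cases and controls at threshold q.

    Subjects with p_i <= q are carriers; equality counts.
    """
    pvals = np.asarray(pvals, dtype=float)
    case_mask = np.asarray(case_mask, dtype=bool)
    if pvals.shape != case_mask.shape:
        raise ValueError("pvals and labels have different lengths")
    carrier = pvals <= q
    a = int(np.sum(carrier & case_mask))
    b = int(np.sum(carrier & ~case_mask))
    return a, b


def fisher_exact(a: int, b: int, m: int, n: int, sided: str = "one") -> float:
    """Fisher exact p-value for the 2x2 table of carriers vs case status.

    One-sided (default): the hypergeometric upper-tail probability of seeing
    >= a carrier-cases given margins (a+b carriers, m cases, n controls).
    """
    if not (0 <= a <= m and 0 <= b <= n):
        raise ValueError("counts exceed group sizes")
    if sided == "one":
        return float(hypergeom.sf(a - 1, m + n, m, a + b))
    if sided == "two":
        return float(_sp_fisher([[a, m - a], [b, n - b]], alternative="two-sided")[1])
    raise ValueError("sided must be 'one' or 'two'")


def _fisher_lookup(c: int, m: int, n: int, sided: str) -> np.ndarray:
    """p-value indexed by a for a fixed carrier margin c."""
    a = np.arange(c + 1)
    if sided == "one":
        return hypergeom.sf(a - 1, m + n, m, c)
    return np.array([fisher_exact(int(j), c - int(j), m, n, "two") for j in a])


def vtet_statistic(pvals, case_mask, qs, sided: str = "one"):
    """Q = min_k Fisher-p at threshold q_k, plus the per-threshold bookkeeping.

    Returns a :class:`VtetResult` with perm_p unset.
    """
    case_mask = np.asarray(case_mask, dtype=bool)
    m = int(case_mask.sum())
    n = int((~case_mask).sum())
    qs = np.asarray(qs, dtype=float)
    aa, bb, pp = [], [], []
    for q in qs:
        a, b = carrier_counts(pvals, case_mask, q)
        aa.append(a)
        bb.append(b)
        pp.append(fisher_exact(a, b, m, n, sided))
    pp = np.asarray(pp)
    return VtetResult(
        thresholds=qs,
        count_cases=np.asarray(aa),
        count_controls=np.asarray(bb),
        fisher_p=pp,
        Q=float(pp.min()),
        m=m,
        n=n,
    )


def _carrier_depths(pvals, qs) -> np.ndarray:
    """For each carrier at the loosest threshold, the deepest k with p <= q_k.

    qs is strictly decreasing, so the carrier sets are nested and a carrier's
    depth d means it is a carrier at thresholds 1..d.  Returns the depth of
    every carrier (1-based), in arbitrary order.
    """
    pvals = np.asarray(pvals, dtype=float)
    qs = np.asarray(qs, dtype=float)
    carriers = pvals[pvals <= qs[0]]
    return (carriers[:, None] <= qs[None, :]).sum(axis=1)


def q_statistic_for_labels(pvals, case_mask, qs, sided: str = "one") -> float:
    """Naive Q: full carrier-count and Fisher recomputation for given labels."""
    return vtet_statistic(pvals, case_mask, qs, sided).Q


def fast_q_for_labels(pvals, case_mask, qs, sided: str = "one") -> float:
    """O(K)-per-permutation Q via fixed carrier sets and depth bookkeeping.

    Exactly equal to :func:`q_statistic_for_labels`; used to verify the
    permutation fast path on explicit label shuffles.
    """
    case_mask = np.asarray(case_mask, dtype=bool)
    pvals = np.asarray(pvals, dtype=float)
    m = int(case_mask.sum())
    n = int((~case_mask).sum())
    qs = np.asarray(qs, dtype=float)
    K = len(qs)
    carrier = pvals <= qs[0]
    depths = (pvals[carrier][:, None] <= qs[None, :]).sum(axis=1)
    c_at = np.array([(depths >= k).sum() for k in range(1, K + 1)])
    case_depth = depths[case_mask[carrier]]
    best = 1.0
    for k in range(1, K + 1):
        a = int((case_depth >= k).sum())
        best = min(best, fisher_exact(a, int(c_at[k - 1]) - a, m, n, sided))
    return best


def permutation_test(pvals, case_mask, params: VtetParams, batch: int = 2000) -> VtetResult:
    """VTET with permutation significance.

    The observed Q is compared against Q under random case-control label
    assignments.  Carrier sets are label-free, so each permutation draws the
    per-depth-group case counts from a multivariate hypergeometric (assigning
    m case labels at random among all subjects) and evaluates K table
    lookups.  Stops once ``min_successes`` exceedances (permuted Q <=
    observed Q, ties counting) accumulate, or at ``max_permutations``;
    perm_p = (1 + successes) / (n_used + 1).
    """
    case_mask = np.asarray(case_mask, dtype=bool)
    pvals = np.asarray(pvals, dtype=float)
    m = int(case_mask.sum())
    n = int((~case_mask).sum())
    if m == 0 or n == 0:
        raise ValueError("need at least one case and one control")
    qs = thresholds_from_expected(m, n, params.expected_false)
    obs = vtet_statistic(pvals, case_mask, qs, params.sided)
    K = params.K

    depths = _carrier_depths(pvals, qs)
    # group g_d = carriers whose deepest threshold is exactly d; the last
    # colour is the non-carrier pool
    g = np.bincount(depths, minlength=K + 1)[1:]
    colors = np.concatenate([g, [m + n - g.sum()]]).astype(np.int64)
    c_at = g[::-1].cumsum()[::-1]  # carriers at threshold k = sum_{d>=k} g_d
    lookups = [_fisher_lookup(int(c), m, n, params.sided) for c in c_at]

    rng = np.random.default_rng(params.seed)
    successes = 0
    used = 0
    while used < params.max_permutations and successes < params.min_successes:
        k = min(batch, params.max_permutations - used)
        draw = rng.multivariate_hypergeometric(colors, m, size=k)[:, :K]
        a_at = draw[:, ::-1].cumsum(axis=1)[:, ::-1]  # cases among carriers at k
        qperm = np.min(
            np.column_stack([lookups[j][a_at[:, j]] for j in range(K)]), axis=1
        )
        successes += int(np.sum(qperm <= obs.Q))
        used += k

    obs.perm_p = (1.0 + successes) / (used + 1.0)
    obs.n_perm_used = used
    obs.seed = params.seed
    return obs
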