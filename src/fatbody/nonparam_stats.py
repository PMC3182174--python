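"""Exact small-sample rank statistics and the resampling-verified cutoff.

This module implements the nonparametric testing battery used throughout the
spectral-count and age-contrast analyses:

* an exact two-sided Mann-Whitney U test whose null distribution is obtained
  by full enumeration of the tie-free rank-sum distribution (a dynamic
  program equivalent to enumerating all ``C(n1+n2, n1)`` rank assignments),
  with a seeded Monte-Carlo permutation fallback under ties;
* a Kruskal-Wallis test with tie correction, with exact enumeration for
  small totals and a shared permutation null otherwise;
* a permutation procedure that verifies a nominal significance cutoff by
  shuffling group labels across samples (sampling without replacement) and
  re-running the whole test battery;
* the dual ``+0.5`` / ``-0.5`` missing-value replacement rule for
  z-transformed label ratios;
* the genotype / treatment effect classifier operating on the three
  group-contrast p-values (CL/KL, CH/KH, CL/CH).

Two-sided p-values follow the convention ``2 * min(P(W <= w), P(W >= w))``
capped at 1, which is what small-sample rank tables print.
"""
from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats

from .design import Design
from .errors import ConfigurationError, DomainError, InsufficientDataError

__all__ = [
    "RankTestResult",
    "CutoffVerification",
    "DualImputationResult",
    "exact_mwu",
    "mwu_p_from_ranksum",
    "ranksum_null_counts",
    "kruskal_wallis",
    "verify_cutoff",
    "dual_imputation_test",
    "classify_effect",
]


@dataclass
class RankTestResult:
    """Outcome of a two-group rank test.

    ``rank_sum_1 + rank_sum_2`` always equals ``N(N+1)/2`` where
    ``N = n1 + n2`` (mid-ranks preserve the total under ties).  ``exact`` is
    True when the p-value came from enumeration of the tie-free null.
    """

    n1: int
    n2: int
    rank_sum_1: float
    rank_sum_2: float
    U: float
    p_two_sided: float
    exact: bool
    method: str = "enumeration"


@dataclass
class CutoffVerification:
    """Result of the label-permutation check of a nominal alpha.

    ``fractions`` holds, for each iteration, the fraction of proteins whose
    re-tested p-value fell at or below ``nominal_alpha`` after the group
    labels were randomly reassigned (sampling without replacement).
    ``verified`` means the mean resampled fraction does not exceed the
    nominal level.
    """

    nominal_alpha: float
    n_iterations: int
    fractions: np.ndarray
    empirical_fpr: float
    verified: bool
    seed: int | None = None
    battery: str = "kw"


@dataclass
class DualImputationResult:
    p_final: float
    retained: bool
    excluded: bool = False
    reason: str | None = None
    p_plus: float = float("nan")
    p_minus: float = float("nan")


# ---------------------------------------------------------------------------
# Exact Mann-Whitney machinery
# ---------------------------------------------------------------------------

@lru_cache(maxsize=128)
def ranksum_null_counts(n1: int, n2: int) -> np.ndarray:
    """Frequencies of the tie-free rank-sum null for the first group.

    Returns an integer array ``c`` where ``c[w]`` is the number of the
    ``C(n1+n2, n1)`` equally likely subsets of ranks ``{1..n1+n2}`` of size
    ``n1`` whose sum is ``w``.  Computed by the classic subset-sum dynamic
    program, which is an exact enumeration of the null distribution.
    """
    n = n1 + n2
    max_sum = sum(range(n - n1 + 1, n + 1))
    # table[k, w] = number of k-subsets of the ranks seen so far summing to w
    table = np.zeros((n1 + 1, max_sum + 1), dtype=np.int64)
    table[0, 0] = 1
    for rank in range(1, n + 1):
        for k in range(min(rank, n1), 0, -1):
            table[k, rank:] += table[k - 1, : max_sum + 1 - rank]
    return table[n1]


def _two_sided_from_counts(counts: np.ndarray, w: int) -> float:
    total = counts.sum()
    lo = counts[: w + 1].sum()
    hi = counts[w:].sum()
    return float(min(1.0, 2.0 * min(lo, hi) / total))


def mwu_p_from_ranksum(n1: int, n2: int, rank_sum: float) -> float:
    """Exact two-sided p-value from a printed rank sum under the tie-free null.

    The achievable range for the first group's rank sum is
    ``[n1(n1+1)/2, n1(2 n2 + n1 + 1)/2]``; values outside it (or
    non-integral values, which cannot occur without ties) raise
    :class:`DomainError`.
    """
    if n1 < 1 or n2 < 1:
        raise DomainError("group sizes must be positive")
    w_min = n1 * (n1 + 1) // 2
    w_max = n1 * (2 * n2 + n1 + 1) // 2
    if not float(rank_sum).is_integer():
        raise DomainError(
            f"rank sum {rank_sum} is not an integer; the tie-free null does "
            "not apply"
        )
    w = int(rank_sum)
    if not w_min <= w <= w_max:
        raise DomainError(
            f"rank sum {w} outside achievable range [{w_min}, {w_max}] "
            f"for n1={n1}, n2={n2}"
        )
    return _two_sided_from_counts(ranksum_null_counts(n1, n2), w)


def exact_mwu(
    x,
    y,
    n_permutations: int = 20000,
    rng: np.random.Generator | int | None = None,
) -> RankTestResult:
    """Two-group Mann-Whitney U test with an enumerated two-sided p-value.

    Mid-ranks are assigned over the pooled data.  Without ties the p-value is
    exact, from full enumeration of the rank-sum null.  With ties the same
    statistic is referred to a seeded Monte-Carlo permutation null
    (``n_permutations`` label shuffles) because the tie-free enumeration is
    invalid; corrected spectral counts rarely tie in practice.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 < 2 or n2 < 2:
        raise InsufficientDataError(
            f"each group needs at least 2 observations (got {n1}, {n2})"
        )
    if np.isnan(x).any() or np.isnan(y).any():
        raise InsufficientDataError("missing values must be handled upstream")
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    rs1 = float(ranks[:n1].sum())
    rs2 = float(ranks[n1:].sum())
    u = rs1 - n1 * (n1 + 1) / 2.0
    has_ties = len(np.unique(pooled)) < len(pooled)
    if not has_ties:
        p = mwu_p_from_ranksum(n1, n2, rs1)
        return RankTestResult(n1, n2, rs1, rs2, u, p, True, "enumeration")
    gen = np.random.default_rng(rng)
    lo = hi = 0
    for _ in range(n_permutations):
        perm = gen.permutation(ranks)
        w = perm[:n1].sum()
        lo += w <= rs1 + 1e-9
        hi += w >= rs1 - 1e-9
    # add-one smoothing keeps Monte-Carlo p strictly positive
    p = min(1.0, 2.0 * min(lo + 1, hi + 1) / (n_permutations + 1))
    return RankTestResult(n1, n2, rs1, rs2, u, p, False, "permutation")


# ---------------------------------------------------------------------------
# Kruskal-Wallis
# ---------------------------------------------------------------------------

def _kw_statistic(ranks: np.ndarray, sizes: list[int], tie_term: float) -> float:
    n = len(ranks)
    h = 0.0
    start = 0
    for sz in sizes:
        rs = ranks[start : start + sz].sum()
        h += rs * rs / sz
        start += sz
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    if tie_term > 0:
        h /= 1.0 - tie_term
    return h


def _tie_term(pooled: np.ndarray) -> float:
    n = len(pooled)
    _, counts = np.unique(pooled, return_counts=True)
    return float(((counts**3 - counts).sum()) / (n**3 - n))


def kruskal_wallis(
    groups: list,
    method: str = "auto",
    n_permutations: int = 20000,
    rng: np.random.Generator | int | None = None,
) -> tuple[float, float, str]:
    """Kruskal-Wallis H with tie correction and a small-sample exact option.

    ``method``:

    * ``"exact"`` — enumerate every assignment of the pooled observations to
      the group sizes (feasible for total n <= 12);
    * ``"permutation"`` — seeded Monte-Carlo label shuffles;
    * ``"asymptotic"`` — chi-square with k-1 df;
    * ``"auto"`` — exact when total n <= 12, else asymptotic.

    Returns ``(H, p, method_used)``.
    """
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2 or any(len(a) < 2 for a in arrays):
        raise InsufficientDataError("need >=2 groups with >=2 observations each")
    sizes = [len(a) for a in arrays]
    pooled = np.concatenate(arrays)
    n = len(pooled)
    ranks = stats.rankdata(pooled)
    tie = _tie_term(pooled)
    if tie >= 1.0:  # all observations identical
        return 0.0, 1.0, "degenerate"
    h_obs = _kw_statistic(ranks, sizes, tie)
    if method == "auto":
        method = "exact" if n <= 12 else "asymptotic"
    if method == "asymptotic":
        p = float(stats.chi2.sf(h_obs, len(sizes) - 1))
        return h_obs, max(min(p, 1.0), np.finfo(float).tiny), "asymptotic"
    if method == "exact":
        if n > 12:
            raise ConfigurationError("method='exact' limited to total n <= 12")
        count = total = 0
        idx = np.arange(n)
        for assignment in _group_assignments(idx, sizes):
            h = _kw_statistic(ranks[assignment], sizes, tie)
            total += 1
            count += h >= h_obs - 1e-12
        return h_obs, count / total, "exact"
    if method == "permutation":
        gen = np.random.default_rng(rng)
        count = 0
        for _ in range(n_permutations):
            perm = gen.permutation(ranks)
            count += _kw_statistic(perm, sizes, tie) >= h_obs - 1e-12
        return h_obs, (count + 1) / (n_permutations + 1), "permutation"
    raise ConfigurationError(f"method: unknown p-value method {method!r}")


def _group_assignments(idx: np.ndarray, sizes: list[int]):
    """Yield index orderings realizing every split of ``idx`` into ``sizes``."""
    if len(sizes) == 1:
        yield idx
        return
    k = sizes[0]
    for chosen in itertools.combinations(range(len(idx)), k):
        chosen = np.array(chosen)
        rest = np.delete(idx, chosen)
        head = idx[chosen]
        for tail in _group_assignments(rest, sizes[1:]):
            yield np.concatenate([head, tail])


# ---------------------------------------------------------------------------
# Vectorized battery + cutoff verification
# ---------------------------------------------------------------------------

def _battery_pvalues(
    rank_rows: np.ndarray,
    tie_terms: np.ndarray,
    labels: np.ndarray,
    battery: str,
    mwu_lookup: dict | None,
) -> np.ndarray:
    """p-values for every protein (row) under the given label assignment."""
    uniq = np.unique(labels)
    n = rank_rows.shape[1]
    if battery == "mwu":
        g1 = labels == uniq[0]
        n1, n2 = int(g1.sum()), int((~g1).sum())
        rs1 = rank_rows[:, g1].sum(axis=1)
        w = np.rint(rs1).astype(int)
        return np.array([mwu_lookup[n1, n2][v] for v in w])
    # Kruskal-Wallis, chi-square tail
    k = len(uniq)
    h = np.zeros(rank_rows.shape[0])
    for g in uniq:
        mask = labels == g
        rs = rank_rows[:, mask].sum(axis=1)
        h += rs * rs / mask.sum()
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        h = np.where(tie_terms < 1.0, h / (1.0 - tie_terms), 0.0)
    return stats.chi2.sf(h, k - 1)


def _mwu_p_lookup(n1: int, n2: int) -> np.ndarray:
    counts = ranksum_null_counts(n1, n2)
    total = counts.sum()
    cum = counts.cumsum()
    tail = total - cum + counts
    return np.minimum(1.0, 2.0 * np.minimum(cum, tail) / total)


def battery_pvalues(values: pd.DataFrame, labels: pd.Series, battery: str = "auto") -> pd.Series:
    """Per-protein p-values for a protein x sample table and group labels.

    ``battery='mwu'`` (two groups, enumerated rank-sum null) or ``'kw'``
    (chi-square Kruskal-Wallis); ``'auto'`` picks by the number of groups.
    Rows are ranked with mid-ranks; the Mann-Whitney lookup assumes the
    tie-free null (rank sums are rounded to the nearest integer).
    """
    labels = labels.loc[values.columns]
    uniq = labels.unique()
    if battery == "auto":
        battery = "mwu" if len(uniq) == 2 else "kw"
    arr = values.to_numpy(dtype=float)
    rank_rows = np.apply_along_axis(stats.rankdata, 1, arr)
    tie_terms = np.array([_tie_term(row) for row in arr])
    lookup = None
    if battery == "mwu":
        g1 = (labels == sorted(uniq)[0]).to_numpy()
        n1, n2 = int(g1.sum()), int(len(labels) - g1.sum())
        lookup = {(n1, n2): _mwu_p_lookup(n1, n2)}
    p = _battery_pvalues(rank_rows, tie_terms, labels.to_numpy(), battery, lookup)
    return pd.Series(p, index=values.index, name="p")


def verify_cutoff(
    values: pd.DataFrame,
    design: Design | pd.Series,
    alpha: float = 0.1,
    iters: int = 1000,
    seed: int | None = None,
    battery: str = "auto",
) -> CutoffVerification:
    """Verify a nominal cutoff by re-running the battery on shuffled labels.

    Group labels are permuted across samples (sampling without replacement,
    i.e. a permutation of the observed label multiset), the full per-protein
    test battery is re-run, and the fraction of proteins with ``p <= alpha``
    is recorded per iteration.  The cutoff is ``verified`` when the mean
    resampled false-positive fraction does not exceed ``alpha``.
    """
    if iters < 1:
        raise ConfigurationError(f"iters: must be >= 1 (got {iters})")
    labels = design.group_labels(list(values.columns)) if isinstance(design, Design) else design.loc[values.columns]
    uniq = labels.unique()
    if len(uniq) < 2:
        raise InsufficientDataError("need >=2 groups to verify a cutoff")
    if battery == "auto":
        battery = "mwu" if len(uniq) == 2 else "kw"
    arr = values.to_numpy(dtype=float)
    rank_rows = np.apply_along_axis(stats.rankdata, 1, arr)
    tie_terms = np.array([_tie_term(row) for row in arr])
    lookup = None
    if battery == "mwu":
        lab = np.sort(labels.to_numpy())
        n1 = int((labels == lab[0]).sum())
        n2 = len(labels) - n1
        lookup = {(n1, n2): _mwu_p_lookup(n1, n2)}
    gen = np.random.default_rng(seed)
    label_arr = labels.to_numpy()
    fractions = np.empty(iters)
    for i in range(iters):
        shuffled = gen.permutation(label_arr)
        p = _battery_pvalues(rank_rows, tie_terms, shuffled, battery, lookup)
        fractions[i] = float(np.mean(p <= alpha))
    fpr = float(fractions.mean())
    return CutoffVerification(
        nominal_alpha=alpha,
        n_iterations=iters,
        fractions=fractions,
        empirical_fpr=fpr,
        verified=fpr <= alpha,
        seed=seed,
        battery=battery,
    )


# ---------------------------------------------------------------------------
# Dual missing-value replacement
# ---------------------------------------------------------------------------

def dual_imputation_test(
    x,
    y,
    alpha: float = 0.1,
    min_present: int = 3,
    require_both_groups: bool = False,
    shift: float = 0.5,
    rng: np.random.Generator | int | None = None,
) -> DualImputationResult:
    """Two-group rank test on z-scale data with the dual +/-0.5 replacement.

    Missing entries are replaced first with ``+shift`` and next with
    ``-shift`` (0.5 standard deviations on the z scale, where SD = 1).  The
    test is run for both options; the protein is ``retained`` only when both
    variants reach ``p <= alpha``.  The reported ``p_final`` is the one from
    the ``+shift`` variant.

    Proteins present in fewer than ``min_present`` replicates (in both
    groups by default — set ``require_both_groups`` to demand it of each
    group) are excluded with reason ``"insufficient presence"`` rather than
    raising.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pres_x = int(np.isfinite(x).sum())
    pres_y = int(np.isfinite(y).sum())
    ok = (
        (pres_x >= min_present and pres_y >= min_present)
        if require_both_groups
        else (pres_x >= min_present or pres_y >= min_present)
    )
    if not ok or min(pres_x, pres_y) == 0:
        return DualImputationResult(
            p_final=float("nan"),
            retained=False,
            excluded=True,
            reason="insufficient presence",
        )
    results = {}
    for s, tag in ((shift, "plus"), (-shift, "minus")):
        xi = np.where(np.isfinite(x), x, s)
        yi = np.where(np.isfinite(y), y, s)
        results[tag] = exact_mwu(xi, yi, rng=rng).p_two_sided
    retained = results["plus"] <= alpha and results["minus"] <= alpha
    return DualImputationResult(
        p_final=results["plus"],
        retained=retained,
        p_plus=results["plus"],
        p_minus=results["minus"],
    )


# ---------------------------------------------------------------------------
# Effect classification
# ---------------------------------------------------------------------------

def classify_effect(
    p_clkl: float, p_chkh: float, p_clch: float, alpha: float = 0.1
) -> str:
    """Classify a protein as G, T, G&T or none from three contrast p-values.

    * ``G``   — genotype only: the control-group contrast CL/CH is
      significant while neither knockdown contrast is;
    * ``T``   — treatment only: CL/CH is not significant but at least one of
      CL/KL, CH/KH is;
    * ``G&T`` — CL/CH significant together with at least one knockdown
      contrast;
    * ``none`` otherwise.
    """
    for name, p in (("p_clkl", p_clkl), ("p_chkh", p_chkh), ("p_clch", p_clch)):
        if not (0.0 <= p <= 1.0):
            raise DomainError(f"{name}={p} outside [0, 1]")
    geno = p_clch < alpha
    treat = p_clkl < alpha or p_chkh < alpha
    if geno and treat:
        return "G&T"
    if geno:
        return "G"
    if treat:
        return "T"
    return "none"
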