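"""Inference layer: rank-sum and Fisher tests, seeded permutation tests
(difference in means/medians), covariate-matched permutation control,
empirical-tail enrichment, rank-based gene-set scoring, and
Benjamini–Hochberg adjustment.

Permutation p-values use the plain ``b / n`` denominator by default (so an
observation more extreme than every replicate reports p = 0); the
``(b + 1) / (n + 1)`` variant — which can never report 0 and is the better
choice for downstream thresholding — is available via ``add_one=True``.
Whenever the full label-permutation set has at most
``EXHAUSTIVE_THRESHOLD`` elements, `perm_diff_test` enumerates it exactly
instead of sampling.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from math import comb
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

EXHAUSTIVE_THRESHOLD = 10_000
_EPS = 1e-12


class StatsError(ValueError):
    pass


@dataclass(frozen=True)
class PermutationTestResult:
    statistic_name: str  # diff_means | diff_medians | tail_count | set_score
    observed: float
    n_replicates: int
    p_value: float
    seed: int | None
    tail: str  # two-sided | greater | less
    exhaustive: bool = False
    note: str | None = None


@dataclass(frozen=True)
class TailTestResult:
    percentile_cutoff: float
    direction: str  # top | bottom
    cutoff_value: float
    observed_in_tail: int
    expected_in_tail: float
    p_value: float
    n_replicates: int
    seed: int | None


# ---------------------------------------------------------------------------
# classical tests (scipy-backed)
# ---------------------------------------------------------------------------

def rank_sum_test(
    x: Sequence[float], y: Sequence[float], alternative: str = "two-sided"
) -> tuple[float, float]:
    """Unpaired Wilcoxon rank-sum (Mann–Whitney U) with midrank ties.

    Exact enumeration is used for small tie-free samples, the
    tie-corrected normal approximation otherwise (scipy's auto policy).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise StatsError("rank_sum_test requires two non-empty groups")
    res = sps.mannwhitneyu(x, y, alternative=alternative, method="auto")
    return float(res.statistic), float(res.pvalue)


def fisher_2x2(table: Sequence[Sequence[int]]) -> tuple[float, float]:
    """Two-sided Fisher's exact test on a 2x2 count table."""
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2) or (t < 0).any():
        raise StatsError("fisher_2x2 expects a 2x2 table of non-negative counts")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise StatsError("degenerate margin in 2x2 table")
    odds, p = sps.fisher_exact(t, alternative="two-sided")
    return float(odds), float(p)


def bh_adjust(p_values: Iterable[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjustment (order-preserving, monotone)."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise StatsError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# permutation tests
# ---------------------------------------------------------------------------

def _tail_p(null: np.ndarray, observed: float, tail: str,
            add_one: bool, two_sided: str = "absolute") -> float:
    """Permutation p-value. ``two_sided='absolute'`` suits null statistics
    centred at 0 (label-reshuffle differences); ``'doubled'`` (twice the
    smaller one-sided tail, capped at 1) suits uncentred statistics such as
    the matched-draw mean."""
    n = null.size
    if tail == "two-sided" and two_sided == "doubled":
        b_lo = int(np.sum(null <= observed + _EPS))
        b_hi = int(np.sum(null >= observed - _EPS))
        b = min(b_lo, b_hi)
        if add_one:
            return min(1.0, 2.0 * (b + 1) / (n + 1))
        return min(1.0, 2.0 * b / n)
    if tail == "two-sided":
        b = int(np.sum(np.abs(null) >= abs(observed) - _EPS))
    elif tail == "greater":
        b = int(np.sum(null >= observed - _EPS))
    elif tail == "less":
        b = int(np.sum(null <= observed + _EPS))
    else:
        raise StatsError(f"unknown tail {tail!r}")
    return (b + 1) / (n + 1) if add_one else b / n


def perm_diff_test(
    values: Sequence[float],
    labels: Sequence,
    stat: str = "mean",
    n_replicates: int = 10_000,
    seed: int | None = None,
    tail: str = "two-sided",
    add_one: bool = False,
    group_order: tuple | None = None,
) -> PermutationTestResult:
    """Two-group permutation test of a difference in means or medians.

    The observed statistic is stat(group A) − stat(group B), with A/B the
    first/second entry of ``group_order`` (sorted unique labels by
    default). The null reshuffles labels without replacement. When the
    number of distinct label assignments C(n, n_A) is at most
    ``EXHAUSTIVE_THRESHOLD`` the test enumerates all of them and the
    p-value is exact.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    if n_replicates < 1:
        raise StatsError("n_replicates must be >= 1")
    if values.shape != labels.shape:
        raise StatsError("values and labels must have equal length")
    uniq = sorted(set(labels.tolist()))
    if len(uniq) != 2:
        raise StatsError(f"expected exactly 2 groups, found {len(uniq)}")
    if group_order is None:
        group_order = tuple(uniq)
    mask_a = labels == group_order[0]
    n = values.size
    n_a = int(mask_a.sum())
    if n_a == 0 or n_a == n:
        raise StatsError("both groups must be non-empty")
    if stat == "mean":
        stat_fn, name = np.mean, "diff_means"
    elif stat == "median":
        stat_fn, name = np.median, "diff_medians"
    else:
        raise StatsError(f"unknown statistic {stat!r}")
    observed = float(stat_fn(values[mask_a]) - stat_fn(values[~mask_a]))

    n_total = comb(n, n_a)
    if n_total <= EXHAUSTIVE_THRESHOLD:
        null = np.empty(n_total)
        idx_all = np.arange(n)
        for r, combo in enumerate(itertools.combinations(range(n), n_a)):
            sel = np.zeros(n, dtype=bool)
            sel[list(combo)] = True
            null[r] = stat_fn(values[sel]) - stat_fn(values[~sel])
        p = _tail_p(null, observed, tail, add_one)
        return PermutationTestResult(name, observed, n_total, p, seed, tail,
                                     exhaustive=True)

    rng = np.random.default_rng(seed)
    # vectorised label reshuffle in memory-capped chunks: each row of
    # `order` is a permutation; the first n_a entries form permuted group A
    null = np.empty(n_replicates)
    chunk = max(1, min(n_replicates, 5_000_000 // n))
    done = 0
    while done < n_replicates:
        m = min(chunk, n_replicates - done)
        order = np.argsort(rng.random((m, n)), axis=1)
        perm_vals = values[order]
        if stat == "mean":
            null[done:done + m] = (perm_vals[:, :n_a].mean(axis=1)
                                   - perm_vals[:, n_a:].mean(axis=1))
        else:
            null[done:done + m] = (np.median(perm_vals[:, :n_a], axis=1)
                                   - np.median(perm_vals[:, n_a:], axis=1))
        done += m
    p = _tail_p(null, observed, tail, add_one)
    return PermutationTestResult(name, observed, n_replicates, p, seed, tail)


def matched_perm_test(
    table: pd.DataFrame,
    target_ids: Sequence[str],
    response: str,
    matching_covariate: str,
    n_replicates: int = 10_000,
    seed: int | None = None,
    tail: str = "two-sided",
    add_one: bool = False,
    id_column: str = "gene_id",
    n_strata: int = 10,
) -> PermutationTestResult:
    """Covariate-matched permutation test of a mean response.

    Each null replicate draws, for every target gene, one pool (non-target)
    gene from the same covariate stratum — deciles of the pool covariate by
    default, without replacement within a replicate — so the null sets
    reproduce the targets' covariate distribution. The p-value compares the
    targets' mean response with the null means.
    """
    target_ids = list(target_ids)
    if not target_ids:
        raise StatsError("empty target set")
    df = table[[id_column, response, matching_covariate]].dropna()
    is_target = df[id_column].isin(target_ids)
    targets = df[is_target]
    pool = df[~is_target]
    if targets.empty or pool.empty:
        raise StatsError("target or pool empty after dropping missing values")
    observed = float(targets[response].mean())

    edges = np.quantile(pool[matching_covariate],
                        np.linspace(0, 1, n_strata + 1))
    inner = np.unique(edges[1:-1])
    pool_stratum = np.searchsorted(inner, pool[matching_covariate], side="right")
    target_stratum = np.searchsorted(inner, targets[matching_covariate],
                                     side="right")
    n_strata_eff = inner.size + 1
    pool_resp = pool[response].to_numpy()
    rng = np.random.default_rng(seed)

    n_targets = len(targets)
    null_sums = np.zeros(n_replicates)
    for s in range(n_strata_eff):
        k = int(np.sum(target_stratum == s))
        if k == 0:
            continue
        members = np.flatnonzero(pool_stratum == s)
        width = 0
        while members.size < k:
            # widen to nearest non-empty neighbouring strata
            width += 1
            lo, hi = s - width, s + width
            members = np.flatnonzero(
                (pool_stratum >= lo) & (pool_stratum <= hi)
            )
            warnings.warn(
                f"stratum {s} has too few pool genes; widened by {width}"
            )
        # draw k without replacement per replicate, vectorised
        pick = np.argpartition(rng.random((n_replicates, members.size)),
                               k - 1, axis=1)[:, :k]
        null_sums += pool_resp[members[pick]].sum(axis=1)
    null = null_sums / n_targets
    p = _tail_p(null, observed, tail, add_one, two_sided="doubled")
    return PermutationTestResult("diff_means", observed, n_replicates, p,
                                 seed, tail,
                                 note="covariate-matched null (stratified draw)")


def tail_count_test(
    values: pd.Series,
    subset_ids: Sequence[str],
    percentile: float = 0.05,
    direction: str = "top",
    n_replicates: int = 10_000,
    seed: int | None = None,
    add_one: bool = False,
) -> TailTestResult:
    """Is a gene set over-represented in a tail of a genome-wide empirical
    distribution?

    The cutoff is the empirical percentile of all (non-missing) values;
    membership is inclusive at the cutoff. Observed = subset genes beyond
    the cutoff; expected = percentile x |subset|. The null is the tail
    count of a uniform random same-size gene set drawn without replacement
    — sampled from its exact distribution (hypergeometric).
    """
    clean = values.dropna()
    subset_ids = [g for g in subset_ids if g in clean.index]
    if not subset_ids:
        raise StatsError("empty subset (or no subset gene has a value)")
    if direction == "top":
        cutoff = float(np.quantile(clean, 1.0 - percentile))
        in_tail = clean >= cutoff
    elif direction == "bottom":
        cutoff = float(np.quantile(clean, percentile))
        in_tail = clean <= cutoff
    else:
        raise StatsError(f"unknown direction {direction!r}")
    observed = int(in_tail.loc[subset_ids].sum())
    k = len(subset_ids)
    n_genes = clean.size
    n_good = int(in_tail.sum())
    rng = np.random.default_rng(seed)
    null = rng.hypergeometric(n_good, n_genes - n_good, k, size=n_replicates)
    p = _tail_p(null.astype(float), float(observed), "greater", add_one)
    return TailTestResult(
        percentile_cutoff=percentile, direction=direction,
        cutoff_value=cutoff, observed_in_tail=observed,
        expected_in_tail=percentile * k, p_value=p,
        n_replicates=n_replicates, seed=seed,
    )


def balancing_selection_candidates(
    pi: pd.Series, d: pd.Series, percentile: float = 0.95
) -> list[str]:
    """Genes at or above the given percentile of BOTH the pi and Tajima's D
    empirical distributions — the classic balancing-selection screen."""
    pi = pi.dropna()
    d = d.dropna()
    common = pi.index.intersection(d.index)
    if common.empty:
        return []
    cut_pi = np.quantile(pi, percentile)
    cut_d = np.quantile(d, percentile)
    hits = [g for g in common if pi[g] >= cut_pi and d[g] >= cut_d]
    return sorted(hits)


def rank_set_score(
    expression: pd.Series,
    gene_set: Sequence[str],
    n_replicates: int = 1000,
    seed: int | None = None,
    add_one: bool = False,
) -> PermutationTestResult:
    """Rank-based single-sample gene-set score with a resampling p-value.

    score = (mean midrank of the set − minimum attainable mean rank) /
    (maximum attainable − minimum attainable), so the k most expressed
    genes score 1 and the k least expressed score 0. The p-value compares
    against random same-size sets (one-sided, greater). This is a
    simplified rank-enrichment score, not the full bidirectional
    normalisation of published single-sample scoring methods.
    """
    expr = expression.dropna()
    gene_set = [g for g in gene_set if g in expr.index]
    if not gene_set:
        raise StatsError("empty gene set (or no member has expression)")
    ranks = pd.Series(sps.rankdata(expr.to_numpy()), index=expr.index)
    k = len(gene_set)
    n = expr.size
    lo = (k + 1) / 2.0
    hi = (2 * n - k + 1) / 2.0
    observed = float((ranks.loc[gene_set].mean() - lo) / (hi - lo))
    rng = np.random.default_rng(seed)
    rank_arr = ranks.to_numpy()
    pick = np.argpartition(rng.random((n_replicates, n)), k - 1, axis=1)[:, :k]
    null = (rank_arr[pick].mean(axis=1) - lo) / (hi - lo)
    p = _tail_p(null, observed, "greater", add_one)
    return PermutationTestResult(
        "set_score", observed, n_replicates, p, seed, "greater",
        note="simplified rank-enrichment score (not full singscore)",
    )
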