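"""Monte-Carlo eigenvalue test for sPCA patterns.

The test statistics are cumulative sums of sPCA eigenvalues,

    f+_j = sum of the j leading positive eigenvalues
    f-_j = sum of the j leading |negative| eigenvalues,

computed on the observed data and on datasets in which genotypes are
randomly re-assigned to coordinates (rows of X permuted, network fixed).
Step 1 tests for any global (f+) or local (f-) structure; step 2, gated on
step 1, assigns per-eigenvalue p-values against rank-matched permutation
distributions and selects significant axes with a sequential Bonferroni
cascade at thresholds alpha / rank.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .genodata import CentredFreqMatrix, ValidationError
from .spatial import SpatialWeights
from .spca import DEFAULT_TOL, SpcaResult, _symmetric_weight, spca, spca_eigenvalues

logger = logging.getLogger(__name__)

__all__ = [
    "NullDistributions",
    "RandtestResult",
    "cumulative_statistics",
    "permutation_null",
    "empirical_pvalue",
    "bonferroni_cascade",
    "spca_randtest",
]

MIN_PERMUTATIONS = 19


@dataclass
class NullDistributions:
    """Permutation null distributions of f+/f- and of each ranked eigenvalue.

    ``lambda_pos_null[b, k]`` is the (k+1)-th largest positive eigenvalue of
    permutation b, rank-aligned with the observed eigenvalues (padded with
    zeros if a permutation yields fewer eigenvalues of that sign);
    ``lambda_neg_null`` holds absolute values of the negative side.
    """

    B: int
    f_pos_null: np.ndarray
    f_neg_null: np.ndarray
    lambda_pos_null: np.ndarray  # (B, r)
    lambda_neg_null: np.ndarray  # (B, s), absolute values
    seed: int | None


@dataclass
class RandtestResult:
    """Outcome of the two-step eigenvalue permutation test."""

    f_pos_obs: float
    f_neg_obs: float
    p_global: float
    p_local: float
    eig_pvalues_pos: np.ndarray
    eig_pvalues_neg: np.ndarray
    n_sig_pos: int
    n_sig_neg: int
    alpha: float
    thresholds_pos: np.ndarray  # alpha / rank
    thresholds_neg: np.ndarray
    nulls: NullDistributions
    spca: SpcaResult


def cumulative_statistics(
    res: SpcaResult, j_pos: int | str = "all", j_neg: int | str = "all"
) -> tuple[float, float]:
    """Cumulative eigenvalue statistics (f+, f-) for the leading axes."""
    if j_pos == "all":
        jp = res.r
    else:
        jp = int(j_pos)
        if not 1 <= jp <= res.r:
            raise ValidationError(f"j_pos={j_pos} outside 1..{res.r}")
    if j_neg == "all":
        jn = res.s
    else:
        jn = int(j_neg)
        if not 1 <= jn <= res.s:
            raise ValidationError(f"j_neg={j_neg} outside 1..{res.s}")
    return float(res.lambda_pos[:jp].sum()), float(np.abs(res.lambda_neg[:jn]).sum())


def empirical_pvalue(obs: float, null: np.ndarray) -> float:
    """Upper-tail Monte-Carlo p-value with the plus-one convention.

    p = (1 + #{null >= obs}) / (B + 1): the observed configuration counts as
    one admissible permutation, so p is never zero; ties count as >=.
    """
    null = np.asarray(null, dtype=float)
    if null.size == 0:
        raise ValidationError("empty null distribution")
    return float((1 + np.count_nonzero(null >= obs)) / (null.size + 1))


def bonferroni_cascade(pvals: Sequence[float], alpha: float) -> int:
    """Sequential Bonferroni selection over rank-ordered p-values.

    Rank i (1-based) is tested at threshold alpha / i; testing stops at the
    first non-significant rank.  Comparison is strict (a p-value equal to
    its threshold is not significant).  Returns the number of leading
    significant ranks.
    """
    if not 0 < alpha < 1:
        raise ValidationError("alpha must lie in (0, 1)")
    k = 0
    for i, p in enumerate(pvals, start=1):
        if p < alpha / i:
            k = i
        else:
            break
    return k


def _resolve_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _pad_ranked(values: np.ndarray, width: int, side: str, warn: list) -> np.ndarray:
    if values.size == width:
        return values
    if not warn:
        logger.warning(
            "numerical rank wobble on the %s side (%d vs %d eigenvalues); "
            "padding/truncating to the observed count",
            side,
            values.size,
            width,
        )
        warn.append(True)
    if values.size > width:
        return values[:width]
    return np.pad(values, (0, width - values.size))


def permutation_null(
    X: CentredFreqMatrix,
    W: SpatialWeights,
    B: int = 999,
    seed: int | np.random.Generator | None = None,
    j_pos: int | str = "all",
    j_neg: int | str = "all",
    tol: float = DEFAULT_TOL,
) -> NullDistributions:
    """Monte-Carlo null: shuffle genotype rows over the fixed network B times.

    Each permutation re-assigns whole genotypes to different coordinates
    (rows of X permuted, W untouched), recomputes the sPCA eigenvalues, and
    records f+/f- plus the rank-aligned eigenvalues of both signs.
    """
    if B < MIN_PERMUTATIONS:
        raise ValidationError(f"at least {MIN_PERMUTATIONS} permutations required")
    rng = _resolve_rng(seed)
    M = _symmetric_weight(W)
    lam_pos_obs, lam_neg_obs = spca_eigenvalues(X.X, M, tol)
    r, s = lam_pos_obs.size, lam_neg_obs.size
    f_pos_null = np.empty(B)
    f_neg_null = np.empty(B)
    lam_pos_null = np.zeros((B, r))
    lam_neg_null = np.zeros((B, s))
    warned: list = []
    # "all" sums every eigenvalue of the permutation's own sign count: the
    # statistic must be a function of the permuted data alone, or the null
    # is no longer exchangeable with the observed value
    jp = None if j_pos == "all" else int(j_pos)
    jn = None if j_neg == "all" else int(j_neg)
    for b in range(B):
        perm = rng.permutation(X.n)
        lp, ln = spca_eigenvalues(X.X[perm], M, tol)
        f_pos_null[b] = lp[:jp].sum()
        f_neg_null[b] = np.abs(ln[:jn]).sum()
        lam_pos_null[b] = _pad_ranked(lp, r, "positive", warned)
        lam_neg_null[b] = _pad_ranked(np.abs(ln), s, "negative", warned)
    return NullDistributions(
        B=B,
        f_pos_null=f_pos_null,
        f_neg_null=f_neg_null,
        lambda_pos_null=lam_pos_null,
        lambda_neg_null=lam_neg_null,
        seed=seed if isinstance(seed, int) else None,
    )


def spca_randtest(
    X: CentredFreqMatrix,
    W: SpatialWeights,
    B: int = 999,
    alpha: float = 0.05,
    seed: int | np.random.Generator | None = None,
    stat_axes: int | str = "all",
    tol: float = DEFAULT_TOL,
) -> RandtestResult:
    """Two-step eigenvalue permutation test for global and local structure.

    Step 1 compares the observed f+ and f- with their permutation nulls
    (p_global, p_local).  Step 2 runs the Bonferroni cascade over
    per-eigenvalue p-values, on the positive side only when p_global <
    alpha and on the negative side only when p_local < alpha; the raw
    per-eigenvalue p-values are reported either way for inspection.
    """
    if not 0 < alpha < 1:
        raise ValidationError("alpha must lie in (0, 1)")
    res = spca(X, W, tol)
    f_pos_obs, f_neg_obs = cumulative_statistics(res, stat_axes, stat_axes)
    nulls = permutation_null(X, W, B=B, seed=seed, j_pos=stat_axes, j_neg=stat_axes, tol=tol)
    p_global = empirical_pvalue(f_pos_obs, nulls.f_pos_null)
    p_local = empirical_pvalue(f_neg_obs, nulls.f_neg_null)
    eig_p_pos = np.array(
        [
            empirical_pvalue(res.lambda_pos[k], nulls.lambda_pos_null[:, k])
            for k in range(res.r)
        ]
    )
    eig_p_neg = np.array(
        [
            empirical_pvalue(abs(res.lambda_neg[k]), nulls.lambda_neg_null[:, k])
            for k in range(res.s)
        ]
    )
    n_sig_pos = bonferroni_cascade(eig_p_pos, alpha) if p_global < alpha else 0
    n_sig_neg = bonferroni_cascade(eig_p_neg, alpha) if p_local < alpha else 0
    return RandtestResult(
        f_pos_obs=f_pos_obs,
        f_neg_obs=f_neg_obs,
        p_global=p_global,
        p_local=p_local,
        eig_pvalues_pos=eig_p_pos,
        eig_pvalues_neg=eig_p_neg,
        n_sig_pos=n_sig_pos,
        n_sig_neg=n_sig_neg,
        alpha=alpha,
        thresholds_pos=alpha / np.arange(1, res.r + 1),
        thresholds_neg=alpha / np.arange(1, res.s + 1),
        nulls=nulls,
        spca=res,
    )
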