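"""Permutation statistics over avalanche transition matrices.

Five constructions, each with its own permutation null:

1. Subject-level edge test — shuffle trial condition labels (MI vs Rest),
   recompute the edge-wise mean-ATM difference, Benjamini-Hochberg across
   edges. Exhaustive enumeration is used automatically when the number of
   distinct label assignments is small.
2. Group-level reliability — within each subject, re-scatter that subject's
   significant edges uniformly over all edge positions (preserving their
   number); edges significant in more subjects than this null predicts are
   "reliable".
3. Node-level concordance — compare each region's count of incident reliable
   edges to uniform random placement of the same number of edges.
4. Hit/miss contrast — test whether the MI-vs-Rest difference is larger in
   successful than unsuccessful trials, shuffling outcome labels within
   condition.
5. BCI-score correlation — edge-wise Spearman correlation of MI-Rest
   differences with per-subject BCI scores, averaged within 5x5 functional
   area blocks; null re-allocates edge coefficients to blocks.

All p-values include the observed statistic in the null, so p >= 1/(n_perm+1).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
from scipy.stats import rankdata

from .avalanches import TrialATMSet

logger = logging.getLogger(__name__)

__all__ = [
    "EdgeTestResult",
    "ReliabilityMap",
    "NodeResult",
    "HitMissResult",
    "AreaCorrelationResult",
    "bh_correct",
    "subject_edge_test",
    "group_reliability",
    "node_concordance",
    "hit_miss_contrast",
    "aggregate_hit_miss",
    "bci_correlation",
]


def bh_correct(p_values: np.ndarray, alpha: float = 0.05) -> tuple[np.ndarray, float]:
    """Benjamini-Hochberg step-up over a family of p-values.

    Rejects the k smallest p-values, where k is the largest index with
    p_(k) <= k * alpha / m. Returns (boolean rejections in input order,
    rejection threshold; 0.0 when nothing is rejected).
    """
    p = np.asarray(p_values, dtype=float).ravel()
    if p.size == 0:
        return np.zeros(0, dtype=bool), 0.0
    if p.min() < 0 or p.max() > 1:
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    below = ranked <= alpha * np.arange(1, m + 1) / m
    if not below.any():
        return np.zeros(m, dtype=bool), 0.0
    k = int(np.flatnonzero(below)[-1]) + 1
    threshold = float(ranked[k - 1])
    reject = np.zeros(m, dtype=bool)
    reject[order[:k]] = True
    return reject.reshape(np.shape(p_values)), threshold


@dataclass
class EdgeTestResult:
    subject_id: str
    observed_diff: np.ndarray  # mean MI ATM - mean Rest ATM
    p_values: np.ndarray
    significant: np.ndarray
    n_permutations: int
    bh_threshold: float
    exhaustive: bool

    @property
    def n_regions(self) -> int:
        return self.observed_diff.shape[0]


def _label_signs(n_mi: int, n_rest: int) -> np.ndarray:
    """Contrast weights turning a (trials x edges) stack into a mean difference."""
    w = np.empty(n_mi + n_rest)
    w[:n_mi] = 1.0 / n_mi
    w[n_mi:] = -1.0 / n_rest
    return w


def subject_edge_test(
    trial_atms: TrialATMSet | np.ndarray,
    labels: np.ndarray | None = None,
    n_permutations: int = 10_000,
    alpha: float = 0.05,
    rng_seed: int | None = 0,
    exhaustive: bool | None = None,
    subject_id: str = "",
) -> EdgeTestResult:
    """Edge-wise permutation test of the MI-vs-Rest mean ATM difference.

    Trial-level ATMs are randomly re-allocated to the two conditions; the
    two-sided p-value of each edge is the rank of |observed difference| in
    the null of |permuted differences| (observed included). BH step-up at
    ``alpha`` across all edges, diagonal included.

    ``exhaustive=None`` auto-selects full enumeration when the number of
    distinct assignments C(n, n_MI) is at most ``n_permutations``.
    """
    if isinstance(trial_atms, TrialATMSet):
        usable = trial_atms.has_avalanches
        mats = trial_atms.matrices[usable]
        labels = trial_atms.condition_labels[usable]
        subject_id = subject_id or trial_atms.subject_id
    else:
        mats = np.asarray(trial_atms)
        if labels is None:
            raise ValueError("labels required when passing a raw matrix stack")
        labels = np.asarray(labels)
    labels = np.asarray(labels)
    mi = labels == "MI"
    rest = labels == "Rest"
    n_mi, n_rest = int(mi.sum()), int(rest.sum())
    if n_mi < 2 or n_rest < 2:
        raise ValueError(
            f"need >= 2 usable trials per condition; got MI={n_mi}, Rest={n_rest}"
        )
    n_regions = mats.shape[1]
    flat = np.concatenate([mats[mi], mats[rest]]).reshape(n_mi + n_rest, -1)
    w = _label_signs(n_mi, n_rest)
    observed = w @ flat

    n_total = n_mi + n_rest
    n_assign = comb(n_total, n_mi)
    use_exhaustive = n_assign <= n_permutations if exhaustive is None else exhaustive
    if use_exhaustive:
        signs = np.full((n_assign, n_total), -1.0 / n_rest)
        for row, chosen in enumerate(combinations(range(n_total), n_mi)):
            signs[row, list(chosen)] = 1.0 / n_mi
        null = np.abs(signs @ flat)
        # the observed assignment is one of the enumerated ones; the small
        # slack keeps its fp-noisy recomputation counted as a tie
        p = (null >= np.abs(observed)[None, :] - 1e-12).mean(axis=0)
        n_perm_used = n_assign
    else:
        rng = np.random.default_rng(rng_seed)
        signs = np.empty((n_permutations, n_total))
        base = w.copy()
        for row in range(n_permutations):
            signs[row] = rng.permutation(base)
        null = np.abs(signs @ flat)
        exceed = (null >= np.abs(observed)[None, :] - 1e-12).sum(axis=0)
        p = (1.0 + exceed) / (n_permutations + 1.0)
        n_perm_used = n_permutations
    significant, thr = bh_correct(p, alpha)
    return EdgeTestResult(
        subject_id=subject_id,
        observed_diff=observed.reshape(n_regions, n_regions),
        p_values=p.reshape(n_regions, n_regions),
        significant=significant.reshape(n_regions, n_regions),
        n_permutations=n_perm_used,
        bh_threshold=thr,
        exhaustive=bool(use_exhaustive),
    )


@dataclass
class ReliabilityMap:
    concordance_counts: np.ndarray  # subjects significant per edge
    p_values: np.ndarray
    reliable: np.ndarray
    n_subjects: int
    n_permutations: int
    bh_threshold: float


def group_reliability(
    edge_results: list[EdgeTestResult],
    n_permutations: int = 10_000,
    alpha: float = 0.05,
    rng_seed: int | None = 0,
) -> ReliabilityMap:
    """Group-level reliability of significant edges.

    The observed statistic is, per edge, the number of subjects in which it
    is individually significant. The null scatters each subject's significant
    edges uniformly over all R^2 positions (diagonal included), preserving
    their number, independently per subject and permutation. Per-edge
    p = P(null count >= observed), BH across edges.
    """
    if len(edge_results) < 2:
        raise ValueError("need >= 2 subjects")
    n_regions = edge_results[0].n_regions
    n_edges = n_regions * n_regions
    sig = np.stack([r.significant.ravel() for r in edge_results])  # subjects x edges
    observed = sig.sum(axis=0)

    rng = np.random.default_rng(rng_seed)
    counts = np.zeros((n_permutations, n_edges), dtype=np.int16)
    for k_s in sig.sum(axis=1):
        if k_s == 0:
            continue
        template = np.zeros(n_edges, dtype=np.int16)
        template[:k_s] = 1
        block = np.tile(template, (n_permutations, 1))
        rng.permuted(block, axis=1, out=block)
        counts += block
    exceed = (counts >= observed[None, :]).sum(axis=0)
    p = (1.0 + exceed) / (n_permutations + 1.0)
    reliable, thr = bh_correct(p, alpha)
    return ReliabilityMap(
        concordance_counts=observed.reshape(n_regions, n_regions),
        p_values=p.reshape(n_regions, n_regions),
        reliable=reliable.reshape(n_regions, n_regions),
        n_subjects=len(edge_results),
        n_permutations=n_permutations,
        bh_threshold=thr,
    )


@dataclass
class NodeResult:
    degree: np.ndarray  # incident reliable edges per region (in+out, diag once)
    p_values: np.ndarray
    significant: np.ndarray
    n_permutations: int
    bh_threshold: float


def node_concordance(
    reliable: np.ndarray,
    n_permutations: int = 10_000,
    alpha: float = 0.05,
    rng_seed: int | None = 0,
) -> NodeResult:
    """Do reliable edges cluster on specific regions?

    A region's degree counts incoming plus outgoing reliable edges, with a
    diagonal edge counted once. The null places the same number of edges
    uniformly at random over all R^2 positions. Per-region p = P(null degree
    >= observed), BH across regions.
    """
    reliable = np.asarray(reliable, dtype=bool)
    if reliable.ndim != 2 or reliable.shape[0] != reliable.shape[1]:
        raise ValueError("reliable must be a square boolean matrix")
    n_regions = reliable.shape[0]
    degree = reliable.sum(axis=0) + reliable.sum(axis=1) - np.diag(reliable)
    m = int(reliable.sum())
    if m == 0:
        p = np.ones(n_regions)
        return NodeResult(degree, p, np.zeros(n_regions, dtype=bool), n_permutations, 0.0)

    rng = np.random.default_rng(rng_seed)
    template = np.zeros(n_regions * n_regions, dtype=bool)
    template[:m] = True
    block = np.tile(template, (n_permutations, 1))
    rng.permuted(block, axis=1, out=block)
    mats = block.reshape(n_permutations, n_regions, n_regions)
    null_deg = (
        mats.sum(axis=1)
        + mats.sum(axis=2)
        - mats[:, np.arange(n_regions), np.arange(n_regions)]
    )
    exceed = (null_deg >= degree[None, :]).sum(axis=0)
    p = (1.0 + exceed) / (n_permutations + 1.0)
    significant, thr = bh_correct(p, alpha)
    return NodeResult(degree, p, significant, n_permutations, thr)


@dataclass
class HitMissResult:
    """Per-subject hit/miss contrast on a set of edges of interest."""

    subject_id: str
    statistic: np.ndarray  # per edge: |diff in hits| - |diff in misses|
    p_values: np.ndarray  # one-sided (greater), per edge on the mask
    mask: np.ndarray
    mean_statistic: float  # mean over masked edges
    p_mean: float  # one-sided p for the mean statistic
    n_permutations: int


def _hit_miss_stat(mats: np.ndarray, mi: np.ndarray, hit: np.ndarray) -> np.ndarray:
    d_hit = mats[mi & hit].mean(axis=0) - mats[~mi & hit].mean(axis=0)
    d_miss = mats[mi & ~hit].mean(axis=0) - mats[~mi & ~hit].mean(axis=0)
    return np.abs(d_hit) - np.abs(d_miss)


def hit_miss_contrast(
    trial_atms: TrialATMSet,
    edge_mask: np.ndarray | None = None,
    n_permutations: int = 10_000,
    rng_seed: int | None = 0,
) -> HitMissResult | None:
    """Is the MI-vs-Rest difference larger in hit than in miss trials?

    Statistic per edge: |mean MI - mean Rest| over hit trials minus the same
    over miss trials. The null shuffles hit/miss labels within each condition
    independently. One-sided p (greater), evaluated on ``edge_mask`` (all
    edges if None). Returns None (with a warning) if any of the four
    condition x outcome cells is empty.
    """
    if trial_atms.outcome_labels is None:
        raise ValueError("outcome labels required for the hit/miss contrast")
    usable = trial_atms.has_avalanches
    mats = trial_atms.matrices[usable]
    mi = trial_atms.condition_labels[usable] == "MI"
    hit = trial_atms.outcome_labels[usable] == "hit"
    cells = [(c, o) for c in (True, False) for o in (True, False)]
    if any(((mi == c) & (hit == o)).sum() == 0 for c, o in cells):
        warnings.warn(
            f"subject {trial_atms.subject_id}: empty condition x outcome cell; "
            "hit/miss contrast skipped",
            stacklevel=2,
        )
        return None
    n_regions = trial_atms.n_regions
    if edge_mask is None:
        edge_mask = np.ones((n_regions, n_regions), dtype=bool)
    edge_mask = np.asarray(edge_mask, dtype=bool)

    observed = _hit_miss_stat(mats, mi, hit)
    obs_masked = observed[edge_mask]
    obs_mean = float(obs_masked.mean())

    # Vectorized null: the masked statistic is |W_hit @ flat| - |W_miss @ flat|
    # for contrast weight vectors over trials; permuting hit/miss within each
    # condition permutes the weights within each condition block.
    flat = mats.reshape(mats.shape[0], -1)[:, edge_mask.ravel()]
    rng = np.random.default_rng(rng_seed)
    n = mats.shape[0]
    w_hit = np.zeros(n)
    w_miss = np.zeros(n)
    for cond_mask, sign in ((mi, 1.0), (~mi, -1.0)):
        w_hit[cond_mask & hit] = sign / (cond_mask & hit).sum()
        w_miss[cond_mask & ~hit] = sign / (cond_mask & ~hit).sum()
    perm_w_hit = np.empty((n_permutations, n))
    perm_w_miss = np.empty((n_permutations, n))
    idx_mi = np.flatnonzero(mi)
    idx_rest = np.flatnonzero(~mi)
    for row in range(n_permutations):
        for idx in (idx_mi, idx_rest):
            shuffled = idx[rng.permutation(idx.size)]
            perm_w_hit[row, shuffled] = w_hit[idx]
            perm_w_miss[row, shuffled] = w_miss[idx]
    null = np.abs(perm_w_hit @ flat) - np.abs(perm_w_miss @ flat)
    exceed = (null >= obs_masked[None, :]).sum(axis=0)
    exceed_mean = (null.mean(axis=1) >= obs_mean).sum()
    p = (1.0 + exceed) / (n_permutations + 1.0)
    p_mean = (1.0 + exceed_mean) / (n_permutations + 1.0)
    return HitMissResult(
        subject_id=trial_atms.subject_id,
        statistic=observed,
        p_values=p,
        mask=edge_mask,
        mean_statistic=obs_mean,
        p_mean=float(p_mean),
        n_permutations=n_permutations,
    )


def aggregate_hit_miss(results: list[HitMissResult | None]) -> dict:
    """Cohort summary of per-subject hit/miss contrasts: sign consistency of
    the mean statistic and the per-subject one-sided p-values."""
    kept = [r for r in results if r is not None]
    if not kept:
        raise ValueError("no subject with a computable hit/miss contrast")
    means = np.array([r.mean_statistic for r in kept])
    ps = np.array([r.p_mean for r in kept])
    return {
        "n_subjects": len(kept),
        "mean_statistic": float(means.mean()),
        "fraction_positive": float((means > 0).mean()),
        "per_subject_p": ps,
        "per_subject_mean": means,
    }


@dataclass
class AreaCorrelationResult:
    edge_correlations: np.ndarray  # regions x regions Spearman rho
    block_means: np.ndarray  # areas x areas
    block_p: np.ndarray
    significant: np.ndarray
    area_names: list[str]
    n_permutations: int
    bh_threshold: float


def _spearman_by_edge(edge_diffs: np.ndarray, scores: np.ndarray) -> np.ndarray:
    """Spearman rho of each edge's MI-Rest difference against subject scores
    (average ranks for ties)."""
    n_subjects = edge_diffs.shape[0]
    flat = edge_diffs.reshape(n_subjects, -1)
    r_edges = rankdata(flat, axis=0)
    r_scores = rankdata(scores)
    re_c = r_edges - r_edges.mean(axis=0)
    rs_c = r_scores - r_scores.mean()
    denom = np.sqrt((re_c**2).sum(axis=0) * (rs_c**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = np.where(denom > 0, (re_c * rs_c[:, None]).sum(axis=0) / denom, 0.0)
    return rho.reshape(edge_diffs.shape[1:])


def bci_correlation(
    edge_diffs: np.ndarray,
    bci_scores: np.ndarray,
    area_labels: np.ndarray,
    n_permutations: int = 10_000,
    alpha: float = 0.05,
    rng_seed: int | None = 0,
) -> AreaCorrelationResult:
    """Functional-area-level correlation between condition differences and
    BCI performance.

    Per edge, the Spearman correlation across subjects between the MI-Rest
    ATM difference and the BCI score; coefficients are averaged within each
    directed area-pair block (self-connections included). The null permutes
    the edge -> block assignment of the coefficients; per-block two-sided p,
    BH across the area_count^2 blocks.

    edge_diffs: (n_subjects, R, R); area_labels: length-R array of area names.
    """
    edge_diffs = np.asarray(edge_diffs, dtype=float)
    bci_scores = np.asarray(bci_scores, dtype=float)
    if edge_diffs.ndim != 3 or edge_diffs.shape[0] != bci_scores.size:
        raise ValueError("edge_diffs must be (n_subjects, R, R) matching bci_scores")
    if bci_scores.size < 4:
        raise ValueError("need >= 4 subjects for a rank correlation")
    if np.ptp(bci_scores) == 0:
        raise ValueError("BCI scores are constant; correlation undefined")
    area_labels = np.asarray(area_labels)
    n_regions = edge_diffs.shape[1]
    if area_labels.size != n_regions:
        raise ValueError("area_labels length must match region count")

    rho = _spearman_by_edge(edge_diffs, bci_scores)
    area_names = sorted(set(area_labels.tolist()))
    n_areas = len(area_names)
    area_idx = np.array([area_names.index(a) for a in area_labels])
    block_of_edge = (area_idx[:, None] * n_areas + area_idx[None, :]).ravel()
    block_counts = np.bincount(block_of_edge, minlength=n_areas * n_areas)
    rho_flat = rho.ravel()
    block_sums = np.bincount(block_of_edge, weights=rho_flat, minlength=n_areas * n_areas)
    with np.errstate(invalid="ignore"):
        observed = np.where(block_counts > 0, block_sums / np.maximum(block_counts, 1), np.nan)

    rng = np.random.default_rng(rng_seed)
    exceed = np.zeros(n_areas * n_areas)
    for _ in range(n_permutations):
        perm = rng.permutation(rho_flat)
        sums = np.bincount(block_of_edge, weights=perm, minlength=n_areas * n_areas)
        null = sums / np.maximum(block_counts, 1)
        exceed += np.abs(null) >= np.abs(observed)
    p = (1.0 + exceed) / (n_permutations + 1.0)
    significant, thr = bh_correct(p, alpha)
    return AreaCorrelationResult(
        edge_correlations=rho,
        block_means=observed.reshape(n_areas, n_areas),
        block_p=p.reshape(n_areas, n_areas),
        significant=significant.reshape(n_areas, n_areas),
        area_names=area_names,
        n_permutations=n_permutations,
        bh_threshold=thr,
    )
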