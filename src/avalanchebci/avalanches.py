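"""Avalanche extraction and transition-matrix estimation.

Implements the core measurement chain for large-scale neuronal avalanches:
per-trial z-scoring and thresholding of source-level signals, OR-binning,
segmentation of avalanches (maximal runs of bins with at least one active
region), estimation of avalanche transition matrices (ATMs, directed
conditional activation probabilities with a meaningful diagonal), and the
branching-ratio estimator

    sigma_i = prod_{j=1}^{Nbin-1} (n_events(j+1) / n_events(j)) ** (1/(Nbin-1))
    sigma   = prod_{i=1}^{Naval} sigma_i ** (1/Naval)

whose value near 1 indicates near-critical cascade dynamics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

CONDITIONS = ("MI", "Rest")
OUTCOMES = ("hit", "miss")

__all__ = [
    "EpochedSourceData",
    "BinaryRaster",
    "Avalanche",
    "TransitionMatrix",
    "BranchingEstimate",
    "TrialATMSet",
    "binarize",
    "segment_avalanches",
    "transition_matrix",
    "average_atm",
    "branching_ratio",
    "extract_trial_atms",
]


class ZeroVarianceError(ValueError):
    """A region has constant signal within a trial; its z-score is undefined."""


@dataclass
class EpochedSourceData:
    """Epoched multi-region source-level time series for one subject.

    signals has shape (n_trials, n_regions, n_samples). Condition labels are
    'MI' (motor imagery) or 'Rest'; optional outcome labels are 'hit'/'miss'.
    """

    subject_id: str
    signals: np.ndarray
    sampling_rate_hz: float
    condition_labels: np.ndarray
    outcome_labels: np.ndarray | None = None
    region_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.signals = np.asarray(self.signals)
        if self.signals.ndim != 3:
            raise ValueError(
                f"signals must be (trials, regions, samples); got shape {self.signals.shape}"
            )
        if not np.all(np.isfinite(self.signals)):
            raise ValueError("signals contain non-finite samples")
        self.condition_labels = np.asarray(self.condition_labels)
        n = self.n_trials
        if len(self.condition_labels) != n:
            raise ValueError(
                f"{len(self.condition_labels)} condition labels for {n} trials"
            )
        bad = set(self.condition_labels) - set(CONDITIONS)
        if bad:
            raise ValueError(f"unknown condition labels {sorted(bad)}; allowed: {CONDITIONS}")
        if self.outcome_labels is not None:
            self.outcome_labels = np.asarray(self.outcome_labels)
            if len(self.outcome_labels) != n:
                raise ValueError(
                    f"{len(self.outcome_labels)} outcome labels for {n} trials"
                )
            bad = set(self.outcome_labels) - set(OUTCOMES)
            if bad:
                raise ValueError(f"unknown outcome labels {sorted(bad)}; allowed: {OUTCOMES}")
        if self.region_names is not None and len(self.region_names) != self.n_regions:
            raise ValueError("region_names length does not match region count")

    @property
    def n_trials(self) -> int:
        return self.signals.shape[0]

    @property
    def n_regions(self) -> int:
        return self.signals.shape[1]

    @property
    def n_samples(self) -> int:
        return self.signals.shape[2]


@dataclass
class BinaryRaster:
    """Thresholded, binned activation raster: (trials, regions, bins) boolean."""

    active: np.ndarray
    threshold_z: float
    bin_length_samples: int

    def __post_init__(self) -> None:
        self.active = np.asarray(self.active)
        if self.active.ndim != 3 or self.active.dtype != bool:
            raise ValueError("active must be a 3-d boolean array (trials, regions, bins)")

    @property
    def n_trials(self) -> int:
        return self.active.shape[0]

    @property
    def n_regions(self) -> int:
        return self.active.shape[1]

    @property
    def n_bins(self) -> int:
        return self.active.shape[2]


@dataclass
class Avalanche:
    """One avalanche: a maximal run of bins with at least one active region."""

    trial_index: int
    start_bin: int
    end_bin: int  # inclusive
    active_sets: list[np.ndarray]  # per-bin sorted region indices
    truncated_start: bool = False
    truncated_end: bool = False
    size: int = field(init=False)
    duration_bins: int = field(init=False)
    n_events_per_bin: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.duration_bins = self.end_bin - self.start_bin + 1
        if len(self.active_sets) != self.duration_bins:
            raise ValueError("active_sets length must equal duration")
        self.n_events_per_bin = np.array([len(s) for s in self.active_sets])
        if (self.n_events_per_bin == 0).any():
            raise ValueError("every bin of an avalanche must have at least one active region")
        self.size = int(self.n_events_per_bin.sum())


@dataclass
class TransitionMatrix:
    """Directed region-to-region conditional activation probabilities.

    Entry (i, j): probability that region j is active one bin after region i
    was active, estimated within avalanches. The diagonal is the
    self-persistence probability. Rows whose source region never has a
    successor frame are all zero.
    """

    probabilities: np.ndarray
    n_avalanches_averaged: int
    scope: str = "avalanche"  # one of {"avalanche", "trial", "condition"}

    def __post_init__(self) -> None:
        p = np.asarray(self.probabilities, dtype=float)
        if p.ndim != 2 or p.shape[0] != p.shape[1]:
            raise ValueError("probabilities must be a square matrix")
        if p.size and (p.min() < -1e-12 or p.max() > 1 + 1e-12):
            raise ValueError("transition probabilities must lie in [0, 1]")
        self.probabilities = p

    @property
    def n_regions(self) -> int:
        return self.probabilities.shape[0]


@dataclass
class BranchingEstimate:
    """Branching-ratio estimate: geometric mean over bins and avalanches."""

    sigma: float
    per_avalanche_sigmas: np.ndarray
    n_avalanches_used: int
    n_single_bin_excluded: int
    bin_length_samples: int | None = None


def binarize(
    data: EpochedSourceData,
    threshold_z: float = 3.0,
    bin_length_samples: int = 1,
) -> BinaryRaster:
    """Z-score per region over time (within each trial), threshold at |z| >
    threshold_z, and OR samples into bins of ``bin_length_samples``.

    A trailing partial bin is discarded. Raises :class:`ZeroVarianceError`
    naming the first offending (trial, region) if any region is constant
    within a trial.
    """
    if threshold_z <= 0:
        raise ValueError("threshold_z must be positive")
    if bin_length_samples not in (1, 2, 3):
        raise ValueError("bin_length_samples must be 1, 2 or 3")
    x = data.signals
    if not np.issubdtype(x.dtype, np.floating):
        x = x.astype(float)
    mean = x.mean(axis=2, keepdims=True)
    sd = x.std(axis=2, keepdims=True)
    zero = x.max(axis=2) == x.min(axis=2)  # constant signal, robust to fp noise
    if zero.any():
        t, r = np.argwhere(zero)[0]
        raise ZeroVarianceError(
            f"region {r} has zero variance in trial {t}; z-score undefined"
        )
    z = (x - mean) / sd
    active = np.abs(z) > threshold_z
    n_bins = data.n_samples // bin_length_samples
    if n_bins < 1:
        raise ValueError("fewer samples than one bin")
    active = active[:, :, : n_bins * bin_length_samples]
    active = active.reshape(data.n_trials, data.n_regions, n_bins, bin_length_samples)
    return BinaryRaster(
        active=active.any(axis=3),
        threshold_z=float(threshold_z),
        bin_length_samples=int(bin_length_samples),
    )


def segment_avalanches(raster: BinaryRaster) -> list[Avalanche]:
    """Segment avalanches as maximal runs of bins with >= 1 active region.

    Trials are independent; avalanches touching a trial boundary are kept and
    flagged truncated on that side.
    """
    avalanches: list[Avalanche] = []
    n_bins = raster.n_bins
    for trial in range(raster.n_trials):
        act = raster.active[trial]  # regions x bins
        any_active = act.any(axis=0)
        edges = np.flatnonzero(np.diff(np.concatenate(([0], any_active.view(np.int8), [0]))))
        for start, stop in zip(edges[::2], edges[1::2]):
            sets = [np.flatnonzero(act[:, b]) for b in range(start, stop)]
            avalanches.append(
                Avalanche(
                    trial_index=trial,
                    start_bin=int(start),
                    end_bin=int(stop - 1),
                    active_sets=sets,
                    truncated_start=start == 0,
                    truncated_end=stop == n_bins,
                )
            )
    return avalanches


def transition_counts(avalanche: Avalanche, n_regions: int) -> tuple[np.ndarray, np.ndarray]:
    """Raw transition counts: numerator (i, j) = frames with i active at t and
    j active at t+1; denominator (i,) = frames with i active at t < end."""
    num = np.zeros((n_regions, n_regions))
    den = np.zeros(n_regions)
    sets = avalanche.active_sets
    for src, dst in zip(sets[:-1], sets[1:]):
        num[np.ix_(src, dst)] += 1.0
        den[src] += 1.0
    return num, den


def transition_matrix(avalanche: Avalanche, n_regions: int) -> TransitionMatrix | None:
    """Per-avalanche ATM. Entry (i, j) = P(j active at t+1 | i active at t),
    counted over the avalanche's frames; the diagonal (self-persistence) is
    computed identically. Rows with no successor frame are zero.

    Single-bin avalanches have no transitions; returns None (logged).
    """
    if avalanche.duration_bins < 2:
        logger.debug(
            "avalanche at trial %d bin %d has a single bin; no transition matrix",
            avalanche.trial_index,
            avalanche.start_bin,
        )
        return None
    num, den = transition_counts(avalanche, n_regions)
    probs = np.divide(num, den[:, None], out=np.zeros_like(num), where=den[:, None] > 0)
    return TransitionMatrix(probabilities=probs, n_avalanches_averaged=1, scope="avalanche")


def average_atm(atms: list[TransitionMatrix], scope: str = "trial") -> TransitionMatrix:
    """Arithmetic, edge-wise mean over per-avalanche transition matrices."""
    atms = [a for a in atms if a is not None]
    if not atms:
        raise ValueError("cannot average an empty list of transition matrices")
    stack = np.stack([a.probabilities for a in atms])
    n = int(sum(a.n_avalanches_averaged for a in atms))
    return TransitionMatrix(probabilities=stack.mean(axis=0), n_avalanches_averaged=n, scope=scope)


def pooled_atm(avalanches: list[Avalanche], n_regions: int, scope: str = "trial") -> TransitionMatrix:
    """Alternative estimator: pool transition counts across avalanches before
    normalizing (instead of averaging per-avalanche probabilities)."""
    multi = [a for a in avalanches if a.duration_bins >= 2]
    if not multi:
        raise ValueError("no multi-bin avalanche to pool")
    num = np.zeros((n_regions, n_regions))
    den = np.zeros(n_regions)
    for av in multi:
        a_num, a_den = transition_counts(av, n_regions)
        num += a_num
        den += a_den
    probs = np.divide(num, den[:, None], out=np.zeros_like(num), where=den[:, None] > 0)
    return TransitionMatrix(probabilities=probs, n_avalanches_averaged=len(multi), scope=scope)


def branching_ratio(avalanches: list[Avalanche]) -> BranchingEstimate:
    """Branching ratio: per-avalanche geometric mean of successive event-count
    ratios, geometrically averaged over avalanches. Single-bin avalanches
    carry no ratio and are excluded (their count is reported)."""
    multi = [a for a in avalanches if a.duration_bins >= 2]
    n_single = len(avalanches) - len(multi)
    if not multi:
        raise ValueError("no avalanche with >= 2 bins; branching ratio undefined")
    sigmas = np.empty(len(multi))
    for k, av in enumerate(multi):
        n = av.n_events_per_bin.astype(float)
        ratios = n[1:] / n[:-1]
        sigmas[k] = np.exp(np.log(ratios).mean())
    sigma = float(np.exp(np.log(sigmas).mean()))
    return BranchingEstimate(
        sigma=sigma,
        per_avalanche_sigmas=sigmas,
        n_avalanches_used=len(multi),
        n_single_bin_excluded=n_single,
    )


@dataclass
class TrialATMSet:
    """Per-trial ATMs for one subject plus per-condition averages.

    matrices has shape (n_trials, n_regions, n_regions); trials without any
    multi-bin avalanche have all-zero matrices and has_avalanches False, and
    are excluded from condition averages.
    """

    subject_id: str
    matrices: np.ndarray
    has_avalanches: np.ndarray
    condition_labels: np.ndarray
    outcome_labels: np.ndarray | None
    threshold_z: float
    bin_length_samples: int
    n_avalanches_per_trial: np.ndarray

    @property
    def n_regions(self) -> int:
        return self.matrices.shape[1]

    def condition_average(self, condition: str) -> TransitionMatrix:
        mask = (self.condition_labels == condition) & self.has_avalanches
        if not mask.any():
            raise ValueError(f"no usable trial for condition {condition!r}")
        return TransitionMatrix(
            probabilities=self.matrices[mask].mean(axis=0),
            n_avalanches_averaged=int(self.n_avalanches_per_trial[mask].sum()),
            scope="condition",
        )


def _trial_atm_fast(act: np.ndarray, pooled: bool) -> tuple[np.ndarray | None, int]:
    """Trial-level ATM straight from the boolean raster (regions x bins).

    Same estimator as segment_avalanches + transition_matrix + average_atm /
    pooled_atm, without per-avalanche object construction (used on full-size
    cohorts; equivalence with the object route is test-covered)."""
    n_regions = act.shape[0]
    any_active = act.any(axis=0)
    edges = np.flatnonzero(np.diff(np.concatenate(([0], any_active.view(np.int8), [0]))))
    acc = np.zeros((n_regions, n_regions))
    den_acc = np.zeros(n_regions) if pooled else None
    n_multi = 0
    for start, stop in zip(edges[::2], edges[1::2]):
        if stop - start < 2:
            continue
        seg = act[:, start:stop].astype(np.float64)
        num = seg[:, :-1] @ seg[:, 1:].T
        den = seg[:, :-1].sum(axis=1)
        n_multi += 1
        if pooled:
            acc += num
            den_acc += den
        else:
            acc += np.divide(num, den[:, None], out=num, where=den[:, None] > 0)
    if n_multi == 0:
        return None, 0
    if pooled:
        probs = np.divide(acc, den_acc[:, None], out=np.zeros_like(acc), where=den_acc[:, None] > 0)
    else:
        probs = acc / n_multi
    return probs, n_multi


def extract_trial_atms(
    data: EpochedSourceData,
    threshold_z: float = 3.0,
    bin_length_samples: int = 1,
    pooled: bool = True,
) -> TrialATMSet:
    """Full measurement chain: binarize -> segment -> transition estimation
    within each trial.

    By default transition counts are pooled across a trial's avalanches
    before normalizing: the estimand is a conditional activation
    probability, and pooling frames is its direct estimate. ``pooled=False``
    instead averages per-avalanche probability matrices edge-wise (with
    zero-filled undefined rows), which conflates an edge's transmission
    probability with its source's avalanche-participation rate and is
    noticeably noisier; it is kept for comparability.
    """
    raster = binarize(data, threshold_z=threshold_z, bin_length_samples=bin_length_samples)
    n_trials, n_regions = data.n_trials, data.n_regions
    matrices = np.zeros((n_trials, n_regions, n_regions))
    has = np.zeros(n_trials, dtype=bool)
    n_aval = np.zeros(n_trials, dtype=int)
    for trial in range(n_trials):
        probs, n_multi = _trial_atm_fast(raster.active[trial], pooled)
        n_aval[trial] = n_multi
        if probs is None:
            continue
        matrices[trial] = probs
        has[trial] = True
    n_empty = int((~has).sum())
    if n_empty:
        logger.warning(
            "subject %s: %d/%d trials have no multi-bin avalanche and are "
            "excluded from condition averages",
            data.subject_id,
            n_empty,
            n_trials,
        )
    return TrialATMSet(
        subject_id=data.subject_id,
        matrices=matrices,
        has_avalanches=has,
        condition_labels=data.condition_labels.copy(),
        outcome_labels=None if data.outcome_labels is None else data.outcome_labels.copy(),
        threshold_z=float(threshold_z),
        bin_length_samples=int(bin_length_samples),
        n_avalanches_per_trial=n_aval,
    )
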