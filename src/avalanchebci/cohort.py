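"""Synthetic cohort generator: cascade activity with planted condition effects.

Real source-reconstructed M/EEG recordings for this kind of study (20
subjects, 68-region Desikan parcellation, 7-s epochs) are rarely shareable,
so this module generates cohorts with known ground truth instead:

* a branching process on a directed graph — each active region triggers each
  downstream region independently per bin, so the avalanche-transition-matrix
  estimand (conditional activation probability) is analytically known;
* a set of planted edges whose propagation probability is multiplied by
  ``effect_size`` during motor imagery (MI) relative to rest;
* miss trials attenuate the MI-rest *difference* by ``miss_attenuation``
  (miss trials interpolate between the two conditions);
* per-subject BCI scores that are a logistic function of the subject's
  realized planted effect plus seeded Gaussian noise;
* continuous signals built by planting super-threshold deflections on a
  Gaussian background, constructed so that re-binarization at the matching
  threshold recovers the planted raster bit-exactly on planted cells.

Everything is reproducible from (spec, ground truth, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .avalanches import CONDITIONS, OUTCOMES, EpochedSourceData

__all__ = [
    "GroundTruth",
    "CohortSpec",
    "SyntheticCohort",
    "make_ground_truth",
    "desikan_region_names",
    "simulate_cascades",
    "simulate_cascade_batch",
    "embed_signals",
    "make_cohort",
    "iter_subjects",
]

#: Mean per-region per-bin initiation probability and the fraction of
#: "excitable" bins over which initiations are concentrated. Initiations come
#: from a common bursty drive — a bin is excitable with probability
#: ``burst_bin_fraction``, and only then each region initiates independently —
#: so avalanches can start with several co-active regions, as stimulus-driven
#: perturbations do. The pair is calibrated (at the 68-region default
#: geometry) so the branching-ratio estimator, which conditions on avalanche
#: shape, reads sigma_target on the critical process: purely singleton starts
#: force per-avalanche ratios >= 1 and bias it upward, while strongly
#: clustered starts bias it downward.
DEFAULT_SPONTANEOUS_RATE = 1.235e-3
DEFAULT_BURST_BIN_FRACTION = 0.14

#: Slope of the logistic link between realized planted effect and BCI score.
BCI_SCORE_SLOPE = 1.5
BCI_SCORE_NOISE_SD = 0.05


class RasterTooDenseError(ValueError):
    """The raster is too dense for its cells to survive z-scoring above threshold."""


@dataclass
class GroundTruth:
    """Generating parameters of the cascade process.

    weights_rest / weights_mi are regions x regions propagation probabilities
    (entry (i, j): probability that region i active at bin t triggers region j
    at bin t+1). The condition effect is confined to the source rows of
    ``planted_edges``: planted entries are strengthened during MI and the
    rest of those rows renormalized (propagation rerouted, not added).
    """

    weights_rest: np.ndarray
    weights_mi: np.ndarray
    planted_edges: np.ndarray  # (k, 2) int pairs (i, j)
    effect_size: float
    miss_attenuation: float
    spontaneous_rate: float = DEFAULT_SPONTANEOUS_RATE
    burst_bin_fraction: float = DEFAULT_BURST_BIN_FRACTION
    sigma_target: float | None = None

    def __post_init__(self) -> None:
        self.weights_rest = np.asarray(self.weights_rest, dtype=float)
        self.weights_mi = np.asarray(self.weights_mi, dtype=float)
        if self.weights_rest.shape != self.weights_mi.shape or self.weights_rest.ndim != 2:
            raise ValueError("weight matrices must be square and share a shape")
        for name, w in (("weights_rest", self.weights_rest), ("weights_mi", self.weights_mi)):
            if w.min() < 0 or w.max() > 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if not 0 <= self.miss_attenuation <= 1:
            raise ValueError("miss_attenuation must lie in [0, 1]")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if not 0 <= self.spontaneous_rate <= 1:
            raise ValueError("spontaneous_rate must lie in [0, 1]")
        if not 0 < self.burst_bin_fraction <= 1:
            raise ValueError("burst_bin_fraction must lie in (0, 1]")
        if self.spontaneous_rate / self.burst_bin_fraction > 1:
            raise ValueError("spontaneous_rate / burst_bin_fraction exceeds 1")
        self.planted_edges = np.asarray(self.planted_edges, dtype=int).reshape(-1, 2)
        # the condition effect (planted strengthening plus the row
        # renormalization it implies) is confined to planted source rows
        diff_rows = set(np.nonzero((self.weights_rest != self.weights_mi).any(axis=1))[0])
        if not diff_rows <= set(self.planted_edges[:, 0].tolist()):
            raise ValueError("weights differ outside planted source rows")

    @property
    def n_regions(self) -> int:
        return self.weights_rest.shape[0]

    def weights_for(self, condition: str, outcome: str | None = None) -> np.ndarray:
        """Condition/outcome-appropriate propagation matrix.

        Rest trials use the rest weights regardless of outcome. MI hit trials
        use the full MI weights; MI miss trials attenuate the MI-rest
        difference by ``miss_attenuation``.
        """
        if condition not in CONDITIONS:
            raise ValueError(f"unknown condition {condition!r}; allowed: {CONDITIONS}")
        if outcome is not None and outcome not in OUTCOMES:
            raise ValueError(f"unknown outcome {outcome!r}; allowed: {OUTCOMES}")
        if condition == "Rest":
            return self.weights_rest
        if outcome == "miss":
            return self.weights_rest + self.miss_attenuation * (
                self.weights_mi - self.weights_rest
            )
        return self.weights_mi


@dataclass
class CohortSpec:
    """Cohort geometry mirroring the study design: 20 subjects, 68 regions,
    7-s epochs at 250 Hz, 48 trials per condition."""

    n_subjects: int = 20
    n_trials_per_condition: int = 48
    n_regions: int = 68
    trial_duration_s: float = 7.0
    sampling_rate_hz: float = 250.0
    hit_rate: float = 0.7
    subject_variability: float = 0.1
    effect_variability: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_subjects", "n_trials_per_condition", "n_regions"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.trial_duration_s <= 0 or self.sampling_rate_hz <= 0:
            raise ValueError("trial duration and sampling rate must be positive")
        if not 0 <= self.hit_rate <= 1:
            raise ValueError("hit_rate must lie in [0, 1]")
        if self.subject_variability < 0:
            raise ValueError("subject_variability must be >= 0")
        if self.effect_variability < 0:
            raise ValueError("effect_variability must be >= 0")

    @property
    def n_samples(self) -> int:
        return int(round(self.trial_duration_s * self.sampling_rate_hz))

    @property
    def n_trials(self) -> int:
        return 2 * self.n_trials_per_condition

    def small(self, **overrides) -> "CohortSpec":
        """Fast-test profile: 19 regions, 2-s trials."""
        base = replace(self, n_regions=19, trial_duration_s=2.0)
        return replace(base, **overrides)


@dataclass
class SubjectRecord:
    data: EpochedSourceData
    bci_score: float
    weights_rest: np.ndarray
    weights_mi: np.ndarray
    realized_effect: float


@dataclass
class SyntheticCohort:
    spec: CohortSpec
    ground_truth: GroundTruth
    subjects: list[SubjectRecord] = field(default_factory=list)

    @property
    def bci_scores(self) -> np.ndarray:
        return np.array([s.bci_score for s in self.subjects])


#: Rest-state propagation probability on planted edges. Planted edges model
#: strong structural pathways (avalanches spread preferentially along
#: white-matter bundles, and the premotor-parietal pathway is such a bundle);
#: the task then modulates an already-existing route rather than conjuring
#: probability mass out of the diffuse background.
DEFAULT_PLANTED_BASELINE = 0.08


def _default_planted_edges(region_names: list[str]) -> np.ndarray:
    """Premotor -> parietal pathway edges from the bundled Desikan-68 map:
    bilateral caudal middle frontal / precentral sources onto bilateral
    superior/inferior parietal and left precuneus targets."""
    sources = [
        "lh_caudalmiddlefrontal",
        "rh_caudalmiddlefrontal",
        "lh_precentral",
        "rh_precentral",
    ]
    targets = [
        "lh_superiorparietal",
        "rh_superiorparietal",
        "lh_inferiorparietal",
        "rh_inferiorparietal",
        "lh_precuneus",
    ]
    index = {name: k for k, name in enumerate(region_names)}
    return np.array([(index[s], index[t]) for s in sources for t in targets])


def desikan_region_names() -> list[str]:
    """Region names of the bundled 68-region Desikan map, in row order."""
    import csv
    from importlib import resources

    ref = resources.files("avalanchebci.data") / "desikan_areas.csv"
    with ref.open() as fh:
        rows = [r for r in csv.reader(fh) if r and not r[0].startswith("#")]
    return [r[0] for r in rows[1:]]


def make_ground_truth(
    n_regions: int = 68,
    sigma_target: float = 1.0,
    effect_size: float = 2.0,
    miss_attenuation: float = 0.5,
    spontaneous_rate: float = DEFAULT_SPONTANEOUS_RATE,
    burst_bin_fraction: float = DEFAULT_BURST_BIN_FRACTION,
    planted_edges: np.ndarray | None = None,
    planted_baseline: float = DEFAULT_PLANTED_BASELINE,
    n_planted: int = 20,
    seed: int = 0,
) -> GroundTruth:
    """Build a ground truth whose every source row has mean offspring count
    ``sigma_target`` (the branching ratio of the cascade process).

    Planted edges carry a strong baseline probability ``planted_baseline`` at
    rest (a structural pathway); the remaining weights of those source rows
    are scaled down so the row sum stays at sigma_target. During MI the
    planted probability is multiplied by ``effect_size`` and the row is
    renormalized again: the task *reroutes* propagation through the pathway
    instead of adding activity, so global dynamics (and the branching ratio)
    stay matched across conditions. Consequently the diffuse entries of
    planted source rows also differ slightly between conditions; the
    condition effect is confined to planted source rows.

    For the default 68-region geometry the planted edges are the
    premotor -> parietal pathway of the bundled area map; otherwise
    ``n_planted`` off-diagonal edges are drawn uniformly (seeded).
    """
    w0 = sigma_target / n_regions
    if not 0 <= w0 <= 1:
        raise ValueError("sigma_target / n_regions must be a probability")
    weights_rest = np.full((n_regions, n_regions), w0)
    if planted_edges is None:
        if n_regions == 68:
            planted_edges = _default_planted_edges(desikan_region_names())
        else:
            rng = np.random.default_rng(seed)
            off_diag = [(i, j) for i in range(n_regions) for j in range(n_regions) if i != j]
            idx = rng.choice(len(off_diag), size=min(n_planted, len(off_diag)), replace=False)
            planted_edges = np.array([off_diag[k] for k in idx])
    planted_edges = np.asarray(planted_edges, dtype=int).reshape(-1, 2)

    weights_mi = weights_rest.copy()
    if planted_edges.size:
        if not 0 <= planted_baseline <= 1:
            raise ValueError("planted_baseline must lie in [0, 1]")
        rows, counts = np.unique(planted_edges[:, 0], return_counts=True)
        for row, k in zip(rows, counts):
            for w, b in ((weights_rest, planted_baseline),
                         (weights_mi, min(planted_baseline * effect_size, 1.0))):
                if k * b >= sigma_target:
                    raise ValueError(
                        f"source row {row}: {k} planted edges at probability {b} "
                        f"exceed sigma_target {sigma_target}; lower planted_baseline "
                        f"or effect_size"
                    )
                w[row] = (sigma_target - k * b) / (n_regions - k)
        weights_rest[planted_edges[:, 0], planted_edges[:, 1]] = planted_baseline
        weights_mi[planted_edges[:, 0], planted_edges[:, 1]] = min(
            planted_baseline * effect_size, 1.0
        )
    return GroundTruth(
        weights_rest=weights_rest,
        weights_mi=weights_mi,
        planted_edges=planted_edges,
        effect_size=effect_size,
        miss_attenuation=miss_attenuation,
        spontaneous_rate=spontaneous_rate,
        burst_bin_fraction=burst_bin_fraction,
        sigma_target=sigma_target,
    )


def _simulate_batch(
    weights: np.ndarray,
    spontaneous_rate: float,
    burst_bin_fraction: float,
    n_trials: int,
    n_bins: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Simulate ``n_trials`` independent cascade rasters (trials, regions, bins).

    Each active region i at bin t triggers region j at bin t+1 with
    probability weights[i, j], independently across edges. Spontaneous
    initiations occur at a mean rate of ``spontaneous_rate`` per region per
    bin, concentrated in "excitable" bins (common bursty drive): a bin is
    excitable with probability ``burst_bin_fraction`` and only then regions
    initiate, each with probability spontaneous_rate / burst_bin_fraction.
    Initiations also occur inside ongoing avalanches and at trial edges, so
    merged and truncated cascades occur, as in real epoched data.
    """
    n_regions = weights.shape[0]
    log_miss = np.log1p(-np.clip(weights, 0.0, 1.0 - 1e-12))
    hot_rate = min(spontaneous_rate / burst_bin_fraction, 1.0)
    raster = np.zeros((n_trials, n_regions, n_bins), dtype=bool)
    active = np.zeros((n_trials, n_regions))
    for t in range(n_bins):
        hot = rng.random(n_trials) < burst_bin_fraction
        keep_silent = np.where(hot, 1.0 - hot_rate, 1.0)[:, None]
        p_quiet = np.exp(active @ log_miss) * keep_silent
        active = (rng.random((n_trials, n_regions)) >= p_quiet).astype(float)
        raster[:, :, t] = active.astype(bool)
    return raster


def simulate_cascades(
    gt: GroundTruth,
    condition: str,
    outcome: str | None,
    n_bins: int,
    rng_seed: int,
) -> np.ndarray:
    """One cascade raster (regions x bins) for the given condition/outcome."""
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    weights = gt.weights_for(condition, outcome)
    rng = np.random.default_rng(rng_seed)
    return _simulate_batch(
        weights, gt.spontaneous_rate, gt.burst_bin_fraction, 1, n_bins, rng
    )[0]


def simulate_cascade_batch(
    gt: GroundTruth,
    condition: str,
    outcome: str | None,
    n_trials: int,
    n_bins: int,
    rng_seed: int,
) -> np.ndarray:
    """Independent cascade rasters (trials x regions x bins) for one
    condition/outcome; the vectorized sibling of :func:`simulate_cascades`."""
    if n_trials < 1 or n_bins < 1:
        raise ValueError("n_trials and n_bins must be >= 1")
    weights = gt.weights_for(condition, outcome)
    rng = np.random.default_rng(rng_seed)
    return _simulate_batch(
        weights, gt.spontaneous_rate, gt.burst_bin_fraction, n_trials, n_bins, rng
    )


def embed_signals(
    raster: np.ndarray,
    noise_sd: float = 1.0,
    threshold_z: float = 3.0,
    rng_seed: int | np.random.Generator = 0,
    bin_length_samples: int = 1,
    n_samples: int | None = None,
    margin: float = 1.5,
) -> np.ndarray:
    """Embed a binary raster (regions x bins) into continuous signals
    (regions x samples).

    Background samples are iid Gaussian noise; every sample of an active bin
    is set to a per-region deflection value chosen, from the realized noise
    moments, so that after per-region z-scoring over time the active samples
    sit at exactly ``c`` z-units with threshold_z < c <= margin * threshold_z.
    Re-binarizing with the same threshold and bin length therefore recovers
    the planted raster exactly on planted cells (background samples may add
    chance crossings at the 2*(1-Phi(threshold)) rate).
    """
    raster = np.asarray(raster, dtype=bool)
    if raster.ndim != 2:
        raise ValueError("raster must be (regions, bins)")
    if threshold_z <= 0:
        raise ValueError("threshold_z must be positive")
    n_regions, n_bins = raster.shape
    if n_samples is None:
        n_samples = n_bins * bin_length_samples
    if n_samples != n_bins * bin_length_samples:
        raise ValueError(
            f"geometry mismatch: {n_bins} bins x {bin_length_samples} samples/bin "
            f"!= {n_samples} samples"
        )
    rng = (
        rng_seed
        if isinstance(rng_seed, np.random.Generator)
        else np.random.default_rng(rng_seed)
    )
    signals = rng.normal(0.0, noise_sd, size=(n_regions, n_samples))
    sample_mask = np.repeat(raster, bin_length_samples, axis=1)
    for r in range(n_regions):
        mask = sample_mask[r]
        f = mask.mean()
        if f == 0:
            continue
        if f == 1:
            raise RasterTooDenseError(
                f"region {r} is active in every bin; z-scoring would erase it"
            )
        quiet = signals[r, ~mask]
        m0, v0 = quiet.mean(), quiet.var()
        c_max = np.sqrt((1 - f) / f)
        c = min(margin * threshold_z, 0.97 * c_max)
        if c <= threshold_z * (1 + 1e-9):
            raise RasterTooDenseError(
                f"region {r}: active fraction {f:.3f} caps the reachable z at "
                f"{c_max:.2f} <= threshold {threshold_z}"
            )
        d = c * np.sqrt((1 - f) * v0 / (1 - c**2 * f / (1 - f)))
        signals[r, mask] = m0 + d / (1 - f)
    return signals


def _bci_score(realized_effect: float, baseline_weight: float, rng: np.random.Generator) -> float:
    """Logistic link from realized planted effect (mean MI-rest weight
    difference, relative to the rest weight) to a BCI score in [0, 1]."""
    from scipy.special import expit

    rel = realized_effect / baseline_weight if baseline_weight > 0 else 0.0
    score = expit(BCI_SCORE_SLOPE * rel) + rng.normal(0.0, BCI_SCORE_NOISE_SD)
    return float(np.clip(score, 0.0, 1.0))


def _make_subject(
    spec: CohortSpec,
    gt: GroundTruth,
    subject_index: int,
    seed_seq: np.random.SeedSequence,
) -> SubjectRecord:
    rng = np.random.default_rng(seed_seq)
    n_regions = gt.n_regions
    if n_regions != spec.n_regions:
        raise ValueError("ground truth and cohort spec disagree on region count")

    # Multiplicative log-normal jitter, shared between conditions so the
    # MI-rest difference stays confined to planted edges; a per-subject
    # "skill" factor scales the planted MI-rest delta, so subjects differ in
    # how strongly the task modulates the pathway.
    jitter = np.exp(rng.normal(0.0, spec.subject_variability, size=(n_regions, n_regions)))
    skill = float(np.exp(rng.normal(0.0, spec.effect_variability)))
    w_rest = np.clip(gt.weights_rest * jitter, 0.0, 1.0)
    w_mi = np.clip(w_rest + skill * jitter * (gt.weights_mi - gt.weights_rest), 0.0, 1.0)
    subject_gt = GroundTruth(
        weights_rest=w_rest,
        weights_mi=w_mi,
        planted_edges=gt.planted_edges,
        effect_size=gt.effect_size,
        miss_attenuation=gt.miss_attenuation,
        spontaneous_rate=gt.spontaneous_rate,
        burst_bin_fraction=gt.burst_bin_fraction,
        sigma_target=gt.sigma_target,
    )

    n_trials = spec.n_trials
    conditions = np.array(["MI"] * spec.n_trials_per_condition + ["Rest"] * spec.n_trials_per_condition)
    rng.shuffle(conditions)
    outcomes = np.where(rng.random(n_trials) < spec.hit_rate, "hit", "miss")

    n_bins = spec.n_samples  # cascades simulated at sample resolution
    signals = np.empty((n_trials, n_regions, spec.n_samples), dtype=np.float32)
    for condition in CONDITIONS:
        for outcome in OUTCOMES:
            idx = np.flatnonzero((conditions == condition) & (outcomes == outcome))
            if idx.size == 0:
                continue
            weights = subject_gt.weights_for(condition, outcome)
            rasters = _simulate_batch(
                weights, gt.spontaneous_rate, gt.burst_bin_fraction, idx.size, n_bins, rng
            )
            for k, trial in enumerate(idx):
                signals[trial] = embed_signals(
                    rasters[k], noise_sd=1.0, threshold_z=3.0, rng_seed=rng
                )

    if gt.planted_edges.size:
        pe = gt.planted_edges
        realized = float((w_mi[pe[:, 0], pe[:, 1]] - w_rest[pe[:, 0], pe[:, 1]]).mean())
        # population baseline, so the score tracks between-subject variation
        baseline = float(gt.weights_rest[pe[:, 0], pe[:, 1]].mean())
    else:
        realized, baseline = 0.0, 1.0
    score = _bci_score(realized, baseline, rng)

    data = EpochedSourceData(
        subject_id=f"sub-{subject_index:02d}",
        signals=signals,
        sampling_rate_hz=spec.sampling_rate_hz,
        condition_labels=conditions,
        outcome_labels=outcomes,
    )
    return SubjectRecord(
        data=data,
        bci_score=score,
        weights_rest=w_rest,
        weights_mi=w_mi,
        realized_effect=realized,
    )


def iter_subjects(spec: CohortSpec, gt: GroundTruth):
    """Yield SubjectRecord one at a time (memory-friendly for large cohorts)."""
    seqs = np.random.SeedSequence(spec.seed).spawn(spec.n_subjects)
    for s, seq in enumerate(seqs):
        yield _make_subject(spec, gt, s, seq)


def make_cohort(spec: CohortSpec, gt: GroundTruth) -> SyntheticCohort:
    """Materialize a full synthetic cohort (see :func:`iter_subjects` to stream)."""
    return SyntheticCohort(spec=spec, ground_truth=gt, subjects=list(iter_subjects(spec, gt)))
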