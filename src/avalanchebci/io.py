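"""HDF5 / CSV containers for cohorts, trial ATMs and results tables."""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .avalanches import CONDITIONS, OUTCOMES, EpochedSourceData, TrialATMSet
from .cohort import CohortSpec, GroundTruth, SubjectRecord, SyntheticCohort

__all__ = [
    "save_cohort",
    "load_cohort",
    "save_trial_atms",
    "load_trial_atms",
    "import_epochs",
    "load_area_map",
    "avalanche_catalog",
]

_STR = h5py.string_dtype(encoding="utf-8")


def save_cohort(path: str | Path, cohort: SyntheticCohort) -> None:
    """Write a synthetic cohort to an HDF5 container.

    Layout: /subjects/<id>/{signals, condition_labels, outcome_labels,
    weights_rest, weights_mi} plus /bci_scores and /ground_truth; the cohort
    spec and seed are stored as root attributes (JSON)."""
    with h5py.File(path, "w") as f:
        f.attrs["spec"] = json.dumps(vars(cohort.spec))
        f.attrs["seed"] = cohort.spec.seed
        gt = cohort.ground_truth
        g = f.create_group("ground_truth")
        g.create_dataset("weights_rest", data=gt.weights_rest)
        g.create_dataset("weights_mi", data=gt.weights_mi)
        g.create_dataset("planted_edges", data=gt.planted_edges)
        g.attrs.update(
            {
                "effect_size": gt.effect_size,
                "miss_attenuation": gt.miss_attenuation,
                "spontaneous_rate": gt.spontaneous_rate,
                "burst_bin_fraction": gt.burst_bin_fraction,
                "sigma_target": -1.0 if gt.sigma_target is None else gt.sigma_target,
            }
        )
        f.create_dataset("bci_scores", data=cohort.bci_scores)
        subs = f.create_group("subjects")
        for rec in cohort.subjects:
            sg = subs.create_group(rec.data.subject_id)
            sg.create_dataset("signals", data=rec.data.signals, compression="gzip", compression_opts=1)
            sg.create_dataset("condition_labels", data=rec.data.condition_labels.astype(object), dtype=_STR)
            if rec.data.outcome_labels is not None:
                sg.create_dataset("outcome_labels", data=rec.data.outcome_labels.astype(object), dtype=_STR)
            sg.create_dataset("weights_rest", data=rec.weights_rest)
            sg.create_dataset("weights_mi", data=rec.weights_mi)
            sg.attrs["bci_score"] = rec.bci_score
            sg.attrs["realized_effect"] = rec.realized_effect
            sg.attrs["sampling_rate_hz"] = rec.data.sampling_rate_hz


def load_cohort(path: str | Path) -> SyntheticCohort:
    with h5py.File(path, "r") as f:
        spec = CohortSpec(**json.loads(f.attrs["spec"]))
        g = f["ground_truth"]
        sigma = float(g.attrs["sigma_target"])
        gt = GroundTruth(
            weights_rest=g["weights_rest"][()],
            weights_mi=g["weights_mi"][()],
            planted_edges=g["planted_edges"][()],
            effect_size=float(g.attrs["effect_size"]),
            miss_attenuation=float(g.attrs["miss_attenuation"]),
            spontaneous_rate=float(g.attrs["spontaneous_rate"]),
            burst_bin_fraction=float(g.attrs["burst_bin_fraction"]),
            sigma_target=None if sigma < 0 else sigma,
        )
        subjects = []
        for sid in sorted(f["subjects"]):
            sg = f["subjects"][sid]
            outcome = (
                sg["outcome_labels"].asstr()[()] if "outcome_labels" in sg else None
            )
            data = EpochedSourceData(
                subject_id=sid,
                signals=sg["signals"][()],
                sampling_rate_hz=float(sg.attrs["sampling_rate_hz"]),
                condition_labels=sg["condition_labels"].asstr()[()],
                outcome_labels=outcome,
            )
            subjects.append(
                SubjectRecord(
                    data=data,
                    bci_score=float(sg.attrs["bci_score"]),
                    weights_rest=sg["weights_rest"][()],
                    weights_mi=sg["weights_mi"][()],
                    realized_effect=float(sg.attrs["realized_effect"]),
                )
            )
    return SyntheticCohort(spec=spec, ground_truth=gt, subjects=subjects)


def save_trial_atms(path: str | Path, atm_sets: list[TrialATMSet]) -> None:
    with h5py.File(path, "w") as f:
        for atms in atm_sets:
            g = f.create_group(atms.subject_id)
            g.create_dataset("matrices", data=atms.matrices, compression="gzip", compression_opts=1)
            g.create_dataset("has_avalanches", data=atms.has_avalanches)
            g.create_dataset("condition_labels", data=atms.condition_labels.astype(object), dtype=_STR)
            if atms.outcome_labels is not None:
                g.create_dataset("outcome_labels", data=atms.outcome_labels.astype(object), dtype=_STR)
            g.create_dataset("n_avalanches_per_trial", data=atms.n_avalanches_per_trial)
            g.attrs["threshold_z"] = atms.threshold_z
            g.attrs["bin_length_samples"] = atms.bin_length_samples


def load_trial_atms(path: str | Path) -> list[TrialATMSet]:
    out = []
    with h5py.File(path, "r") as f:
        for sid in sorted(f):
            g = f[sid]
            out.append(
                TrialATMSet(
                    subject_id=sid,
                    matrices=g["matrices"][()],
                    has_avalanches=g["has_avalanches"][()].astype(bool),
                    condition_labels=g["condition_labels"].asstr()[()],
                    outcome_labels=(
                        g["outcome_labels"].asstr()[()] if "outcome_labels" in g else None
                    ),
                    threshold_z=float(g.attrs["threshold_z"]),
                    bin_length_samples=int(g.attrs["bin_length_samples"]),
                    n_avalanches_per_trial=g["n_avalanches_per_trial"][()],
                )
            )
    return out


def import_epochs(path: str | Path, dialect: str = "hdf5", subject_id: str | None = None) -> EpochedSourceData:
    """Import epoched source time series from a standard container.

    dialect="hdf5": a file with datasets ``signals`` (trials x regions x
    samples), ``condition_labels``, optional ``outcome_labels`` and attribute
    ``sampling_rate_hz``. dialect="csvdir": a directory with one delimited
    matrix (regions x samples) per trial named trial_*.csv plus labels.csv
    (columns: trial, condition[, outcome]) and meta.json
    ({"sampling_rate_hz": ...}).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "hdf5":
        with h5py.File(path, "r") as f:
            if "signals" not in f:
                raise ValueError(f"{path}: missing 'signals' dataset")
            outcome = f["outcome_labels"].asstr()[()] if "outcome_labels" in f else None
            return EpochedSourceData(
                subject_id=subject_id or path.stem,
                signals=f["signals"][()],
                sampling_rate_hz=float(f.attrs["sampling_rate_hz"]),
                condition_labels=f["condition_labels"].asstr()[()],
                outcome_labels=outcome,
            )
    if dialect == "csvdir":
        labels = pd.read_csv(path / "labels.csv")
        if "condition" not in labels.columns:
            raise ValueError("labels.csv must have a 'condition' column")
        bad = set(labels["condition"]) - set(CONDITIONS)
        if bad:
            raise ValueError(f"unknown condition labels {sorted(bad)}; allowed: {CONDITIONS}")
        if "outcome" in labels.columns:
            bad = set(labels["outcome"]) - set(OUTCOMES)
            if bad:
                raise ValueError(f"unknown outcome labels {sorted(bad)}; allowed: {OUTCOMES}")
        meta = json.loads((path / "meta.json").read_text())
        trials = []
        files = sorted(path.glob("trial_*.csv"))
        if len(files) != len(labels):
            raise ValueError(f"{len(files)} trial files but {len(labels)} label rows")
        shape = None
        for fp in files:
            mat = np.loadtxt(fp, delimiter=",", ndmin=2)
            if shape is None:
                shape = mat.shape
            elif mat.shape != shape:
                raise ValueError(
                    f"{fp.name}: shape {mat.shape} differs from {shape} (wrong region count?)"
                )
            trials.append(mat)
        return EpochedSourceData(
            subject_id=subject_id or path.name,
            signals=np.stack(trials),
            sampling_rate_hz=float(meta["sampling_rate_hz"]),
            condition_labels=labels["condition"].to_numpy(),
            outcome_labels=labels["outcome"].to_numpy() if "outcome" in labels.columns else None,
        )
    raise ValueError(f"unknown dialect {dialect!r}; use 'hdf5' or 'csvdir'")


def load_area_map(path: str | Path | None = None) -> pd.DataFrame:
    """Region -> functional-area map (columns: region, area).

    Defaults to the bundled approximate Desikan-68 assignment into five
    areas: executive, pre/motor, parietal, temporal, occipital."""
    if path is None:
        ref = resources.files("avalanchebci.data") / "desikan_areas.csv"
        with resources.as_file(ref) as p:
            df = pd.read_csv(p, comment="#")
    else:
        df = pd.read_csv(path, comment="#")
    if not {"region", "area"} <= set(df.columns):
        raise ValueError("area map needs 'region' and 'area' columns")
    return df


def avalanche_catalog(avalanches) -> pd.DataFrame:
    """Tabulate avalanches: trial, start, end, size, duration (CSV-friendly)."""
    return pd.DataFrame(
        [
            {
                "trial": a.trial_index,
                "start_bin": a.start_bin,
                "end_bin": a.end_bin,
                "size": a.size,
                "duration_bins": a.duration_bins,
                "truncated_start": a.truncated_start,
                "truncated_end": a.truncated_end,
            }
            for a in avalanches
        ]
    )
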