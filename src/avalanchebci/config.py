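"""Pipeline configuration (YAML) and run manifests."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import yaml

from . import __version__

__all__ = ["PipelineConfig", "RunManifest", "load_config"]

_PROFILES = ("small", "paper-scale")


@dataclass
class PipelineConfig:
    """Resolved configuration of the end-to-end pipeline.

    ``profile='small'`` selects the fast 19-region / 2-s geometry; the
    'paper-scale' profile uses the full study design (20 subjects, 68
    regions, 7-s epochs)."""

    out_dir: str = "results"
    profile: str = "small"
    seed: int = 0
    threshold_z: float = 3.0
    bin_length: int = 1
    n_permutations: int = 10_000
    alpha: float = 0.05
    n_splits: int = 50
    test_fraction: float = 0.2
    n_subjects: int | None = None
    n_trials_per_condition: int | None = None
    effect_size: float = 2.0
    miss_attenuation: float = 0.5
    area_map: str | None = None  # None -> bundled Desikan-68 map
    cohort_path: str | None = None  # reuse an existing cohort file

    def __post_init__(self) -> None:
        if self.profile not in _PROFILES:
            raise ValueError(f"profile must be one of {_PROFILES}")
        if self.bin_length not in (1, 2, 3):
            raise ValueError("bin_length must be 1, 2 or 3")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if not 0 < self.test_fraction < 1:
            raise ValueError("test_fraction must lie in (0, 1)")
        for name in ("n_permutations", "n_splits"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")

    def cohort_spec_kwargs(self) -> dict:
        kw: dict = {"seed": self.seed}
        if self.n_subjects is not None:
            kw["n_subjects"] = self.n_subjects
        if self.n_trials_per_condition is not None:
            kw["n_trials_per_condition"] = self.n_trials_per_condition
        return kw

    def dump(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))


def load_config(path: str | Path | None, **overrides) -> PipelineConfig:
    raw = {}
    if path is not None:
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ValueError(f"{path}: config must be a YAML mapping")
        unknown = set(raw) - set(PipelineConfig.__dataclass_fields__)
        if unknown:
            raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
    raw.update({k: v for k, v in overrides.items() if v is not None})
    return PipelineConfig(**raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Provenance of one pipeline run: enough to reproduce outputs."""

    stage: str
    seed: int
    config: dict
    version: str = __version__
    timestamp: str = field(
        default_factory=lambda: datetime.now(timezone.utc).isoformat()
    )
    input_hashes: dict = field(default_factory=dict)

    def add_input(self, path: str | Path) -> None:
        p = Path(path)
        self.input_hashes[p.name] = _sha256(p)

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))
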