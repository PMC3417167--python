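"""Run configuration.

All printed analysis constants live here as defaults: TR 2.112 s, rating rate
5 Hz, high-pass cutoff 128 s, FDR q = 0.05, ROI radii 3 mm (beta summaries) and
6 mm (connectivity), 10^6 permutations with a minimum circular shift of 10
samples, and 100 community-detection restarts. Call sites never hard-code them.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import yaml

from .errors import ValidationError


@dataclass
class RunConfig:
    tr_s: float = 2.112
    rating_rate_hz: float = 5.0
    highpass_cutoff_s: float = 128.0
    fdr_q: float = 0.05
    roi_radius_beta_mm: float = 3.0
    roi_radius_conn_mm: float = 6.0
    n_permutations: int = 1_000_000
    min_shift_samples: int = 10
    n_community_restarts: int = 100
    rng_seed: int = 0
    hrf_mode: str = "canonical"          # "canonical" | "none"
    glm_mode: str = "per_feature"        # "per_feature" | "combined"
    orthogonalize: bool = False

    def __post_init__(self):
        for name in ("tr_s", "rating_rate_hz", "highpass_cutoff_s", "fdr_q",
                     "roi_radius_beta_mm", "roi_radius_conn_mm"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be > 0")
        if self.min_shift_samples < 1:
            raise ValidationError("min_shift_samples must be >= 1")
        if self.n_permutations < 1:
            raise ValidationError("n_permutations must be >= 1")
        if self.n_community_restarts < 1:
            raise ValidationError("n_community_restarts must be >= 1")
        if self.hrf_mode not in ("canonical", "none"):
            raise ValidationError(f"unknown hrf_mode {self.hrf_mode!r}")
        if self.glm_mode not in ("per_feature", "combined"):
            raise ValidationError(f"unknown glm_mode {self.glm_mode!r}")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        """Stable hash of the configuration, logged by every stage."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
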