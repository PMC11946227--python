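"""Run configuration: YAML schema, validation and hashing.

Schema (all keys optional; defaults shown):

.. code-block:: yaml

    fps: 25.0
    reference:
      alpha_interval: [146.26, 164.87]
      beta_interval: [175.29, 179.99]
      alpha_band_edges: [0.75, 0.50, 0.25]
      beta_band_edges: [0.90, 0.80, 0.70]
      overlap_method: sample_fraction    # or interval_overlap
    cleaning:
      likelihood_threshold: 0.6
      max_gap: 12
    summary:
      interval_method: minmax            # or percentile
      percentile_tail: 2.5
      min_valid_frames: 50
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import gait_features as gf
from . import scoring
from .exceptions import ValidationError


@dataclass
class RunConfig:
    fps: float = 25.0
    alpha_interval: tuple = scoring.NORMAL_ALPHA_INTERVAL
    beta_interval: tuple = scoring.NORMAL_BETA_INTERVAL
    alpha_band_edges: tuple = scoring.ALPHA_BAND_EDGES
    beta_band_edges: tuple = scoring.BETA_BAND_EDGES
    overlap_method: str = "sample_fraction"
    likelihood_threshold: float = gf.DEFAULT_LIKELIHOOD_THRESHOLD
    max_gap: int = gf.DEFAULT_MAX_GAP
    interval_method: str = "minmax"
    percentile_tail: float = 2.5
    min_valid_frames: int = gf.DEFAULT_MIN_VALID_FRAMES

    def reference(self) -> scoring.ReferenceModel:
        return scoring.ReferenceModel(
            alpha_ref_low=self.alpha_interval[0],
            alpha_ref_high=self.alpha_interval[1],
            beta_ref_low=self.beta_interval[0],
            beta_ref_high=self.beta_interval[1],
            alpha_bands=tuple(self.alpha_band_edges),
            beta_bands=tuple(self.beta_band_edges),
            overlap_method=self.overlap_method,
        )

    def scorer(self) -> scoring.LamenessScorer:
        return scoring.LamenessScorer(
            alpha_ref=tuple(self.alpha_interval),
            beta_ref=tuple(self.beta_interval),
            alpha_band_edges=tuple(self.alpha_band_edges),
            beta_band_edges=tuple(self.beta_band_edges),
            overlap_method=self.overlap_method,
            likelihood_threshold=self.likelihood_threshold,
            max_gap=self.max_gap,
            min_valid_frames=self.min_valid_frames,
            interval_method=self.interval_method,
            percentile_tail=self.percentile_tail,
        ).fit()

    def digest(self) -> str:
        """Short stable hash of the effective configuration."""
        payload = json.dumps(asdict(self), sort_keys=True, default=list)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


_SECTIONS = {
    "reference": {
        "alpha_interval",
        "beta_interval",
        "alpha_band_edges",
        "beta_band_edges",
        "overlap_method",
    },
    "cleaning": {"likelihood_threshold", "max_gap"},
    "summary": {"interval_method", "percentile_tail", "min_valid_frames"},
}


def load_config(path: str | Path | None = None) -> RunConfig:
    """Load and validate a YAML config, merged over defaults.

    Unknown keys raise a schema error before any computation.
    """
    cfg = RunConfig()
    if path is None:
        return cfg
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValidationError(f"{path}: config must be a mapping")
    for key, value in raw.items():
        if key == "fps":
            cfg.fps = float(value)
        elif key in _SECTIONS:
            if not isinstance(value, dict):
                raise ValidationError(f"{path}: section {key!r} must be a mapping")
            for sub, v in value.items():
                if sub not in _SECTIONS[key]:
                    raise ValidationError(
                        f"{path}: unknown key {key}.{sub!r} in config"
                    )
                setattr(cfg, sub, tuple(v) if isinstance(v, list) else v)
        else:
            raise ValidationError(f"{path}: unknown key {key!r} in config")
    cfg.reference()  # validates intervals and band edges
    if cfg.interval_method not in ("minmax", "percentile"):
        raise ValidationError(f"{path}: unknown interval_method {cfg.interval_method!r}")
    return cfg
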