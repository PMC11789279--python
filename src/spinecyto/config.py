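"""Run configuration shared by the pipeline, the generators and the CLI.

Defaults mirror the analysis parameters of the study this package
re-implements: Gaussian blur sd 3 µm, order-4 polynomial detrend,
significance level 0.05, 1000 bootstrap resamples, 15 µm wide ROIs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from typing import Optional

import yaml


@dataclass(frozen=True)
class RunConfig:
    """All tunable parameters of a run, persisted alongside every output.

    Parameters
    ----------
    sigma_um : Gaussian blur standard deviation applied to each ROI (µm).
    poly_order : order of the polynomial detrend of the dorsoventral profile.
    alpha : significance level for the Fisher g-test and the ACF bootstrap.
    n_boot : number of permutation resamples for the ACF threshold.
    seed : master seed; every stochastic step derives from it.
    roi_width_um : default apicobasal width of analysis boxes (µm).
    pixel_um : optional pixel-size override when TIFF metadata is absent.
    puncta_k_mad : puncta must exceed background median + k * MAD.
    puncta_min_sep_um : minimum spacing between counted puncta (µm).
    lifetime_cap_min : protrusion tracks with longer lifetimes are excluded.
    """

    sigma_um: float = 3.0
    poly_order: int = 4
    alpha: float = 0.05
    n_boot: int = 1000
    seed: int = 0
    roi_width_um: float = 15.0
    pixel_um: Optional[float] = None
    puncta_k_mad: float = 3.0
    puncta_min_sep_um: float = 1.0
    lifetime_cap_min: float = 100.0

    def __post_init__(self) -> None:
        if self.sigma_um < 0:
            raise ValueError("sigma_um must be >= 0")
        if self.poly_order < 0:
            raise ValueError("poly_order must be >= 0")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.n_boot < 1:
            raise ValueError("n_boot must be >= 1")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def hash(self) -> str:
        """Short stable digest of the effective configuration."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
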