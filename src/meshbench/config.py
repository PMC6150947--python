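"""Run configuration: every tunable of the benchmark in one document.

Defaults pin the benchmark's canonical operating point: 8 HMM states on
40 PCA components, 200 ms epochs, the 4 most-occupied states, 16 temporal
modes, 512 MSP patches, 10 cross-validation folds holding out 10% of
channels, WFS bandwidth sigma = 1e-4 with a 50-order library. A ``tiny``
preset scales the synthetic problem down for smoke tests.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from typing import Optional

import yaml

from .synthgen import SimConfig

__all__ = ["MeshSection", "SensorSection", "WFSSection", "HMMSection",
           "InversionSection", "CVSection", "StatsSection", "RunConfig"]


@dataclass
class MeshSection:
    n_vertices: int = 2562
    fold_amplitude: float = 5.0  # mm
    fold_frequency: int = 12
    radius: float = 70.0  # mm
    n_components: int = 1


@dataclass
class SensorSection:
    n_channels: int = 272
    cap_radius: float = 120.0  # mm
    conductor_radius: float = 95.0  # mm


@dataclass
class WFSSection:
    L_max: int = 50
    sigma: float = 1e-4


@dataclass
class HMMSection:
    K: int = 8
    n_pca: int = 40
    epoch_ms: float = 200.0
    n_dominant: int = 4
    n_restarts: int = 5


@dataclass
class InversionSection:
    priors: tuple = ("EBB",)
    R: int = 16
    msp_patches: int = 512
    smooth_s: float = 0.6


@dataclass
class CVSection:
    n_folds: int = 10
    holdout_frac: float = 0.10


@dataclass
class StatsSection:
    alpha: float = 0.05
    bmc_draws: int = 100_000


@dataclass
class RunConfig:
    sim: SimConfig = field(default_factory=SimConfig)
    mesh: MeshSection = field(default_factory=MeshSection)
    sensors: SensorSection = field(default_factory=SensorSection)
    wfs: WFSSection = field(default_factory=WFSSection)
    hmm: HMMSection = field(default_factory=HMMSection)
    inversion: InversionSection = field(default_factory=InversionSection)
    cv: CVSection = field(default_factory=CVSection)
    stats: StatsSection = field(default_factory=StatsSection)
    n_subjects: int = 8
    seed: int = 0
    paths: Optional[dict] = None  # external mesh/recording/sensor files

    def validate(self) -> None:
        checks = [
            (self.wfs.L_max >= 1, "wfs.L_max must be >= 1"),
            (0 < self.wfs.sigma, "wfs.sigma must be positive"),
            (self.hmm.K >= 1, "hmm.K must be >= 1"),
            (self.hmm.n_dominant <= self.hmm.K, "hmm.n_dominant cannot exceed hmm.K"),
            (self.hmm.epoch_ms > 0, "hmm.epoch_ms must be positive"),
            (self.inversion.R >= 1, "inversion.R must be >= 1"),
            (0 < self.cv.holdout_frac < 1, "cv.holdout_frac must lie in (0, 1)"),
            (self.cv.n_folds >= 1, "cv.n_folds must be >= 1"),
            (0 < self.stats.alpha < 1, "stats.alpha must lie in (0, 1)"),
            (self.n_subjects >= 1, "n_subjects must be >= 1"),
            (
                self.sensors.cap_radius > self.sensors.conductor_radius,
                "sensors.cap_radius must exceed sensors.conductor_radius",
            ),
            (
                all(
                    str(p).upper() in {"MMN", "LOR", "EBB", "MSP"}
                    for p in self.inversion.priors
                ),
                "inversion.priors entries must be among MMN/LOR/EBB/MSP",
            ),
        ]
        errors = [msg for ok, msg in checks if not ok]
        try:
            self.sim.validate()
        except ValueError as e:
            errors.append(f"sim: {e}")
        if errors:
            raise ValueError("invalid configuration:\n  " + "\n  ".join(errors))

    # -- serialization -----------------------------------------------------

    def to_yaml(self, path) -> None:
        with open(path, "w") as f:
            yaml.safe_dump(asdict(self), f, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as f:
            raw = yaml.safe_load(f) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        sections = {
            "sim": SimConfig,
            "mesh": MeshSection,
            "sensors": SensorSection,
            "wfs": WFSSection,
            "hmm": HMMSection,
            "inversion": InversionSection,
            "cv": CVSection,
            "stats": StatsSection,
        }
        kwargs = {}
        for key, val in raw.items():
            if key in sections:
                klass = sections[key]
                known = klass.__dataclass_fields__
                bad = set(val) - set(known)
                if bad:
                    raise ValueError(f"unknown field(s) in '{key}': {sorted(bad)}")
                if key == "inversion" and "priors" in val:
                    val = dict(val, priors=tuple(val["priors"]))
                kwargs[key] = klass(**val)
            elif key in ("n_subjects", "seed", "paths"):
                kwargs[key] = val
            else:
                raise ValueError(f"unknown configuration section '{key}'")
        cfg = cls(**kwargs)
        cfg.validate()
        return cfg

    # -- presets -----------------------------------------------------------

    @classmethod
    def tiny(cls, seed: int = 0, priors=("EBB", "MMN")) -> "RunConfig":
        """Desk-scale preset: 642-vertex cortex, 64 channels, short block."""
        return cls(
            sim=SimConfig(
                n_states=2,
                state_dwell_ms=200.0,
                sources_per_state=3,
                source_amplitude=20.0,
                snr_db=5.0,
                duration_s=40.0,
                fs=600.0,
                seed=seed,
            ),
            mesh=MeshSection(n_vertices=642, fold_frequency=8),
            sensors=SensorSection(n_channels=64),
            wfs=WFSSection(L_max=8),
            hmm=HMMSection(K=2, n_pca=16, n_dominant=2, n_restarts=2),
            inversion=InversionSection(priors=tuple(priors), R=8, msp_patches=64),
            cv=CVSection(n_folds=10, holdout_frac=0.10),
            stats=StatsSection(bmc_draws=20_000),
            n_subjects=8,
            seed=seed,
        )
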