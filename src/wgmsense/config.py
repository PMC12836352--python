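"""Run configuration: load/save, validation, provenance hashing."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .optics import OpticalConfig
from .viability import ViabilityThresholds

__all__ = ["RunConfig", "ConfigError"]


class ConfigError(ValueError):
    """Invalid or inconsistent run configuration."""


@dataclass(frozen=True)
class RunConfig:
    """Everything a pipeline run needs, serializable to YAML/JSON.

    ``config_hash`` (of the canonical JSON form) plus the seed give full
    provenance for every artifact a run writes.
    """

    manifest: str | None = None
    out_dir: str = "wgmsense_out"
    n_ld: float = 1.47
    n_cell: float = 1.36
    band_nm: tuple[float, float] = (590.0, 650.0)
    radial_order: int = 1
    n_eff: float | None = None  # defaults to n_ld
    snr_threshold: float = 20.0
    lasing_score: float = 0.5
    rupture_dncell: float = 0.01
    static_window_h: float = 3.0
    static_factor: float = 3.0
    seed: int = 0
    verbosity: int = 1

    def optical(self) -> OpticalConfig:
        try:
            return OpticalConfig(
                n_ld=self.n_ld,
                n_cell=self.n_cell,
                radial_order=self.radial_order,
                band_nm=tuple(self.band_nm),
            )
        except ValueError as exc:
            raise ConfigError(str(exc)) from exc

    def thresholds(self) -> ViabilityThresholds:
        return ViabilityThresholds(
            lasing_score=self.lasing_score,
            rupture_dncell=self.rupture_dncell,
            static_window_h=self.static_window_h,
            static_factor=self.static_factor,
        )

    @property
    def effective_n_eff(self) -> float:
        return self.n_ld if self.n_eff is None else self.n_eff

    def to_dict(self) -> dict:
        d = asdict(self)
        d["band_nm"] = list(self.band_nm)
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def save(self, path: str | Path) -> None:
        path = Path(path)
        with open(path, "w") as fh:
            if path.suffix in (".yaml", ".yml"):
                yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
            else:
                json.dump(self.to_dict(), fh, indent=2, sort_keys=True)

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        if not path.exists():
            raise ConfigError(f"config file {path} does not exist")
        with open(path) as fh:
            raw = (
                yaml.safe_load(fh)
                if path.suffix in (".yaml", ".yml")
                else json.load(fh)
            )
        if not isinstance(raw, dict):
            raise ConfigError(f"config file {path} must hold a mapping")
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        if "band_nm" in raw:
            raw["band_nm"] = tuple(raw["band_nm"])
        cfg = cls(**raw)
        cfg.optical()  # validate the optical block
        return cfg
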