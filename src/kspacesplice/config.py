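"""Pipeline configuration: a versioned YAML-backed schema.

A bare default configuration reproduces the reference study geometry —
220×440 scan matrix, three gains 6 dB apart, the three-region partition,
N = 120 middle samples — so running the pipeline with no options exercises
the method under its nominal conditions.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Sequence

import yaml

from .core import KSpaceAcquisition
from .errors import ConfigError
from .synthetic import DEFAULT_GAINS_DB, PhantomSpec, ReceiverModel, simulate_study

SCHEMA_VERSION = 1

__all__ = ["PipelineConfig", "SCHEMA_VERSION"]


def _build(cls, payload: dict[str, Any], path: str):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(payload) - known
    if unknown:
        raise ConfigError(f"{path}: unknown keys {sorted(unknown)}")
    try:
        return cls(**payload)
    except (TypeError, ConfigError) as exc:
        raise ConfigError(f"{path}: {exc}") from exc


@dataclass(frozen=True)
class PipelineConfig:
    """Everything a full simulate→splice→evaluate run needs."""

    mode: str = "simulate"  # "simulate" or "files"
    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    receiver: ReceiverModel = field(default_factory=ReceiverModel)
    gains_db: tuple[float, float, float] = DEFAULT_GAINS_DB
    seeds: tuple[int, int, int] = (101, 202, 303)
    phase_offsets_deg: tuple[float, float, float] | None = None
    input_paths: tuple[str, str, str] | None = None  # files mode: hi, mid, lo
    n_middle: int = 120
    corner_frac: float = 0.1
    roi: tuple[int, int, int, int] | None = None  # explicit 1-based ROI bounds
    phase_threshold_deg: float = 2.0
    output_dir: str = "."

    def __post_init__(self) -> None:
        if self.mode not in ("simulate", "files"):
            raise ConfigError(f"mode must be 'simulate' or 'files', got {self.mode!r}")
        if len(self.gains_db) != 3:
            raise ConfigError("gains_db must list exactly three gains")
        if len(self.seeds) != 3:
            raise ConfigError("seeds must list exactly three integers")
        if self.phase_offsets_deg is not None and len(self.phase_offsets_deg) != 3:
            raise ConfigError("phase_offsets_deg must list exactly three values")
        if self.mode == "files" and (
            self.input_paths is None or len(self.input_paths) != 3
        ):
            raise ConfigError("files mode requires input_paths: [hi, mid, lo]")
        if self.n_middle < 1:
            raise ConfigError("n_middle must be >= 1")

    # -- construction -----------------------------------------------------

    @classmethod
    def from_dict(cls, payload: dict[str, Any]) -> "PipelineConfig":
        payload = dict(payload)
        version = payload.pop("schema_version", SCHEMA_VERSION)
        if version != SCHEMA_VERSION:
            raise ConfigError(f"unsupported schema_version {version}")
        if "phantom" in payload:
            payload["phantom"] = _build(PhantomSpec, dict(payload["phantom"]), "phantom")
        if "receiver" in payload:
            payload["receiver"] = _build(
                ReceiverModel, dict(payload["receiver"]), "receiver"
            )
        for key in ("gains_db", "seeds", "phase_offsets_deg", "input_paths", "roi"):
            if payload.get(key) is not None:
                payload[key] = tuple(payload[key])
        return _build(cls, payload, "config")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        payload = yaml.safe_load(Path(path).read_text())
        if payload is None:
            payload = {}
        if not isinstance(payload, dict):
            raise ConfigError(f"{path}: top level must be a mapping")
        return cls.from_dict(payload)

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict[str, Any]:
        out: dict[str, Any] = {"schema_version": SCHEMA_VERSION}
        for f in dataclasses.fields(self):
            value = getattr(self, f.name)
            if dataclasses.is_dataclass(value):
                value = dataclasses.asdict(value)
            elif isinstance(value, tuple):
                value = list(value)
            out[f.name] = value
        return out

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()

    def with_seed_offset(self, offset: int) -> "PipelineConfig":
        return dataclasses.replace(
            self, seeds=tuple(int(s) + int(offset) for s in self.seeds)
        )

    # -- execution helpers -------------------------------------------------

    def acquisitions(self) -> tuple[KSpaceAcquisition, ...]:
        """The three (hi, mid, lo) acquisitions: simulated or loaded."""
        if self.mode == "simulate":
            return simulate_study(
                spec=self.phantom,
                base_rx=self.receiver,
                gains_db=self.gains_db,
                seeds=self.seeds,
                phase_offsets_deg=self.phase_offsets_deg,
            )
        from .io import read_kspace

        return tuple(read_kspace(p) for p in self.input_paths)  # type: ignore[union-attr]
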