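"""Run configuration: phantom + protocol + noise + seed, YAML/JSON round-trip."""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .acquisition import PROTOCOL_NAMES
from .errors import ValidationError
from .geometry import ImageGeometry

__all__ = ["RunConfig"]

_PHANTOM_KINDS = ("medium", "long", "heart")


@dataclass
class RunConfig:
    """Everything needed to reproduce one pipeline run.

    ``phantom`` holds the generator kind plus keyword overrides; ``protocol``
    a preset name plus overrides. The seed drives every random draw and is
    recorded in every output; a config round-trips losslessly through YAML
    or JSON.
    """

    phantom: dict = field(default_factory=lambda: {"kind": "medium"})
    protocol: dict = field(default_factory=lambda: {"name": "MS"})
    geometry: dict | None = None
    noise_sigma: float = 0.0
    seed: int = 0
    outdir: str = "run_output"
    registration: dict = field(default_factory=dict)

    def __post_init__(self):
        kind = self.phantom.get("kind")
        if kind not in _PHANTOM_KINDS:
            raise ValidationError(
                f"unknown phantom kind {kind!r}; expected one of {_PHANTOM_KINDS}"
            )
        name = self.protocol.get("name")
        if name not in PROTOCOL_NAMES:
            raise ValidationError(
                f"unknown protocol {name!r}; expected one of {PROTOCOL_NAMES}"
            )
        if self.noise_sigma < 0:
            raise ValidationError("noise sigma must be non-negative")

    def image_geometry(self) -> ImageGeometry | None:
        return None if self.geometry is None else ImageGeometry.from_dict(self.geometry)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        return cls(**d)

    def to_yaml(self, path) -> Path:
        path = Path(path)
        path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
        return path

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix == ".json":
            return cls.from_dict(json.loads(text))
        return cls.from_dict(yaml.safe_load(text))
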