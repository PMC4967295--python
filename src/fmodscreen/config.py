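"""YAML configuration loading/validation and run provenance.

Every randomized stage derives its RNG stream from the single seed in
the config, so one (config, inputs) pair reproduces a run
byte-identically — the manifest records the digests needed to check
that.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass
from pathlib import Path

import yaml

from . import __version__
from .screen import ScreenConfig

__all__ = ["load_config", "save_config", "config_hash", "RunManifest"]


def load_config(path: str | Path | None = None) -> ScreenConfig:
    """Load a screen config from YAML; missing keys take defaults.

    Unknown keys and out-of-range values are reported together in one
    error. An absent or empty file yields the all-defaults config.
    """
    data = {}
    if path is not None:
        data = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(data, dict):
            raise ValueError(f"{path}: config must be a YAML mapping")
    known = {f.name for f in dataclasses.fields(ScreenConfig)}
    unknown = sorted(set(data) - known)
    if unknown:
        raise ValueError(f"unknown config keys: {unknown}")
    cfg = ScreenConfig(**data)
    cfg.validate()
    return cfg


def save_config(cfg: ScreenConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(dataclasses.asdict(cfg),
                                         sort_keys=True))


def config_hash(cfg: ScreenConfig) -> str:
    blob = yaml.safe_dump(dataclasses.asdict(cfg), sort_keys=True)
    return hashlib.sha256(blob.encode()).hexdigest()


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    with path.open("rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Provenance of one run: everything needed to reproduce it."""

    config_hash: str
    input_digests: dict[str, str]
    seed: int
    timestamp: str
    tool_version: str

    @classmethod
    def create(cls, cfg: ScreenConfig, inputs: dict[str, str | Path],
               timestamp: str | None = None) -> "RunManifest":
        """Build a manifest; pass an explicit ``timestamp`` for
        byte-reproducible manifests (wall clock by default)."""
        digests = {name: _digest(Path(p)) for name, p in sorted(inputs.items())}
        if timestamp is None:
            timestamp = time.strftime("%Y-%m-%dT%H:%M:%S%z")
        return cls(config_hash(cfg), digests, cfg.seed, timestamp,
                   __version__)

    def to_json(self, path: str | Path | None = None) -> str:
        blob = json.dumps(dataclasses.asdict(self), indent=2,
                          sort_keys=True) + "\n"
        if path is not None:
            Path(path).write_text(blob)
        return blob
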