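"""YAML experiment configuration and the run manifest.

One YAML file describes a whole experiment in sections — ``cohort``,
``preprocess``, ``split``, ``model``, ``train``, ``eval`` — each mapping
directly onto the corresponding dataclass.  CLI flags override config
values.  Every stage writes its inputs' digests into a run manifest so a
published report can be traced back to bit-identical inputs.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict
from pathlib import Path

import yaml

from .model import ModelConfig
from .records import CohortSpec
from .splits import SplitSpec
from .training import TrainConfig

_SECTIONS = ("cohort", "preprocess", "split", "model", "train", "eval")


class ConfigError(ValueError):
    pass


def load_config(path) -> dict:
    """Parse and validate an experiment YAML into dataclasses where known.

    Unknown top-level sections raise; unknown keys inside a section raise
    with the section and key named, before any compute runs.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    for section in raw:
        if section not in _SECTIONS:
            raise ConfigError(f"{path}: unknown section {section!r} "
                              f"(valid: {', '.join(_SECTIONS)})")
    cfg: dict = {"eval": raw.get("eval", {}), "preprocess": raw.get("preprocess", {})}
    builders = {"cohort": CohortSpec, "split": SplitSpec,
                "model": ModelConfig, "train": TrainConfig}
    for section, cls in builders.items():
        params = raw.get(section, {})
        if not isinstance(params, dict):
            raise ConfigError(f"{path}: section {section!r} must be a mapping")
        if section == "split" and params:
            params = dict(params)
            params["train_subjects"] = tuple(params.get("train_subjects", ()))
            params["test_subjects"] = tuple(params.get("test_subjects", ()))
        try:
            cfg[section] = cls(**params) if params else None
        except TypeError as exc:
            raise ConfigError(f"{path}: section {section!r}: {exc}") from None
    return cfg


def file_digest(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


class RunManifest:
    """Accumulates per-stage input/output digests and seeds for a run."""

    def __init__(self, package_version: str):
        self.data = {"package_version": package_version,
                     "created": time.strftime("%Y-%m-%dT%H:%M:%S"),
                     "stages": {}}

    def record_stage(self, name: str, *, config: dict | None = None,
                     inputs: dict[str, str] | None = None,
                     outputs: dict[str, str] | None = None) -> None:
        self.data["stages"][name] = {
            "config": config or {},
            "input_digests": inputs or {},
            "output_digests": outputs or {},
        }

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.data, indent=2, default=str))


def dataclass_digest(obj) -> str:
    return hashlib.sha256(
        json.dumps(asdict(obj), sort_keys=True, default=str).encode()
    ).hexdigest()
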