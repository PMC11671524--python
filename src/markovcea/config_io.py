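"""Reading, writing and validating model configurations (YAML/JSON)."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml
from pydantic import ValidationError

from .model import ModelConfig

__all__ = ["load_config", "save_config", "config_schema", "config_hash", "ConfigError"]


class ConfigError(ValueError):
    """A configuration file that fails schema validation; the message
    names the offending field path."""


def load_config(path: str | Path) -> ModelConfig:
    """Load and validate a model configuration from YAML or JSON."""
    path = Path(path)
    text = path.read_text()
    try:
        doc = json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
    except (json.JSONDecodeError, yaml.YAMLError) as exc:
        raise ConfigError(f"{path}: not valid YAML/JSON: {exc}") from exc
    if isinstance(doc, dict) and "config" in doc and "states" not in doc:
        doc = doc["config"]  # accept a full fixture bundle too
    try:
        return ModelConfig.model_validate(doc)
    except ValidationError as exc:
        fields = ", ".join(
            ".".join(str(p) for p in err["loc"]) or "<root>" for err in exc.errors()
        )
        raise ConfigError(f"{path}: invalid configuration at: {fields}\n{exc}") from exc


def save_config(config: ModelConfig, path: str | Path) -> None:
    """Write a configuration as YAML (or JSON if the suffix says so)."""
    path = Path(path)
    doc = config.model_dump(mode="json", exclude_none=True)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(doc, indent=2) + "\n")
    else:
        path.write_text(yaml.safe_dump(doc, sort_keys=False))


def config_schema() -> dict:
    """JSON schema for the model configuration."""
    return ModelConfig.model_json_schema()


def config_hash(config: ModelConfig) -> str:
    """Stable SHA-256 over the canonicalised configuration."""
    doc = json.dumps(config.model_dump(mode="json"), sort_keys=True)
    return hashlib.sha256(doc.encode()).hexdigest()
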