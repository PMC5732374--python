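"""Reproducibility manifests for CLI runs.

Every subcommand writes a RunManifest JSON next to its outputs recording
the resolved parameters, seeds, input checksums and artifact paths.
Re-running the same subcommand with the same parameters and inputs
reproduces identical outputs; the manifest is the audit trail. The JSON
schema shipped with the package (``manifest_schema.json``) is generated
from the pydantic model below.
"""

from __future__ import annotations

import hashlib
import json
from importlib import resources
from pathlib import Path

from pydantic import BaseModel, Field

from . import __version__

__all__ = ["RunManifest", "sha256_of", "write_manifest", "load_manifest"]


def sha256_of(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


class RunManifest(BaseModel):
    """Resolved record of one CLI invocation."""

    tool: str = "rfclue"
    version: str = Field(default=__version__)
    subcommand: str
    parameters: dict
    seed: int | None = None
    input_checksums: dict[str, str] = Field(default_factory=dict)
    artifacts: list[str] = Field(default_factory=list)
    wall_clock_seconds: float | None = None  # informational only


def write_manifest(path, manifest: RunManifest) -> None:
    Path(path).write_text(manifest.model_dump_json(indent=2) + "\n")


def load_manifest(path) -> RunManifest:
    return RunManifest.model_validate_json(Path(path).read_text())


def shipped_schema() -> dict:
    """The JSON schema bundled as package data."""
    text = resources.files("rfclue").joinpath("manifest_schema.json").read_text()
    return json.loads(text)
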