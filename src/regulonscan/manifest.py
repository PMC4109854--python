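"""Run manifests: reproducibility metadata written beside every output.

A manifest records the tool version, subcommand, parameters, seed(s) and
SHA-256 hashes of every input file — enough to re-run a deterministic stage
bit-identically.  Wall-clock timestamps are omitted by default so that two
identical runs produce identical manifests; pass ``include_timestamp=True``
to add one.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

TOOL_NAME = "regulonscan"
TOOL_VERSION = "0.1.0"
MANIFEST_SCHEMA = {
    "required": ["tool", "version", "subcommand", "parameters", "inputs",
                 "seed", "outputs"],
}


def file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    subcommand: str
    parameters: dict
    inputs: dict = field(default_factory=dict)   # path -> sha256
    seed: int | None = None
    outputs: list = field(default_factory=list)
    timestamp: str | None = None
    tool: str = TOOL_NAME
    version: str = TOOL_VERSION

    @classmethod
    def create(
        cls,
        subcommand: str,
        parameters: dict,
        input_paths=(),
        seed: int | None = None,
        outputs=(),
        include_timestamp: bool = False,
        base_dir: str | Path | None = None,
    ) -> "RunManifest":
        """``base_dir`` records input paths relative to a run directory, so
        reruns of the same inputs in different directories stay identical."""
        def key(p):
            if base_dir is not None:
                try:
                    return str(Path(p).resolve().relative_to(
                        Path(base_dir).resolve()))
                except ValueError:
                    pass
            return str(p)

        inputs = {key(p): file_sha256(p) for p in input_paths}
        ts = (datetime.now(timezone.utc).isoformat()
              if include_timestamp else None)
        return cls(subcommand=subcommand, parameters=parameters,
                   inputs=inputs, seed=seed, outputs=list(outputs),
                   timestamp=ts)

    def to_dict(self) -> dict:
        d = {
            "tool": self.tool,
            "version": self.version,
            "subcommand": self.subcommand,
            "parameters": self.parameters,
            "inputs": self.inputs,
            "seed": self.seed,
            "outputs": self.outputs,
        }
        if self.timestamp is not None:
            d["timestamp"] = self.timestamp
        return d

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, indent=1) + "\n"

    def write(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(self.to_json())
        return path

    @classmethod
    def load(cls, path: str | Path) -> "RunManifest":
        d = json.loads(Path(path).read_text())
        validate_manifest(d)
        return cls(subcommand=d["subcommand"], parameters=d["parameters"],
                   inputs=d["inputs"], seed=d["seed"], outputs=d["outputs"],
                   timestamp=d.get("timestamp"), tool=d["tool"],
                   version=d["version"])


def validate_manifest(d: dict) -> None:
    missing = [k for k in MANIFEST_SCHEMA["required"] if k not in d]
    if missing:
        raise ValueError(f"manifest missing required fields: {missing}")
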