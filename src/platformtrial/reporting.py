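"""Run manifests and artifact writing for reproducible pipeline runs."""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

from . import __version__


def _digest(obj) -> str:
    return hashlib.sha256(
        json.dumps(obj, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def file_digest(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


@dataclass
class RunManifest:
    """Identifies one analytical run: same manifest (minus timestamp) =>
    byte-identical analytical outputs."""

    subcommand: str
    seed: int
    analysis_day: int | None
    config_hash: str
    input_digests: dict[str, str] = field(default_factory=dict)
    package_version: str = __version__
    timestamp: str = field(default_factory=lambda: time.strftime("%Y-%m-%dT%H:%M:%S"))

    @classmethod
    def create(cls, subcommand: str, seed: int, analysis_day, config: dict,
               inputs: dict[str, str] | None = None) -> "RunManifest":
        return cls(
            subcommand=subcommand,
            seed=seed,
            analysis_day=analysis_day,
            config_hash=_digest(config),
            input_digests={k: file_digest(v) for k, v in (inputs or {}).items()},
        )

    def write(self, out_dir) -> Path:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        path = out / "manifest.json"
        path.write_text(json.dumps(asdict(self), indent=2))
        return path
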