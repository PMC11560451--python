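"""Run manifests and seed management.

One global seed fans out to named per-stage substreams by hashing the stage
name, so any stage (simulation, rebalancing, fold initialization, epoch
resampling) can be reproduced in isolation.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic substream seed for a named stage, in [0, 2^31)."""
    digest = hashlib.sha256(f"{seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "little") % (2**31)


def file_digest(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Everything needed to re-run a training bit-identically on the same
    backend: resolved configs, the global seed, package version, timestamps
    and input-file digests. Written before training starts."""

    model_config: dict
    train_config: dict
    seed: int
    package_version: str
    created: str = field(
        default_factory=lambda: time.strftime("%Y-%m-%dT%H:%M:%S")
    )
    input_digests: dict = field(default_factory=dict)
    extra: dict = field(default_factory=dict)

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2) + "\n")

    @staticmethod
    def read(path) -> "RunManifest":
        return RunManifest(**json.loads(Path(path).read_text()))
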