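"""Run manifests: reproducibility metadata written next to every CLI output."""

from __future__ import annotations

import datetime as _dt
import hashlib
import json
import os
from dataclasses import asdict, dataclass, field

__all__ = ["RunManifest", "file_checksum"]


def file_checksum(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    command: str
    parameters: dict
    seed: int | None = None
    version: str = ""
    started: str = ""
    finished: str = ""
    outputs: dict = field(default_factory=dict)

    def __post_init__(self):
        if not self.version:
            from . import __version__

            self.version = __version__
        if not self.started:
            self.started = _dt.datetime.now(_dt.timezone.utc).isoformat()

    def finish(self, output_paths) -> "RunManifest":
        self.finished = _dt.datetime.now(_dt.timezone.utc).isoformat()
        for p in output_paths:
            self.outputs[os.path.basename(str(p))] = file_checksum(p)
        return self

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def read(cls, path) -> "RunManifest":
        with open(path) as fh:
            return cls(**json.load(fh))
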