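"""NamedWeights: the currency of cross-architecture weight transfer.

A flat mapping from dotted layer names to parameter arrays, plus a
provenance tag naming the source task. Serialized as a single .npz archive
whose manifest (name, shape, sha256, source_task) travels inside it as a
JSON string.
"""
from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = ["NamedWeights"]


def _checksum(a: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(a).tobytes()).hexdigest()[:16]


@dataclass
class NamedWeights:
    entries: dict[str, np.ndarray]
    source_task: str = "unknown"

    def __post_init__(self) -> None:
        for k, v in self.entries.items():
            v = np.asarray(v)
            if not np.issubdtype(v.dtype, np.floating):
                v = v.astype(np.float32)
            if not np.all(np.isfinite(v)):
                raise ValueError(f"non-finite values in {k}")
            self.entries[k] = v

    def manifest(self) -> list[dict]:
        return [
            {"name": k, "shape": list(v.shape), "sha256": _checksum(v)}
            for k, v in sorted(self.entries.items())
        ]

    def save(self, path: str | Path) -> None:
        meta = json.dumps({"source_task": self.source_task, "entries": self.manifest()})
        np.savez(path, __manifest__=np.array(meta), **self.entries)

    @classmethod
    def load(cls, path: str | Path) -> "NamedWeights":
        with np.load(path, allow_pickle=False) as z:
            meta = json.loads(str(z["__manifest__"]))
            entries = {k: z[k] for k in z.files if k != "__manifest__"}
        nw = cls(entries=entries, source_task=meta["source_task"])
        for rec in meta["entries"]:
            if _checksum(nw.entries[rec["name"]]) != rec["sha256"]:
                raise ValueError(f"checksum mismatch for {rec['name']}")
        return nw

    def subset(self, prefix: str) -> "NamedWeights":
        return NamedWeights(
            entries={k: v.copy() for k, v in self.entries.items() if k.startswith(prefix)},
            source_task=self.source_task,
        )
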