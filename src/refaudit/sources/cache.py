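"""Tiny disk cache for live responses, keyed by (db, statement, fetch type).

Iterative searching is the dominant use pattern, so repeated identical
queries within a session should not hit the network twice. One file per
key under the cache directory; no eviction — callers bypass or wipe it.
"""

from __future__ import annotations

import hashlib
from pathlib import Path
from typing import Optional


class DiskCache:
    def __init__(self, directory):
        self.directory = Path(directory)
        self.directory.mkdir(parents=True, exist_ok=True)

    @staticmethod
    def key(db: str, statement: str, fetch_type: str) -> str:
        digest = hashlib.sha256(f"{db}\x00{statement}\x00{fetch_type}".encode()).hexdigest()
        return digest

    def _path(self, key: str) -> Path:
        return self.directory / f"{key}.cache"

    def get(self, key: str) -> Optional[bytes]:
        p = self._path(key)
        return p.read_bytes() if p.is_file() else None

    def put(self, key: str, payload: bytes) -> None:
        self._path(key).write_bytes(payload)

    def clear(self) -> None:
        for p in self.directory.glob("*.cache"):
            p.unlink()
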