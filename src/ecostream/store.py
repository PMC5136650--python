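"""Keyed block storage for matrix chunks that must not stay resident.

Intermediates larger than memory (taxonomic distance blocks, mostly) are
spilled to a block store and re-read incrementally.  Two backends are
provided behind one contract: an in-memory dict for small runs and
tests, and a directory backend that writes one raw binary file per key
with a JSON sidecar recording shape and dtype, and therefore survives a
process restart.

Both backends keep running accounting (number of puts, bytes written,
largest single block) so callers can assert that a streaming pipeline
really did hold at most one block at a time.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import ValidationError

__all__ = ["StoreStats", "MemoryBlockStore", "DirectoryBlockStore", "open_store"]


@dataclass
class StoreStats:
    n_puts: int = 0
    n_gets: int = 0
    total_bytes_written: int = 0
    max_block_nbytes: int = 0

    def record_put(self, nbytes: int) -> None:
        self.n_puts += 1
        self.total_bytes_written += nbytes
        self.max_block_nbytes = max(self.max_block_nbytes, nbytes)


class _BaseStore:
    def __init__(self) -> None:
        self.stats = StoreStats()

    def put(self, key: str, block: np.ndarray) -> None:
        raise NotImplementedError

    def get(self, key: str) -> np.ndarray:
        raise NotImplementedError

    def keys(self) -> list[str]:
        raise NotImplementedError

    def __contains__(self, key: str) -> bool:
        return key in self.keys()


class MemoryBlockStore(_BaseStore):
    """Dict-backed store; blocks are copied on put and get."""

    backend = "memory"

    def __init__(self) -> None:
        super().__init__()
        self._data: dict[str, np.ndarray] = {}

    def put(self, key: str, block: np.ndarray) -> None:
        if key in self._data:
            raise ValidationError(f"duplicate block key {key!r}")
        block = np.ascontiguousarray(block)
        self._data[key] = block.copy()
        self.stats.record_put(block.nbytes)

    def get(self, key: str) -> np.ndarray:
        if key not in self._data:
            raise KeyError(key)
        self.stats.n_gets += 1
        return self._data[key].copy()

    def keys(self) -> list[str]:
        return sorted(self._data)


class DirectoryBlockStore(_BaseStore):
    """One raw binary file per key plus a JSON sidecar of shape/dtype."""

    backend = "directory"

    def __init__(self, path: str | Path) -> None:
        super().__init__()
        self.path = Path(path)
        self.path.mkdir(parents=True, exist_ok=True)

    def _files(self, key: str) -> tuple[Path, Path]:
        if "/" in key or key.startswith("."):
            raise ValidationError(f"invalid block key {key!r}")
        return self.path / f"{key}.bin", self.path / f"{key}.json"

    def put(self, key: str, block: np.ndarray) -> None:
        bin_path, meta_path = self._files(key)
        if bin_path.exists():
            raise ValidationError(f"duplicate block key {key!r}")
        block = np.ascontiguousarray(block)
        bin_path.write_bytes(block.tobytes())
        meta_path.write_text(json.dumps(
            {"shape": list(block.shape), "dtype": str(block.dtype)}))
        self.stats.record_put(block.nbytes)

    def get(self, key: str) -> np.ndarray:
        bin_path, meta_path = self._files(key)
        if not bin_path.exists():
            raise KeyError(key)
        meta = json.loads(meta_path.read_text())
        self.stats.n_gets += 1
        return np.frombuffer(
            bin_path.read_bytes(), dtype=np.dtype(meta["dtype"])
        ).reshape(meta["shape"]).copy()

    def keys(self) -> list[str]:
        return sorted(p.stem for p in self.path.glob("*.bin"))


def open_store(spec: str | Path | None):
    """``None`` -> in-memory store, a path -> directory store."""
    if spec is None:
        return MemoryBlockStore()
    return DirectoryBlockStore(spec)
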