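"""Loaders for externally produced protein language-model embeddings.

Embedding generation itself (e.g. by a transformer protein language model)
is outside this package: embeddings arrive as files and are presented to the
classifier through the same :class:`~rbpkit.encoders.FeatureSet` contract as
the hand-crafted encoders.  Both per-protein vectors (width D) and
per-residue matrices (L x D) are supported.

Dialects
--------
* TSV — header ``id<TAB>e1..eD``; one row per protein.  For per-residue
  tables an extra ``pos`` column (1-based residue index) follows ``id``.
* NPZ — one array per protein id (1-D of width D, or 2-D L x D).
* HDF5 — one dataset per protein id at the file root; little-endian floats.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np

from .encoders import FeatureSet

POOL_MODES = ("mean", "last", "none")


@dataclass
class EmbeddingTable:
    """Map protein id -> embedding (1-D vector or L x D per-residue array)."""

    entries: dict[str, np.ndarray]
    width: int
    source_name: str = ""

    def __post_init__(self) -> None:
        for pid, arr in self.entries.items():
            arr = np.asarray(arr, dtype=float)
            if arr.ndim not in (1, 2):
                raise ValueError(f"{pid}: embedding must be 1-D or 2-D")
            if arr.shape[-1] != self.width:
                raise ValueError(
                    f"{pid}: width {arr.shape[-1]} != table width {self.width}"
                )
            self.entries[pid] = arr

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, pid: str) -> bool:
        return pid in self.entries

    def features(self, ids: Iterable[str] | None = None, pool: str = "mean") -> list[FeatureSet]:
        """Materialize per-protein FeatureSets, pooling per-residue entries.

        Missing ids raise ``KeyError`` listing every absent id.
        """
        ids = list(self.entries) if ids is None else list(ids)
        missing = [i for i in ids if i not in self.entries]
        if missing:
            raise KeyError(f"ids missing from embedding table: {missing}")
        out = []
        for pid in ids:
            arr = self.entries[pid]
            vec = pool_residues(arr, pool) if arr.ndim == 2 else arr
            out.append(FeatureSet(pid, vec, self.source_name or "embedding"))
        return out


def pool_residues(entry: np.ndarray, mode: str = "mean") -> np.ndarray:
    """Collapse a per-residue L x D embedding to one vector (or pass through).

    ``mean`` = columnwise average, ``last`` = final row, ``none`` = the
    unchanged L x D sequence (for feeding the recurrent stack residue by
    residue).
    """
    if mode not in POOL_MODES:
        raise ValueError(f"unknown pooling mode {mode!r}; choose from {POOL_MODES}")
    entry = np.asarray(entry, dtype=float)
    if entry.ndim == 1:
        return entry
    if entry.shape[0] < 1:
        raise ValueError("per-residue entry must have L >= 1 rows")
    if mode == "mean":
        return entry.mean(axis=0)
    if mode == "last":
        return entry[-1]
    return entry


def _from_entries(entries: Mapping[str, np.ndarray], source_name: str) -> EmbeddingTable:
    widths = {np.asarray(a).shape[-1] for a in entries.values()}
    if len(widths) != 1:
        raise ValueError(f"ragged embedding widths across entries: {sorted(widths)}")
    return EmbeddingTable(dict(entries), widths.pop(), source_name)


def load_embeddings(path: str | Path, source_name: str = "") -> EmbeddingTable:
    """Load an embedding table, auto-detecting the dialect by file suffix
    (.tsv/.txt, .npz, .h5/.hdf5)."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".tsv", ".txt"):
        return _load_tsv(path, source_name or path.stem)
    if suffix == ".npz":
        with np.load(path) as data:
            entries = {pid: np.asarray(data[pid], dtype=float) for pid in data.files}
        return _from_entries(entries, source_name or path.stem)
    if suffix in (".h5", ".hdf5"):
        import h5py

        entries = {}
        with h5py.File(path, "r") as fh:
            for pid in fh:
                entries[pid] = np.asarray(fh[pid], dtype=float)
        return _from_entries(entries, source_name or path.stem)
    raise ValueError(f"unsupported embedding file type: {path.name}")


def _load_tsv(path: Path, source_name: str) -> EmbeddingTable:
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if not header or header[0] != "id":
            raise ValueError(f"{path}: embedding TSV must start with an 'id' column")
        per_residue = len(header) > 1 and header[1] == "pos"
        ncols = len(header) - (2 if per_residue else 1)
        if ncols < 1:
            raise ValueError(f"{path}: no embedding columns found")
        rows: dict[str, list] = {}
        for ln_no, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            toks = line.rstrip("\n").split("\t")
            expected = len(header)
            if len(toks) != expected:
                raise ValueError(
                    f"{path}:{ln_no}: ragged row with {len(toks)} columns, expected {expected}"
                )
            pid = toks[0]
            vals = [float(t) for t in toks[(2 if per_residue else 1):]]
            if per_residue:
                rows.setdefault(pid, []).append((int(toks[1]), vals))
            else:
                if pid in rows:
                    raise ValueError(f"{path}:{ln_no}: duplicate id '{pid}'")
                rows[pid] = vals
    if per_residue:
        entries = {}
        for pid, pairs in rows.items():
            pairs.sort(key=lambda p: p[0])  # keep residue order
            entries[pid] = np.array([v for _, v in pairs])
    else:
        entries = {pid: np.array(v) for pid, v in rows.items()}
    return _from_entries(entries, source_name)


def save_embeddings(table: EmbeddingTable, path: str | Path) -> None:
    """Write a table in the dialect implied by the file suffix."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".tsv", ".txt"):
        per_residue = any(a.ndim == 2 for a in table.entries.values())
        with open(path, "w", encoding="utf-8") as fh:
            cols = "\t".join(f"e{i+1}" for i in range(table.width))
            fh.write(("id\tpos\t" if per_residue else "id\t") + cols + "\n")
            for pid in sorted(table.entries):
                arr = table.entries[pid]
                if per_residue:
                    arr2 = arr if arr.ndim == 2 else arr[None, :]
                    for pos, row in enumerate(arr2, start=1):
                        fh.write(f"{pid}\t{pos}\t" + "\t".join(f"{v:.10g}" for v in row) + "\n")
                else:
                    fh.write(pid + "\t" + "\t".join(f"{v:.10g}" for v in arr) + "\n")
    elif suffix == ".npz":
        np.savez_compressed(path, **table.entries)
    elif suffix in (".h5", ".hdf5"):
        import h5py

        with h5py.File(path, "w") as fh:
            for pid, arr in table.entries.items():
                fh.create_dataset(pid, data=arr.astype("<f8"))
    else:
        raise ValueError(f"unsupported embedding file type: {path.name}")
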