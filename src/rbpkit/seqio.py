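"""Protein sequence datasets: reading, cleaning, partitioning, preprocessing.

Sequences are plain strings over the 20 standard one-letter amino-acid
codes.  Labels are binary: 1 = RNA-binding protein (RBP), 0 = non-RBP.
Dataset manifests are TSV files with columns ``id``, ``label``, ``species``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np

logger = logging.getLogger(__name__)

STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"
_STANDARD_SET = frozenset(STANDARD_AA)

CLEAN_POLICIES = ("reject", "drop_nonstandard", "map_to_X_then_drop")


@dataclass(frozen=True)
class ProteinRecord:
    """One protein: unique id, sequence, species tag, optional binary label."""

    id: str
    sequence: str
    species: str = ""
    label: Optional[int] = None
    description: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"{self.id}: empty sequence")
        bad = set(self.sequence) - _STANDARD_SET
        if bad:
            raise ValueError(
                f"{self.id}: non-standard residues {sorted(bad)}; "
                "pass the sequence through clean_sequence first"
            )
        if self.label is not None and self.label not in (0, 1):
            raise ValueError(f"{self.id}: label must be 0 or 1, got {self.label}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class DatasetSplit:
    """Disjoint train/validation/test partition of a record list."""

    train: list[ProteinRecord]
    validation: list[ProteinRecord]
    test: list[ProteinRecord]
    fractions: tuple[float, float, float]
    seed: int

    @property
    def sizes(self) -> tuple[int, int, int]:
        return len(self.train), len(self.validation), len(self.test)


def clean_sequence(raw: str, policy: str = "drop_nonstandard") -> str:
    """Normalise a raw sequence to the 20-letter alphabet.

    Policies:

    ``reject``
        any character outside the standard alphabet raises ``ValueError``.
    ``drop_nonstandard``
        characters outside the alphabet (incl. B, Z, X, U, O, ``*``, gaps)
        are removed.
    ``map_to_X_then_drop``
        non-standard characters are first mapped to X, then all X dropped
        (this also drops X already present in the input).
    """
    if not raw:
        raise ValueError("empty input sequence")
    if policy not in CLEAN_POLICIES:
        raise ValueError(f"unknown policy {policy!r}; choose from {CLEAN_POLICIES}")
    seq = raw.upper()
    if policy == "reject":
        for i, ch in enumerate(seq):
            if ch not in _STANDARD_SET:
                raise ValueError(
                    f"illegal character {ch!r} at position {i + 1} under policy 'reject'"
                )
        cleaned = seq
    elif policy == "drop_nonstandard":
        cleaned = "".join(ch for ch in seq if ch in _STANDARD_SET)
    else:  # map_to_X_then_drop
        mapped = "".join(ch if ch in _STANDARD_SET else "X" for ch in seq)
        cleaned = mapped.replace("X", "")
    if not cleaned:
        raise ValueError("sequence empty after cleaning")
    return cleaned


def read_fasta(
    path: str | Path,
    species: str = "",
    policy: str = "drop_nonstandard",
) -> list[ProteinRecord]:
    """Read a FASTA file into ProteinRecords.

    The id is the header token before the first whitespace; the remainder is
    kept as the record description.  Sequences are upper-cased and passed
    through :func:`clean_sequence` with the given policy.  Duplicate ids and
    malformed entries raise ``ValueError`` naming the offending line.
    """
    path = Path(path)
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    header: Optional[str] = None
    desc = ""
    chunks: list[str] = []
    header_line = 0

    def flush(line_no: int) -> None:
        nonlocal header
        if header is None:
            return
        raw = "".join(chunks)
        if not raw:
            raise ValueError(f"{path}:{header_line}: entry '{header}' has no sequence")
        try:
            seq = clean_sequence(raw, policy=policy)
        except ValueError as exc:
            raise ValueError(f"{path}:{header_line}: entry '{header}': {exc}") from exc
        records.append(
            ProteinRecord(id=header, sequence=seq, species=species, description=desc)
        )
        header = None

    with open(path, encoding="utf-8") as fh:
        for i, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith(">"):
                flush(i)
                parts = line[1:].split(maxsplit=1)
                if not parts:
                    raise ValueError(f"{path}:{i}: empty FASTA header")
                header, desc = parts[0], parts[1] if len(parts) > 1 else ""
                header_line = i
                if header in seen:
                    raise ValueError(f"{path}:{i}: duplicate id '{header}'")
                seen.add(header)
                chunks = []
            else:
                if header is None:
                    raise ValueError(f"{path}:{i}: sequence data before first header")
                chunks.append(line.strip())
        flush(-1)
    if not records:
        logger.warning("%s: no FASTA entries found", path)
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path, width: int = 80) -> None:
    """Write records as FASTA, sequence lines wrapped at ``width`` columns."""
    with open(path, "w", encoding="utf-8") as fh:
        for rec in records:
            head = f">{rec.id}"
            if rec.description:
                head += f" {rec.description}"
            fh.write(head + "\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


def read_manifest(path: str | Path) -> dict[str, tuple[int, str]]:
    """Read a label manifest TSV (columns id, label, species; header required).

    Returns id -> (label, species).
    """
    import csv

    out: dict[str, tuple[int, str]] = {}
    with open(path, encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"id", "label", "species"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise ValueError(f"{path}: manifest must have header columns {sorted(required)}")
        for row in reader:
            pid = row["id"]
            if pid in out:
                raise ValueError(f"{path}: duplicate id '{pid}' in manifest")
            out[pid] = (int(row["label"]), row["species"])
    return out


def write_manifest(records: Iterable[ProteinRecord], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("id\tlabel\tspecies\n")
        for rec in records:
            label = "" if rec.label is None else str(rec.label)
            fh.write(f"{rec.id}\t{label}\t{rec.species}\n")


def attach_labels(
    records: Sequence[ProteinRecord], manifest: dict[str, tuple[int, str]]
) -> list[ProteinRecord]:
    """Join records with a manifest; missing ids raise listing them."""
    missing = [r.id for r in records if r.id not in manifest]
    if missing:
        raise KeyError(f"ids missing from manifest: {missing}")
    return [
        replace(r, label=manifest[r.id][0], species=manifest[r.id][1] or r.species)
        for r in records
    ]


def apportion(n: int, fractions: Sequence[float]) -> list[int]:
    """Largest-remainder apportionment of ``n`` items by ``fractions``.

    Ties in the remainder are broken toward earlier parts (train first).
    """
    if any(f < 0 for f in fractions):
        raise ValueError("fractions must be non-negative")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1, got {sum(fractions)}")
    quotas = [n * f for f in fractions]
    sizes = [int(np.floor(q)) for q in quotas]
    leftover = n - sum(sizes)
    order = sorted(range(len(fractions)), key=lambda i: (-(quotas[i] - sizes[i]), i))
    for i in order[:leftover]:
        sizes[i] += 1
    return sizes


def split_dataset(
    records: Sequence[ProteinRecord],
    fractions: tuple[float, float, float] = (0.81, 0.09, 0.10),
    seed: int = 0,
) -> DatasetSplit:
    """Partition records into train/validation/test parts.

    Part sizes follow largest-remainder apportionment of ``len(records)`` by
    ``fractions``.  When labels are present the split is stratified: positives
    are apportioned by the same rule, so the positive ratio of each part
    matches the dataset's within one record.  Deterministic in ``seed``.
    """
    if not records:
        raise ValueError("cannot split an empty record list")
    sizes = apportion(len(records), fractions)
    rng = np.random.default_rng(seed)

    labelled = all(r.label is not None for r in records)
    parts: list[list[ProteinRecord]] = [[], [], []]
    if labelled and any(r.label == 1 for r in records) and any(r.label == 0 for r in records):
        pos = [r for r in records if r.label == 1]
        neg = [r for r in records if r.label == 0]
        pos_sizes = apportion(len(pos), fractions)
        neg_sizes = [s - p for s, p in zip(sizes, pos_sizes)]
        if any(s < 0 for s in neg_sizes):  # extreme imbalance edge case
            neg_sizes = apportion(len(neg), fractions)
            pos_sizes = [s - g for s, g in zip(sizes, neg_sizes)]
        for group, gsizes in ((pos, pos_sizes), (neg, neg_sizes)):
            idx = rng.permutation(len(group))
            start = 0
            for k, gs in enumerate(gsizes):
                parts[k].extend(group[i] for i in idx[start : start + gs])
                start += gs
    else:
        idx = rng.permutation(len(records))
        start = 0
        for k, s in enumerate(sizes):
            parts[k].extend(records[i] for i in idx[start : start + s])
            start += s

    for part in parts:
        part.sort(key=lambda r: r.id)
    split = DatasetSplit(parts[0], parts[1], parts[2], tuple(fractions), seed)
    assert split.sizes == tuple(sizes)
    return split


def truncate_sequence(record: ProteinRecord, max_len: int = 6000) -> ProteinRecord:
    """Keep the N-terminal ``max_len``-residue prefix of over-length sequences.

    Proteins longer than ``max_len`` amino acids are truncated; id, species
    and label are unchanged.  Truncation events are logged.
    """
    if max_len < 1:
        raise ValueError("max_len must be >= 1")
    if len(record.sequence) <= max_len:
        return record
    logger.info(
        "truncating %s from %d to %d residues (N-terminal prefix kept)",
        record.id, len(record.sequence), max_len,
    )
    return replace(record, sequence=record.sequence[:max_len])


def _kmer_set(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def kmer_identity(a: str, b: str, k: int = 3) -> float:
    """Estimate pairwise identity as the fraction of the shorter sequence's
    k-mers found in the longer one.  Crude but monotone in true identity for
    the clustering use below."""
    if len(a) < len(b):
        a, b = b, a
    if len(b) < k:
        return 1.0 if b in a else 0.0
    kb = _kmer_set(b, k)
    ka = _kmer_set(a, k)
    return len(kb & ka) / len(kb)


def dedup_by_identity(
    records: Sequence[ProteinRecord], threshold: float = 0.25, k: int = 3
) -> list[ProteinRecord]:
    """Greedy longest-first redundancy removal at a given identity threshold.

    This is a documented k-mer-based approximation of CD-HIT-style
    clustering, adequate for dataset construction: records are visited
    longest first (ties by id), each record either joins the first existing
    representative whose estimated identity is >= threshold or founds a new
    cluster.  Representatives are returned sorted longest first.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must be in (0, 1]")
    logger.info(
        "dedup_by_identity: greedy %d-mer identity approximation at threshold %.2f "
        "(not an exact CD-HIT replication)", k, threshold,
    )
    ordered = sorted(records, key=lambda r: (-len(r.sequence), r.id))
    reps: list[ProteinRecord] = []
    for rec in ordered:
        if not any(kmer_identity(rep.sequence, rec.sequence, k) >= threshold for rep in reps):
            reps.append(rec)
    return reps
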