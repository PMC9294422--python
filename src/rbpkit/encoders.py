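"""Hand-crafted per-protein feature encoders.

Four classic sequence representations used in RBP prediction:

* **PSSM-400** — an L x 20 evolutionary profile collapsed to 20 x 20 = 400
  values by summing, for each residue type, the profile rows at positions
  holding that residue (with a BLOSUM62 fallback profile when no
  PSI-BLAST PSSM is available).
* **C-T-D** — composition / transition / distribution over physicochemical
  residue classes (7 property groupings x 3 classes -> 147 values).
* **Conjoint triad** — frequencies of the 343 class-triads over 7 residue
  classes clustered by side-chain dipole and volume.
* **PAAC** — type-1 pseudo amino acid composition: 20 frequencies plus
  ``lam`` sequence-order correlation factors.

Column convention: every 20-wide amino-acid axis in this package is ordered
alphabetically by one-letter code (``ACDEFGHIKLMNPQRSTVWY``).  Files in
other orders (e.g. PSI-BLAST output) are reordered on read.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .seqio import STANDARD_AA, _STANDARD_SET

logger = logging.getLogger(__name__)

AA_INDEX = {aa: i for i, aa in enumerate(STANDARD_AA)}

PSSM_SOURCES = ("psiblast", "blosum62_fallback", "synthetic")


@dataclass
class PSSMProfile:
    """L x 20 evolutionary score matrix for one protein.

    Columns follow the alphabetical amino-acid ordering of this package.
    """

    protein_id: str
    matrix: np.ndarray
    source: str = "psiblast"

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 20:
            raise ValueError(
                f"{self.protein_id}: PSSM must be L x 20, got {self.matrix.shape}"
            )
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError(f"{self.protein_id}: non-finite PSSM entries")
        if self.source not in PSSM_SOURCES:
            raise ValueError(f"unknown PSSM source {self.source!r}")

    def __len__(self) -> int:
        return self.matrix.shape[0]


@dataclass
class FeatureSet:
    """Fixed-width numeric representation of one protein."""

    protein_id: str
    vector: np.ndarray
    encoder_name: str

    def __post_init__(self) -> None:
        self.vector = np.asarray(self.vector, dtype=float).ravel()
        if not np.all(np.isfinite(self.vector)):
            raise ValueError(f"{self.protein_id}: non-finite feature values")

    @property
    def width(self) -> int:
        return self.vector.size


# --------------------------------------------------------------------------
# PSSM-400 and the BLOSUM62 fallback profile
# --------------------------------------------------------------------------

def encode_pssm400(pssm: PSSMProfile, sequence: str) -> FeatureSet:
    """Collapse an L x 20 profile to the 400-dimensional PSSM-400 feature.

    For each residue type ``a`` the 20-wide block ``a`` is the elementwise
    sum of the profile rows at positions where the sequence has residue
    ``a`` (a zero block when ``a`` is absent); the 20 blocks are then
    concatenated in alphabetical residue order, giving 20 x 20 = 400 values.
    """
    if len(pssm) != len(sequence):
        raise ValueError(
            f"{pssm.protein_id}: PSSM has {len(pssm)} rows but sequence has "
            f"{len(sequence)} residues"
        )
    blocks = np.zeros((20, 20))
    for pos, aa in enumerate(sequence):
        blocks[AA_INDEX[aa]] += pssm.matrix[pos]
    return FeatureSet(pssm.protein_id, blocks.ravel(), "pssm400")


def _blosum62_rows() -> np.ndarray:
    """20 x 20 BLOSUM62 block in alphabetical order, loaded from Biopython."""
    from Bio.Align import substitution_matrices

    mat = substitution_matrices.load("BLOSUM62")
    out = np.empty((20, 20))
    for i, a in enumerate(STANDARD_AA):
        for j, b in enumerate(STANDARD_AA):
            out[i, j] = mat[a, b]
    return out


_BLOSUM62: np.ndarray | None = None


def blosum62_profile(sequence: str, protein_id: str = "") -> PSSMProfile:
    """Substitute profile for proteins without a PSI-BLAST PSSM: row t is the
    BLOSUM62 substitution-score row of residue t."""
    global _BLOSUM62
    if _BLOSUM62 is None:
        _BLOSUM62 = _blosum62_rows()
    rows = np.array([_BLOSUM62[AA_INDEX[aa]] for aa in sequence])
    return PSSMProfile(protein_id or "", rows, source="blosum62_fallback")


# --------------------------------------------------------------------------
# C-T-D
# --------------------------------------------------------------------------

# Three-class residue groupings per physicochemical property (Dubchak-style
# global description; classes listed low/medium/high or the field's
# conventional order).  Secondary structure and solvent accessibility are
# residue-propensity groupings: no structure prediction is run.
CTD_GROUPS: dict[str, tuple[str, str, str]] = {
    "hydrophobicity": ("RKEDQN", "GASTPHY", "CLVIMFW"),
    "vdw_volume": ("GASTPDC", "NVEQIL", "MHKFRYW"),
    "polarity": ("LIFWCMVY", "PATGS", "HQRKNED"),
    "polarizability": ("GASDT", "CPNVEQIL", "KMHFRYW"),
    "charge": ("KR", "ANCQGHILMFPSTWYV", "DE"),
    "secondary_structure": ("EALMQKRH", "VIYCWFT", "GNPSD"),
    "solvent_accessibility": ("ALFCGIVW", "RKQEND", "MPSTHY"),
}

CTD_WIDTH_PER_PROPERTY = 3 + 3 + 15  # composition + transition + distribution


def _class_string(sequence: str, groups: tuple[str, str, str]) -> np.ndarray:
    lut = np.zeros(26, dtype=int)
    for cls, members in enumerate(groups):
        for aa in members:
            lut[ord(aa) - 65] = cls
    return lut[[ord(c) - 65 for c in sequence]]


def encode_ctd(
    sequence: str,
    properties: Sequence[str] = tuple(CTD_GROUPS),
    protein_id: str = "",
) -> FeatureSet:
    """Composition-transition-distribution encoding.

    Per property: residues map into 3 classes; *composition* is the 3 class
    frequencies; *transition* is the 3 frequencies of adjacent unordered
    class pairs (1-2, 1-3, 2-3) among the L-1 adjacent pairs; *distribution*
    gives, for each class, the positions (as percent of L) of its first
    occurrence and of the occurrences nearest the 25%, 50%, 75% and 100%
    quantiles of its occurrence count (0 when the class is absent).
    Width = n_properties x 21 (147 with the default 7 properties).
    """
    if not sequence:
        raise ValueError("empty sequence")
    L = len(sequence)
    out: list[float] = []
    for prop in properties:
        classes = _class_string(sequence, CTD_GROUPS[prop])
        # composition
        comp = np.bincount(classes, minlength=3) / L
        out.extend(comp)
        # transition: unordered adjacent pairs (0,1), (0,2), (1,2)
        if L >= 2:
            a, b = classes[:-1], classes[1:]
            n_pairs = L - 1
            for c1, c2 in ((0, 1), (0, 2), (1, 2)):
                cnt = np.sum(((a == c1) & (b == c2)) | ((a == c2) & (b == c1)))
                out.append(cnt / n_pairs)
        else:
            out.extend([0.0, 0.0, 0.0])
        # distribution
        for cls in range(3):
            positions = np.flatnonzero(classes == cls) + 1  # 1-based
            if positions.size == 0:
                out.extend([0.0] * 5)
                continue
            n = positions.size
            for frac in (0.0, 0.25, 0.50, 0.75, 1.0):
                # occurrence nearest each quantile (half-up), frac 0 -> first
                k = max(1, int(np.floor(frac * n + 0.5)))
                out.append(100.0 * positions[k - 1] / L)
    name = "ctd" if tuple(properties) == tuple(CTD_GROUPS) else (
        "ctd[" + ",".join(properties) + "]"
    )
    return FeatureSet(protein_id, np.array(out), name)


# --------------------------------------------------------------------------
# Conjoint triad
# --------------------------------------------------------------------------

# Seven residue classes by side-chain dipole scale and volume.
CONJOINT_CLASSES = ("AGV", "ILFP", "YMTS", "HNQW", "RK", "DE", "C")

_CT_LUT = np.zeros(26, dtype=int)
for _cls, _members in enumerate(CONJOINT_CLASSES):
    for _aa in _members:
        _CT_LUT[ord(_aa) - 65] = _cls


def conjoint_triad_counts(sequence: str) -> np.ndarray:
    """Raw counts of the 343 class-triads over the L-2 sliding windows."""
    if len(sequence) < 3:
        raise ValueError("conjoint triad needs length >= 3")
    cls = _CT_LUT[[ord(c) - 65 for c in sequence]]
    codes = cls[:-2] * 49 + cls[1:-1] * 7 + cls[2:]
    return np.bincount(codes, minlength=343).astype(float)


def encode_conjoint_triad(sequence: str, protein_id: str = "") -> FeatureSet:
    """343-dimensional conjoint-triad frequencies, normalized by the maximum
    count (the all-zero case cannot arise for a valid length >= 3 input)."""
    counts = conjoint_triad_counts(sequence)
    peak = counts.max()
    vec = counts / peak if peak > 0 else counts
    return FeatureSet(protein_id, vec, "conjoint_triad")


# --------------------------------------------------------------------------
# PAAC
# --------------------------------------------------------------------------

# Chou's original property tables: hydrophobicity, hydrophilicity and
# side-chain mass, keyed in alphabetical residue order.
_PAAC_HYDROPHOBICITY = {
    "A": 0.62, "C": 0.29, "D": -0.90, "E": -0.74, "F": 1.19, "G": 0.48,
    "H": -0.40, "I": 1.38, "K": -1.50, "L": 1.06, "M": 0.64, "N": -0.78,
    "P": 0.12, "Q": -0.85, "R": -2.53, "S": -0.18, "T": -0.05, "V": 1.08,
    "W": 0.81, "Y": 0.26,
}
_PAAC_HYDROPHILICITY = {
    "A": -0.5, "C": -1.0, "D": 3.0, "E": 3.0, "F": -2.5, "G": 0.0,
    "H": -0.5, "I": -1.8, "K": 3.0, "L": -1.8, "M": -1.3, "N": 0.2,
    "P": 0.0, "Q": 0.2, "R": 3.0, "S": 0.3, "T": -0.4, "V": -1.5,
    "W": -3.4, "Y": -2.3,
}
_PAAC_SIDECHAIN_MASS = {
    "A": 15.0, "C": 47.0, "D": 59.0, "E": 73.0, "F": 91.0, "G": 1.0,
    "H": 82.0, "I": 57.0, "K": 73.0, "L": 57.0, "M": 75.0, "N": 58.0,
    "P": 42.0, "Q": 72.0, "R": 101.0, "S": 31.0, "T": 45.0, "V": 43.0,
    "W": 130.0, "Y": 107.0,
}


def _normalized_paac_properties() -> np.ndarray:
    """3 x 20 array of standardized property values (zero mean, unit
    population standard deviation over the 20 amino acids)."""
    rows = []
    for table in (_PAAC_HYDROPHOBICITY, _PAAC_HYDROPHILICITY, _PAAC_SIDECHAIN_MASS):
        v = np.array([table[aa] for aa in STANDARD_AA])
        rows.append((v - v.mean()) / v.std())
    return np.stack(rows)


_PAAC_PROPS = _normalized_paac_properties()


def encode_paac(
    sequence: str, lam: int = 30, weight: float = 0.05, protein_id: str = ""
) -> FeatureSet:
    """Type-1 pseudo amino acid composition (width 20 + lam).

    The first 20 entries are amino-acid frequencies; the last ``lam`` are
    sequence-order correlation factors theta_k, the mean over positions of
    the mean squared difference of three standardized residue properties
    (hydrophobicity, hydrophilicity, side-chain mass) at sequence distance
    k.  All entries share the denominator sum(f) + weight * sum(theta).
    """
    if lam < 0:
        raise ValueError("lam must be non-negative")
    if weight <= 0:
        raise ValueError("weight must be positive")
    L = len(sequence)
    if L <= lam:
        raise ValueError(f"sequence length {L} must exceed lam={lam}")
    idx = np.array([AA_INDEX[aa] for aa in sequence])
    freqs = np.bincount(idx, minlength=20) / L
    props = _PAAC_PROPS[:, idx]  # 3 x L
    thetas = np.empty(lam)
    for k in range(1, lam + 1):
        diff = props[:, :-k] - props[:, k:]
        thetas[k - 1] = np.mean(diff**2, axis=0).mean()
    denom = freqs.sum() + weight * thetas.sum()
    vec = np.concatenate([freqs, weight * thetas]) / denom
    return FeatureSet(protein_id, vec, f"paac(lam={lam},w={weight})")


# --------------------------------------------------------------------------
# Composition and recipes
# --------------------------------------------------------------------------

def concat_features(parts: Sequence[FeatureSet]) -> FeatureSet:
    """Concatenate feature sets of one protein in the given order."""
    if not parts:
        raise ValueError("nothing to concatenate")
    ids = {p.protein_id for p in parts}
    if len(ids) > 1:
        raise ValueError(f"protein_id mismatch across parts: {sorted(ids)}")
    if len(parts) == 1:
        return parts[0]
    vec = np.concatenate([p.vector for p in parts])
    name = "+".join(p.encoder_name for p in parts)
    return FeatureSet(parts[0].protein_id, vec, name)


# Composite recipes mirroring earlier RBP predictors: an evolutionary
# profile + physicochemical recipe (890 wide), a physicochemical-only
# recipe (490), and a profile + composition recipe.
RECIPES: dict[str, tuple[str, ...]] = {
    "pssm400": ("pssm400",),
    "ctd": ("ctd",),
    "triad": ("triad",),
    "paac": ("paac",),
    "pssm400+ctd+triad": ("pssm400", "ctd", "triad"),
    "ctd+triad": ("ctd", "triad"),
    "pssm400+ctd+paac": ("pssm400", "ctd", "paac"),
}


def encode_recipe(
    sequence: str,
    recipe: str,
    protein_id: str = "",
    pssm: PSSMProfile | None = None,
    lam: int = 30,
    weight: float = 0.05,
) -> FeatureSet:
    """Encode one protein with a named recipe of concatenated encoders.

    When a recipe needs a PSSM and none is given, the BLOSUM62 fallback
    profile is used (with a warning).
    """
    if recipe not in RECIPES:
        raise ValueError(f"unknown recipe {recipe!r}; known: {sorted(RECIPES)}")
    parts = []
    for step in RECIPES[recipe]:
        if step == "pssm400":
            prof = pssm
            if prof is None:
                logger.warning(
                    "%s: no PSSM available, using BLOSUM62 fallback profile", protein_id
                )
                prof = blosum62_profile(sequence, protein_id)
            fs = encode_pssm400(prof, sequence)
            parts.append(FeatureSet(protein_id, fs.vector, fs.encoder_name))
        elif step == "ctd":
            parts.append(encode_ctd(sequence, protein_id=protein_id))
        elif step == "triad":
            parts.append(encode_conjoint_triad(sequence, protein_id=protein_id))
        elif step == "paac":
            parts.append(encode_paac(sequence, lam=lam, weight=weight, protein_id=protein_id))
    return concat_features(parts)


# --------------------------------------------------------------------------
# PSSM file parsing and feature table IO
# --------------------------------------------------------------------------

def read_pssm(path: str | Path, protein_id: str = "") -> PSSMProfile:
    """Read a PSSM from PSI-BLAST ASCII output or a plain L x 20 matrix.

    The dialect is auto-detected: a PSI-BLAST file carries a header line of
    amino-acid column labels and per-row position/residue prefixes; a plain
    file has exactly 20 whitespace-separated numbers per row (assumed
    already in alphabetical column order).  PSI-BLAST columns are reordered
    to the package's alphabetical convention.
    """
    path = Path(path)
    lines = [ln.rstrip("\n") for ln in path.read_text().splitlines()]
    pid = protein_id or path.stem

    # locate a PSI-BLAST header: >= 20 single-letter AA tokens
    header_order: list[str] | None = None
    header_idx = -1
    for i, ln in enumerate(lines[:6]):
        toks = ln.split()
        letters = [t for t in toks if len(t) == 1 and t in _STANDARD_SET]
        if len(letters) >= 20:
            header_order = letters[:20]
            header_idx = i
            break

    rows: list[list[float]] = []
    if header_order is not None:
        for ln in lines[header_idx + 1 :]:
            toks = ln.split()
            if len(toks) < 22 or not toks[0].isdigit():
                if rows:
                    break
                continue
            if toks[1] not in _STANDARD_SET and toks[1] != "X":
                raise ValueError(f"{path}: unexpected residue column '{toks[1]}'")
            rows.append([float(t) for t in toks[2:22]])
        perm = [header_order.index(aa) for aa in STANDARD_AA]
        matrix = np.array(rows)[:, perm]
        return PSSMProfile(pid, matrix, source="psiblast")

    for ln in lines:
        toks = ln.split()
        if not toks:
            continue
        if len(toks) != 20:
            raise ValueError(f"{path}: plain PSSM rows need 20 columns, got {len(toks)}")
        rows.append([float(t) for t in toks])
    if not rows:
        raise ValueError(f"{path}: no PSSM rows found")
    return PSSMProfile(pid, np.array(rows), source="psiblast")


def write_pssm(pssm: PSSMProfile, path: str | Path) -> None:
    """Write a plain whitespace-delimited L x 20 matrix (alphabetical order)."""
    np.savetxt(path, pssm.matrix, fmt="%.6g")


def write_feature_table(features: Iterable[FeatureSet], path: str | Path) -> None:
    """Write features as a wide TSV: id column + one column per dimension."""
    feats = list(features)
    if not feats:
        raise ValueError("no features to write")
    widths = {f.width for f in feats}
    if len(widths) > 1:
        raise ValueError(f"inconsistent feature widths: {sorted(widths)}")
    width = widths.pop()
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("id\t" + "\t".join(f"f{i+1}" for i in range(width)) + "\n")
        for f in feats:
            fh.write(f.protein_id + "\t" + "\t".join(f"{v:.10g}" for v in f.vector) + "\n")


def read_feature_table(path: str | Path, encoder_name: str = "table") -> list[FeatureSet]:
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    if df.columns[0] != "id":
        raise ValueError(f"{path}: first column must be 'id'")
    return [
        FeatureSet(str(row[0]), np.asarray(row[1:], dtype=float), encoder_name)
        for row in df.itertuples(index=False)
    ]


def save_features_npz(features: Iterable[FeatureSet], path: str | Path) -> None:
    """Compact binary table keyed by protein id."""
    np.savez_compressed(path, **{f.protein_id: f.vector for f in features})


def load_features_npz(path: str | Path, encoder_name: str = "npz") -> list[FeatureSet]:
    with np.load(path) as data:
        return [FeatureSet(pid, data[pid], encoder_name) for pid in data.files]
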