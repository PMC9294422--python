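"""Synthetic fixtures: domain-shifted labeled embedding datasets, toy
protein sequences with class-dependent residue composition, and random
PSSM profiles.

The embedding generator emulates the geometry the transfer-learning setting
needs: every domain shares one discriminative direction for the positive
class, each species domain rotates that direction by an angle ``theta`` in
a fixed 2-plane (its domain shift relative to the pre-training reference),
and labels are drawn at a ~1:10 positive:negative ratio.  The default
transfer benchmark mirrors the 1 pre-training + 4 species layout at desk
scale: a large unrotated pre-training domain, a "eukaryote-like" pair of
mid-size domains with a small shared rotation, and a "prokaryote-like"
pair of small domains with a larger shared rotation.

All generators are pure functions of their spec + seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .encoders import FeatureSet, PSSMProfile
from .seqio import STANDARD_AA, ProteinRecord


@dataclass(frozen=True)
class DomainSpec:
    """One labeled embedding domain."""

    name: str
    n_samples: int
    pos_ratio: float = 1.0 / 11.0
    dim: int = 16
    delta: float = 2.0  # class-mean separation along the discriminative direction
    theta: float = 0.0  # rotation of that direction vs the reference domain
    sigma: float = 1.0  # isotropic noise scale
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.pos_ratio < 1.0:
            raise ValueError("pos_ratio must be in (0, 1)")
        if self.dim < 2:
            raise ValueError("dim must be >= 2")
        if not 0.0 <= self.theta <= np.pi / 2:
            raise ValueError("theta must be in [0, pi/2]")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")


@dataclass
class LabeledFeatures:
    """Features plus labels for one domain, convertible to model arrays."""

    name: str
    features: list[FeatureSet]
    labels: np.ndarray

    def arrays(self) -> tuple[np.ndarray, np.ndarray]:
        X = np.stack([f.vector for f in self.features])
        return X, np.asarray(self.labels, dtype=int)

    @property
    def pos_ratio(self) -> float:
        return float(np.mean(self.labels))

    def __len__(self) -> int:
        return len(self.features)


def _direction(dim: int, theta: float) -> np.ndarray:
    """Reference unit direction e_0 rotated by theta in the (e_0, e_1) plane."""
    u = np.zeros(dim)
    u[0] = np.cos(theta)
    u[1] = np.sin(theta)
    return u


def gen_embedding_domain(spec: DomainSpec) -> LabeledFeatures:
    """Draw one labeled embedding domain.

    Labels ~ Bernoulli(pos_ratio); features = mu_y + Gaussian noise, where
    mu_1 - mu_0 = delta * u_theta and mu_0 = 0.
    """
    rng = np.random.default_rng(spec.seed)
    y = (rng.random(spec.n_samples) < spec.pos_ratio).astype(int)
    u = _direction(spec.dim, spec.theta)
    X = rng.normal(scale=spec.sigma, size=(spec.n_samples, spec.dim))
    X += np.outer(y, spec.delta * u)
    feats = [
        FeatureSet(f"{spec.name}_{i:05d}", X[i], f"synthetic:{spec.name}")
        for i in range(spec.n_samples)
    ]
    return LabeledFeatures(spec.name, feats, y)


def gen_transfer_benchmark(
    seed: int = 0,
    dim: int = 16,
    delta: float = 2.0,
    sigma: float = 1.0,
    pos_ratio: float = 1.0 / 11.0,
) -> tuple[LabeledFeatures, list[LabeledFeatures]]:
    """Default transfer-learning testbed: one pre-training domain plus four
    species domains.

    Layout (desk-scaled): pretrain n=5000 at theta=0; species A, B n=600 at
    theta=0.15 (eukaryote-like pair sharing a small rotation); species C
    n=300 and D n=200 at theta=0.45 (prokaryote-like pair, larger shift).
    """
    specs = [
        DomainSpec("pretrain", 5000, pos_ratio, dim, delta, 0.0, sigma, seed),
        DomainSpec("speciesA", 600, pos_ratio, dim, delta, 0.15, sigma, seed + 1),
        DomainSpec("speciesB", 600, pos_ratio, dim, delta, 0.15, sigma, seed + 2),
        DomainSpec("speciesC", 300, pos_ratio, dim, delta, 0.45, sigma, seed + 3),
        DomainSpec("speciesD", 200, pos_ratio, dim, delta, 0.45, sigma, seed + 4),
    ]
    domains = [gen_embedding_domain(s) for s in specs]
    return domains[0], domains[1:]


# Background residue frequencies, roughly uniform with mild realism; the
# class bias below perturbs them for positives.
_BACKGROUND = np.full(20, 1.0 / 20.0)


def gen_sequences(
    n: int,
    length_range: tuple[int, int] = (50, 300),
    class_bias: dict[str, float] | None = None,
    pos_ratio: float = 1.0 / 11.0,
    seed: int = 0,
    species: str = "synthetic",
) -> list[ProteinRecord]:
    """Labeled toy sequences with class-dependent residue composition.

    Positives are drawn from the background residue distribution perturbed
    by ``class_bias`` (residue -> additive frequency shift, renormalized;
    e.g. ``{"E": 0.03, "S": 0.03, "P": 0.03}`` echoes the elevated
    glutamate/serine/proline content of human RBPs); negatives come from
    the unperturbed background.  Lengths are uniform in ``length_range``.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    lo, hi = length_range
    if not 1 <= lo <= hi:
        raise ValueError("invalid length range")
    bias = np.zeros(20)
    for aa, shift in (class_bias or {}).items():
        bias[STANDARD_AA.index(aa)] = shift
    pos_freq = _BACKGROUND + bias
    if pos_freq.min() < 0:
        raise ValueError("class_bias drives a residue frequency negative")
    pos_freq = pos_freq / pos_freq.sum()

    rng = np.random.default_rng(seed)
    records = []
    aas = np.array(list(STANDARD_AA))
    for i in range(n):
        label = int(rng.random() < pos_ratio)
        L = int(rng.integers(lo, hi + 1))
        freq = pos_freq if label else _BACKGROUND
        seq = "".join(rng.choice(aas, size=L, p=freq))
        records.append(
            ProteinRecord(f"{species}_{i:05d}", seq, species=species, label=label)
        )
    return records


def gen_pssm(sequence: str, seed: int = 0, elevation: float = 6.0) -> PSSMProfile:
    """Random integer-like L x 20 profile with the true residue's column
    elevated at every position (a PSI-BLAST-shaped fixture for encoder
    tests)."""
    rng = np.random.default_rng(seed)
    L = len(sequence)
    matrix = rng.integers(-5, 6, size=(L, 20)).astype(float)
    for pos, aa in enumerate(sequence):
        matrix[pos, STANDARD_AA.index(aa)] += elevation
    return PSSMProfile("synthetic", matrix, source="synthetic")
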