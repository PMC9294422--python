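"""Probability calibration and genome-scale proteome screening.

Raw classifier scores are turned into confidence levels by single-parameter
temperature scaling: a temperature T > 0 is fitted on a labeled validation
set to minimize the negative log-likelihood of sigmoid(score / T), which
rescales confidence without changing the ranking (AUC is preserved
exactly).  A screened proteome is then summarized by counting predictions
whose calibrated confidence is strictly greater than each threshold in
{0.5, 0.6, 0.7, 0.8, 0.9}.

Before scoring, proteins that appeared in the training data (matched by
exact id or exact sequence) are excluded, and sequences longer than 6000
amino acids are truncated to their N-terminal 6000 residues.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Iterable, Optional, Sequence

import numpy as np
from scipy.optimize import minimize_scalar

from . import model as M
from .objectives import PROB_EPS, LabeledScores
from .seqio import ProteinRecord, truncate_sequence

logger = logging.getLogger(__name__)

CONFIDENCE_THRESHOLDS = (0.5, 0.6, 0.7, 0.8, 0.9)


@dataclass
class CalibrationMap:
    """Monotone map from raw logits to calibrated confidence."""

    method: str = "temperature"  # or "identity"
    temperature: float = 1.0
    nll_before: float = float("nan")
    nll_after: float = float("nan")

    def __post_init__(self) -> None:
        if self.method not in ("temperature", "identity"):
            raise ValueError(f"unknown calibration method {self.method!r}")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")

    def __call__(self, logits: np.ndarray) -> np.ndarray:
        logits = np.asarray(logits, dtype=float)
        if self.method == "identity":
            return M.sigmoid(logits)
        return M.sigmoid(logits / self.temperature)


def _nll(logits: np.ndarray, y: np.ndarray, T: float) -> float:
    p = np.clip(M.sigmoid(logits / T), PROB_EPS, 1 - PROB_EPS)
    return float(-np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))


def fit_calibration(
    logits: np.ndarray,
    y: np.ndarray,
    method: str = "temperature",
) -> CalibrationMap:
    """Fit a calibration map on validation logits and labels.

    The temperature method minimizes the validation negative log-likelihood
    of sigmoid(logit / T) by a 1-D search over log T.  Strictly monotone in
    the logit, so the score ranking (and hence AUC) is unchanged.
    """
    logits = np.asarray(logits, dtype=float).ravel()
    y = np.asarray(y, dtype=int).ravel()
    if logits.shape != y.shape:
        raise ValueError("logits and labels must have equal length")
    if y.min() == y.max():
        raise ValueError("calibration needs both classes in the validation set")
    if method == "identity":
        return CalibrationMap("identity", 1.0)
    res = minimize_scalar(
        lambda logT: _nll(logits, y, float(np.exp(logT))),
        bounds=(-6.0, 6.0),
        method="bounded",
        options={"xatol": 1e-10},
    )
    T = float(np.exp(res.x))
    cal = CalibrationMap("temperature", T, _nll(logits, y, 1.0), _nll(logits, y, T))
    logger.info("temperature calibration: T=%.4f, NLL %.4f -> %.4f",
                T, cal.nll_before, cal.nll_after)
    return cal


@dataclass
class ScreenedProtein:
    id: str
    confidence: Optional[float]
    truncated: bool = False
    excluded: bool = False
    exclusion_reason: str = ""


@dataclass
class ScreenResult:
    proteins: list[ScreenedProtein]
    bin_counts: dict[float, int]
    thresholds: tuple[float, ...] = CONFIDENCE_THRESHOLDS

    @property
    def n_scored(self) -> int:
        return sum(1 for p in self.proteins if not p.excluded)

    @property
    def n_excluded(self) -> int:
        return sum(1 for p in self.proteins if p.excluded)

    def to_tsv(self) -> str:
        lines = ["id\tconfidence\ttruncated\texcluded\treason"]
        for p in self.proteins:
            conf = "" if p.confidence is None else f"{p.confidence:.6f}"
            lines.append(
                f"{p.id}\t{conf}\t{int(p.truncated)}\t{int(p.excluded)}\t{p.exclusion_reason}"
            )
        return "\n".join(lines) + "\n"

    def summary_tsv(self) -> str:
        lines = ["confidence_level\tpredicted_positives"]
        for t in self.thresholds:
            lines.append(f">{t:.0%}\t{self.bin_counts[t]}")
        return "\n".join(lines) + "\n"


def summarize_bins(
    confidences: Sequence[float],
    thresholds: tuple[float, ...] = CONFIDENCE_THRESHOLDS,
) -> dict[float, int]:
    """Count confidences strictly greater than each threshold."""
    conf = np.asarray(confidences, dtype=float)
    if conf.size and (conf.min() <= 0.0 or conf.max() >= 1.0):
        raise ValueError("confidences must lie in (0, 1)")
    return {t: int(np.sum(conf > t)) for t in thresholds}


def screen_proteome(
    records: Sequence[ProteinRecord],
    params: M.ClassifierParams,
    featurizer: Callable[[ProteinRecord], np.ndarray],
    calib: Optional[CalibrationMap] = None,
    exclude_ids: Iterable[str] = (),
    exclude_sequences: Iterable[str] = (),
    max_len: int = 6000,
) -> ScreenResult:
    """Score a whole proteome and summarize predictions by confidence bin.

    Proteins whose id or exact sequence appears in the exclusion sets are
    dropped with reason "training overlap".  Survivors are truncated to
    ``max_len`` residues, featurized, scored in eval mode (deterministic)
    and calibrated.  The output is sorted by protein id.
    """
    calib = calib or CalibrationMap("identity")
    id_set = set(exclude_ids)
    seq_set = set(exclude_sequences)
    out: list[ScreenedProtein] = []
    kept: list[tuple[int, ProteinRecord]] = []
    n_trunc = 0
    for rec in sorted(records, key=lambda r: r.id):
        if rec.id in id_set or rec.sequence in seq_set:
            out.append(ScreenedProtein(rec.id, None, excluded=True,
                                       exclusion_reason="training overlap"))
            continue
        truncated = len(rec.sequence) > max_len
        if truncated:
            rec = truncate_sequence(rec, max_len)
            n_trunc += 1
        out.append(ScreenedProtein(rec.id, None, truncated=truncated))
        kept.append((len(out) - 1, rec))

    if not kept:
        logger.warning("screening: no proteins survive exclusion")
        return ScreenResult(out, {t: 0 for t in CONFIDENCE_THRESHOLDS})

    X = np.stack([featurizer(rec) for _, rec in kept])
    logits, _ = M.forward(X, params, mode="eval")
    conf = calib(logits)
    for (pos, _), c in zip(kept, conf):
        out[pos].confidence = float(c)
    logger.info("screened %d proteins (%d excluded, %d truncated)",
                len(kept), len(out) - len(kept), n_trunc)
    return ScreenResult(out, summarize_bins(conf))
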