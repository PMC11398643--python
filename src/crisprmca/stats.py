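"""Class-imbalance diagnostics and mismatch profiling.

Three scalar metrics quantify how skewed a labeled off-target dataset is:

* **IR** (imbalance ratio): negatives / positives.
* **CVIR**: coefficient of variation (population sigma / mean) of the two
  class proportions {p, q}.  Since p + q = 1 this equals |q - p|; the
  literal sigma/mu form is computed so the identity is testable.
* **IE** (information entropy): Shannon entropy of the label distribution
  in bits, H = -p log2 p - q log2 q; 1 at perfect balance.

Severity bands follow the IR: < 200 mild, 200-1000 moderate, >= 1000
severe.  A "balanced" band (IR < 40) is additionally reported for
post-rebalancing summaries; the boundary is a documented heuristic since
published labelings near the balanced/mild border are not monotone in IR.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import DatasetFormatError, UndefinedRatioError
from .pairs import DNA_BASES, GuideTargetPair

#: IR thresholds for (balanced, mild, moderate) upper bounds.
BALANCED_MAX_IR = 40.0
MILD_MAX_IR = 200.0
MODERATE_MAX_IR = 1000.0

SEVERITIES = ("balanced", "mild", "moderate", "severe")


def imbalance_ratio(n_pos: int, n_neg: int) -> float:
    """Negatives over positives; undefined (raises) when there are no positives."""
    if n_pos <= 0:
        raise UndefinedRatioError("imbalance ratio undefined: no positive samples")
    return n_neg / n_pos


def cvir(n_pos: int, n_neg: int) -> float:
    """Coefficient of variation of the two class proportions.

    Computed literally as population sigma over mean of {p, q}; for a
    binary dataset this reduces to |q - p|.
    """
    total = n_pos + n_neg
    if total <= 0:
        raise DatasetFormatError("cvir undefined for an empty dataset")
    p = n_pos / total
    q = n_neg / total
    mean = (p + q) / 2.0
    sigma = math.sqrt(((p - mean) ** 2 + (q - mean) ** 2) / 2.0)
    return sigma / mean


def information_entropy(n_pos: int, n_neg: int) -> float:
    """Shannon entropy (bits) of the label distribution; 0*log0 := 0."""
    total = n_pos + n_neg
    if total <= 0:
        raise DatasetFormatError("entropy undefined for an empty dataset")
    h = 0.0
    for n in (n_pos, n_neg):
        prop = n / total
        if prop > 0.0:
            h -= prop * math.log2(prop)
    return h


def classify_imbalance(ir: float) -> str:
    """Map an imbalance ratio to a severity class."""
    if ir < BALANCED_MAX_IR:
        return "balanced"
    if ir < MILD_MAX_IR:
        return "mild"
    if ir < MODERATE_MAX_IR:
        return "moderate"
    return "severe"


@dataclass(frozen=True)
class ImbalanceReport:
    """Counts plus IR / CVIR / IE and the severity class for one dataset."""

    n_pos: int
    n_neg: int
    ir: float
    cvir: float
    ie: float
    severity: str

    @property
    def total(self) -> int:
        return self.n_pos + self.n_neg

    @classmethod
    def from_counts(cls, n_pos: int, n_neg: int) -> "ImbalanceReport":
        ir = imbalance_ratio(n_pos, n_neg)
        return cls(
            n_pos=n_pos,
            n_neg=n_neg,
            ir=ir,
            cvir=cvir(n_pos, n_neg),
            ie=information_entropy(n_pos, n_neg),
            severity=classify_imbalance(ir),
        )

    @classmethod
    def from_pairs(cls, pairs: list[GuideTargetPair]) -> "ImbalanceReport":
        labels = [p.label for p in pairs]
        if any(lab is None for lab in labels):
            raise DatasetFormatError("imbalance report requires labeled records")
        return cls.from_counts(sum(labels), len(labels) - sum(labels))

    def format(self, name: str = "dataset") -> str:
        return (
            f"{name}: total={self.total} pos={self.n_pos} neg={self.n_neg} "
            f"IR={self.ir:.4f} CVIR={self.cvir:.4f} IE={self.ie:.4f} [{self.severity}]"
        )


@dataclass(frozen=True)
class MismatchProfile:
    """Per-position mismatch counts and a 4x4 guide-base x target-base matrix.

    Positions are reported 1-based from the PAM-distal end (PAM at 21-23 for
    23-mers).  ``type_matrix`` is aggregated over all positions, rows =
    guide base, columns = target base, ordered A, C, G, T; its diagonal is
    zero by construction.
    """

    position_counts: np.ndarray
    type_matrix: np.ndarray

    @property
    def total_mismatches(self) -> int:
        return int(self.position_counts.sum())


def mismatch_profile(
    pairs: list[GuideTargetPair], positives_only: bool = True
) -> MismatchProfile:
    """Count mismatch positions and substitution types over gap-free pairs.

    ``positives_only`` restricts the count to label==1 records, matching how
    off-target mismatch-tolerance profiles are normally drawn.
    """
    selected = [p for p in pairs if (not positives_only) or p.label == 1]
    if any(p.has_gap for p in selected):
        raise DatasetFormatError(
            "mismatch_profile supports mismatches-only (gap-free) records"
        )
    length = len(selected[0].guide) if selected else 23
    base_idx = {b: i for i, b in enumerate(DNA_BASES)}
    position_counts = np.zeros(length, dtype=np.int64)
    type_matrix = np.zeros((4, 4), dtype=np.int64)
    for p in selected:
        if len(p.guide) != length:
            raise DatasetFormatError("mixed-length pairs in mismatch_profile")
        for i, (g, t) in enumerate(zip(p.guide, p.target)):
            if g != t:
                position_counts[i] += 1
                type_matrix[base_idx[g], base_idx[t]] += 1
    return MismatchProfile(position_counts, type_matrix)
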