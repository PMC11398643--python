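"""Shared fixtures and independent oracles for the test suite.

The oracle functions here deliberately re-derive results by exhaustive /
brute-force means (window-by-window genome scans, threshold sweeps,
per-position summation) so that the package's vectorized implementations
are checked against an independent computation path.
"""
from __future__ import annotations

import numpy as np
import pytest

from crisprmca.pairs import DNA_BASES, GuideTargetPair, reverse_complement
from crisprmca.scoring import GUIDE_LENGTH, ScoreTable


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------

def brute_force_sites(guide: str, genome: dict[str, str], max_mm: int):
    """Exhaustive per-window scan over both strands; the genome-search oracle.

    Returns a set of (chrom, start, strand, n_mismatch, site_seq) tuples with
    forward-strand coordinates, applying the same matching contract as the
    scanner: trailing NGG with a real base in the N slot, mismatches counted
    over the 20-nt protospacer, ambiguous characters never matching.
    """
    hits = set()
    for chrom, raw in genome.items():
        seq = raw.upper()
        n = len(seq)
        for strand in "+-":
            s = seq if strand == "+" else reverse_complement(seq)
            for off in range(n - 22):
                win = s[off : off + 23]
                if win[21] != "G" or win[22] != "G" or win[20] not in "ACGT":
                    continue
                mm = sum(a != b for a, b in zip(win[:20], guide))
                if mm <= max_mm:
                    start = off if strand == "+" else n - 23 - off
                    hits.add((chrom, start, strand, mm, win))
    return hits


def sweep_metrics(labels, scores, threshold=0.5):
    """Brute-force Recall / ROC-AUC / PR-AUC from first principles.

    ROC-AUC by pair counting (ties count half); PR-AUC as the step
    integral sum_n (R_n - R_{n-1}) P_n over thresholds at every distinct
    score, descending.
    """
    labels = np.asarray(labels, dtype=int)
    scores = np.asarray(scores, dtype=float)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    n_pos, n_neg = len(pos), len(neg)
    recall = float(((scores >= threshold) & (labels == 1)).sum() / n_pos)
    greater = sum((p > n).sum() for p, n in [(pos[:, None], neg[None, :])])
    ties = sum((p == n).sum() for p, n in [(pos[:, None], neg[None, :])])
    roc = float((greater + 0.5 * ties) / (n_pos * n_neg))
    ap = 0.0
    r_prev = 0.0
    for t in np.sort(np.unique(scores))[::-1]:
        pred = scores >= t
        tp = int((pred & (labels == 1)).sum())
        fp = int((pred & (labels == 0)).sum())
        precision = tp / (tp + fp)
        r = tp / n_pos
        ap += (r - r_prev) * precision
        r_prev = r
    return {"recall": recall, "roc_auc": roc, "pr_auc": float(ap)}


def random_pairs(rng: np.random.Generator, n: int, length: int = 23, labeled=True):
    """Random gap-free guide/target records for property tests."""
    out = []
    for i in range(n):
        guide = "".join(rng.choice(list(DNA_BASES), size=length - 3)) + rng.choice(list(DNA_BASES)) + "GG"
        target = list(guide)
        for pos in rng.choice(length - 3, size=rng.integers(0, 5), replace=False):
            target[pos] = rng.choice([b for b in DNA_BASES if b != target[pos]])
        out.append(
            GuideTargetPair(
                guide=guide,
                target="".join(target),
                label=int(rng.random() < 0.3) if labeled else None,
                source_id=f"rand:{i}",
            )
        )
    return out


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def score_table() -> ScoreTable:
    return ScoreTable.synthetic(seed=7)


@pytest.fixture(scope="session")
def zero_table() -> ScoreTable:
    return ScoreTable(v=np.zeros((GUIDE_LENGTH, 4, 4)), a=1.0, b=0.5)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240903)
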