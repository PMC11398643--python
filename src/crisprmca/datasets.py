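"""Published benchmark dataset summaries.

Positive/negative record counts for the nine public off-target benchmark
datasets commonly used in this area (GUIDE-seq, SITE-seq, CIRCLE-seq,
Digenome-seq derived collections), and the positive counts after ESB
rebalancing of the mismatches-only subsets.  These are printed summary
numbers shipped as inputs for imbalance arithmetic; the raw datasets
themselves are optional external downloads.
"""
from __future__ import annotations

from .stats import ImbalanceReport

#: dataset name -> (n_pos, n_neg)
BENCHMARK_COUNTS: dict[str, tuple[int, int]] = {
    "Hek293t": (536, 132378),
    "K562": (120, 20199),
    "D3": (54, 95775),
    "D4": (354, 294180),
    "D5": (56, 383407),
    "D6": (3767, 213966),
    "D7": (52, 10077),
    "D8": (7371, 577578),
    "D9": (50, 213883),
}

#: Mismatches-only datasets: positive count after ESB rebalancing.
REBALANCED_POSITIVES: dict[str, int] = {
    "D6": 41412,
    "K562": 1076,
    "D7": 327,
    "Hek293t": 4935,
    "D4": 3381,
    "D3": 330,
    "D5": 281,
}


def benchmark_report(name: str) -> ImbalanceReport:
    """Imbalance report for one of the published benchmark datasets."""
    n_pos, n_neg = BENCHMARK_COUNTS[name]
    return ImbalanceReport.from_counts(n_pos, n_neg)


def rebalanced_ir(name: str) -> float:
    """Post-ESB imbalance ratio: original negatives over rebalanced positives."""
    _, n_neg = BENCHMARK_COUNTS[name]
    return n_neg / REBALANCED_POSITIVES[name]
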