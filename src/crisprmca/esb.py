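"""Efficiency-and-Specificity-Based (ESB) class rebalancing.

Off-target datasets are extremely positive-poor.  ESB augments the
positive class with *single-substitution mutants* of positive-sample
guides that survive two screens:

1. **Efficiency**: every one of the 60 single-base variants of the 20-nt
   guide is scored against the parent record's target; only variants
   scoring *strictly* above the parent pass.
2. **Specificity**: candidate off-target sites for each surviving variant
   are enumerated genome-wide (NGG PAM, small mismatch tolerance), and an
   aggregate specificity score S_on / (S_on + sum S_off) is computed; only
   variants strictly more specific than the parent guide pass.

Surviving variants are paired with the parent record's target DNA as new
positive training records.  Rebalancing is applied to the training split
only; any variant whose guide coincides with a test-set guide is dropped,
and exact (guide, target) duplicates are removed from both splits.

The strategy is defined for mismatches-only data; bulge-aligned records
cannot be screened (gaps break both the score lookup and the genome scan).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import DatasetFormatError, InvalidAlphabetError
from .pairs import DNA_BASES, GuideTargetPair, dedupe_pairs, reverse_complement
from .scoring import GUIDE_LENGTH, ScoreTable, crisot_score

SITE_LENGTH = 23  # 20-nt protospacer + NGG PAM

_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}
_G_CODE = 2


# ---------------------------------------------------------------------------
# variant enumeration
# ---------------------------------------------------------------------------

@dataclass
class GuideVariant:
    """A single-substitution mutant of a positive-sample guide."""

    parent_guide: str
    position: int          # 1-based over the 20-nt protospacer
    new_base: str
    sequence: str
    efficiency: float | None = None
    specificity: float | None = None
    passed_phase1: bool = False
    passed_phase2: bool = False


def enumerate_single_substitutions(guide: str) -> list[GuideVariant]:
    """All 20 x 3 = 60 Hamming-distance-1 variants of a gap-free 20-mer.

    Deterministic ordering: position ascending, replacement base A < C < G < T.
    """
    if len(guide) != GUIDE_LENGTH or any(ch not in _CODE for ch in guide):
        raise InvalidAlphabetError(
            f"expected a gap-free {GUIDE_LENGTH}-mer guide, got {guide!r}"
        )
    variants = []
    for pos in range(GUIDE_LENGTH):
        for base in DNA_BASES:
            if base == guide[pos]:
                continue
            seq = guide[:pos] + base + guide[pos + 1:]
            variants.append(
                GuideVariant(parent_guide=guide, position=pos + 1, new_base=base, sequence=seq)
            )
    return variants


def efficiency_screen(
    parent_pair: GuideTargetPair, variants: list[GuideVariant], table: ScoreTable
) -> list[GuideVariant]:
    """Phase 1: keep variants strictly more efficient than the parent guide.

    Efficiency is the table score against the parent record's target
    protospacer (first 20 nt); ties are rejected.
    """
    target20 = parent_pair.target[:GUIDE_LENGTH]
    parent_eff = crisot_score(parent_pair.guide[:GUIDE_LENGTH], target20, table)
    passing = []
    for v in variants:
        v.efficiency = crisot_score(v.sequence, target20, table)
        v.passed_phase1 = v.efficiency > parent_eff
        if v.passed_phase1:
            passing.append(v)
    return passing


# ---------------------------------------------------------------------------
# genome candidate search (Cas-Offinder-style NGG scan)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OffTargetCandidate:
    """A 23-mer genomic window (protospacer + NGG) near-matching a guide.

    ``start`` is the 0-based half-open start of the 23-mer window on the
    forward strand regardless of ``strand``; ``site_seq`` is read on the
    strand carrying the PAM.
    """

    site_seq: str
    chrom: str
    start: int
    strand: str
    n_mismatch: int

    @property
    def protospacer(self) -> str:
        return self.site_seq[:GUIDE_LENGTH]

    @property
    def end(self) -> int:
        return self.start + SITE_LENGTH


def _encode_seq(seq: str) -> np.ndarray:
    # non-ACGT characters (N, ...) -> 4: never equal to any base, never a G
    arr = np.full(len(seq), 4, dtype=np.int8)
    for base, code in _CODE.items():
        arr[np.frombuffer(seq.encode(), dtype=np.uint8) == ord(base)] = code
    return arr


def _scan_strand(seq: str, arr: np.ndarray, guide_arr: np.ndarray, max_mm: int):
    """Yield (offset_on_this_strand, site_seq, n_mismatch) for NGG windows."""
    n = len(arr)
    if n < SITE_LENGTH:
        return
    windows = np.lib.stride_tricks.sliding_window_view(arr, SITE_LENGTH)
    # PAM: position 20 is N (any real base), 21-22 must be G; ambiguous
    # characters never match a base, so they fail GG and the N slot alike.
    pam_ok = (windows[:, 20] <= 3) & (windows[:, 21] == _G_CODE) & (windows[:, 22] == _G_CODE)
    mism = (windows[:, :GUIDE_LENGTH] != guide_arr[None, :]).sum(axis=1)
    hits = np.nonzero(pam_ok & (mism <= max_mm))[0]
    for off in hits:
        yield int(off), seq[off : off + SITE_LENGTH], int(mism[off])


def find_candidate_sites(
    guide: str,
    genome: dict[str, str] | str,
    max_mm: int = 1,
) -> list[OffTargetCandidate]:
    """All NGG-adjacent genomic windows within ``max_mm`` of a 20-nt guide.

    Both strands are scanned; mismatches are counted over the 20-nt
    protospacer only and ambiguous genome characters never match (they
    count as mismatches in the protospacer, fail the GG requirement, and
    are not accepted in the N slot).  Results are sorted by
    (chrom, start, strand).
    """
    if len(guide) != GUIDE_LENGTH or any(ch not in _CODE for ch in guide):
        raise InvalidAlphabetError(f"expected a gap-free 20-mer guide, got {guide!r}")
    if max_mm < 0:
        raise DatasetFormatError(f"max_mm must be >= 0, got {max_mm}")
    if isinstance(genome, str):
        genome = {"seq": genome}
    guide_arr = _encode_seq(guide)
    out: list[OffTargetCandidate] = []
    for chrom, raw in genome.items():
        seq = raw.upper()
        n = len(seq)
        fwd = _encode_seq(seq)
        for off, site, mm in _scan_strand(seq, fwd, guide_arr, max_mm):
            out.append(OffTargetCandidate(site, chrom, off, "+", mm))
        rc = reverse_complement(seq.replace("_", "N"))
        rc_arr = _encode_seq(rc)
        for off, site, mm in _scan_strand(rc, rc_arr, guide_arr, max_mm):
            out.append(OffTargetCandidate(site, chrom, n - SITE_LENGTH - off, "-", mm))
    out.sort(key=lambda c: (c.chrom, c.start, c.strand))
    return out


# ---------------------------------------------------------------------------
# specificity
# ---------------------------------------------------------------------------

def specificity_score(
    guide: str,
    on_target: str,
    candidates: list[OffTargetCandidate],
    table: ScoreTable,
) -> float:
    """Aggregate specificity S_on / (S_on + sum_off S_off) in [0, 1].

    ``on_target`` is the guide's intended 20-nt protospacer; candidate
    windows whose protospacer equals it are treated as the on-target locus
    and excluded from the off-target sum.  With no remaining candidates the
    guide is perfectly specific (1.0); a zero on-target score with
    competing candidates scores 0.0.
    """
    s_on = crisot_score(guide, on_target, table)
    offs = [c for c in candidates if c.protospacer != on_target]
    if not offs:
        return 1.0
    if s_on == 0.0:
        return 0.0
    s_off = sum(crisot_score(guide, c.protospacer, table) for c in offs)
    return s_on / (s_on + s_off)


# ---------------------------------------------------------------------------
# full rebalancing pass
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EsbConfig:
    """Knobs for the rebalancing pass."""

    max_mm: int = 1
    seed: int = 0


@dataclass
class EsbResult:
    """Augmented training split, deduplicated test split, and audit trail."""

    train: list[GuideTargetPair]
    test: list[GuideTargetPair]
    audit: pd.DataFrame

    @property
    def n_new_positives(self) -> int:
        return int(self.audit["n_added"].sum()) if len(self.audit) else 0


def esb_rebalance(
    train: list[GuideTargetPair],
    test: list[GuideTargetPair],
    genome: dict[str, str] | str,
    table: ScoreTable,
    config: EsbConfig | None = None,
) -> EsbResult:
    """Run both ESB screens over every positive training record.

    Original records (positive and negative) are never modified or removed
    (beyond exact-duplicate removal); accepted variants are appended as new
    positives pairing the mutated guide (parent PAM retained) with the
    parent record's target DNA.  The audit frame records per-parent counts
    at each stage.
    """
    config = config or EsbConfig()
    positives = [p for p in train if p.label == 1]
    audit_rows = []
    if not positives:
        warnings.warn("esb_rebalance: no positive records in the training split; no-op")
        return EsbResult(
            dedupe_pairs(list(train)),
            dedupe_pairs(list(test)),
            pd.DataFrame(
                columns=[
                    "parent_guide", "n_variants", "n_pass_efficiency",
                    "n_pass_specificity", "n_after_leakage", "n_added",
                ]
            ),
        )
    for p in positives:
        if p.has_gap:
            raise DatasetFormatError(
                "esb_rebalance supports mismatches-only data; bulge-aligned "
                f"record found (source_id={p.source_id!r})"
            )

    test_guides = {p.guide for p in test}
    existing = {(p.guide, p.target) for p in train}
    candidate_cache: dict[str, list[OffTargetCandidate]] = {}
    spec_cache: dict[str, float] = {}

    def _specificity(guide20: str) -> float:
        if guide20 not in spec_cache:
            if guide20 not in candidate_cache:
                candidate_cache[guide20] = find_candidate_sites(guide20, genome, config.max_mm)
            spec_cache[guide20] = specificity_score(
                guide20, guide20, candidate_cache[guide20], table
            )
        return spec_cache[guide20]

    new_records: list[GuideTargetPair] = []
    for parent in positives:
        guide20 = parent.guide[:GUIDE_LENGTH]
        pam = parent.guide[GUIDE_LENGTH:]
        variants = enumerate_single_substitutions(guide20)
        phase1 = efficiency_screen(parent, variants, table)
        phase2: list[GuideVariant] = []
        if phase1:
            parent_spec = _specificity(guide20)
            for v in phase1:
                v.specificity = _specificity(v.sequence)
                v.passed_phase2 = v.specificity > parent_spec
                if v.passed_phase2:
                    phase2.append(v)
        kept = [v for v in phase2 if (v.sequence + pam) not in test_guides]
        added = 0
        for v in kept:
            rec = GuideTargetPair(
                guide=v.sequence + pam,
                target=parent.target,
                label=1,
                source_id=f"esb:{parent.source_id}:{v.position}{v.new_base}",
            )
            if (rec.guide, rec.target) not in existing:
                existing.add((rec.guide, rec.target))
                new_records.append(rec)
                added += 1
        audit_rows.append(
            {
                "parent_guide": parent.guide,
                "n_variants": len(variants),
                "n_pass_efficiency": len(phase1),
                "n_pass_specificity": len(phase2),
                "n_after_leakage": len(kept),
                "n_added": added,
            }
        )

    augmented = dedupe_pairs(list(train) + new_records)
    return EsbResult(augmented, dedupe_pairs(list(test)), pd.DataFrame(audit_rows))
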