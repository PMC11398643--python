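"""Guide/target sequence records.

A dataset row is one aligned guide-RNA / target-DNA pair with an optional
binary activity label.  Mismatches-only data use 23-mers (20-nt protospacer
+ 3-nt PAM); data with bulges use 24-mers in which ``_`` marks the unpaired
side of an insertion/deletion.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

from .errors import InvalidAlphabetError, PairValidationError

#: Valid symbols after normalization.
ALPHABET = frozenset("ACGT_")

#: DNA bases (no gap), in the conventional order used for count matrices.
DNA_BASES = "ACGT"

_COMPLEMENT = str.maketrans("ACGTN_", "TGCAN_")


def normalize_sequence(raw: str) -> str:
    """Uppercase a sequence and replace uracil by thymine.

    Guide RNAs are reported over {A, C, G, U}; target DNA over {A, C, G, T};
    ``_`` marks a bulge.  Any other symbol raises
    :class:`~crisprmca.errors.InvalidAlphabetError` naming the 1-based
    offending position.
    """
    if not raw:
        raise InvalidAlphabetError("empty sequence")
    seq = raw.upper().replace("U", "T")
    for i, ch in enumerate(seq):
        if ch not in ALPHABET:
            raise InvalidAlphabetError(
                f"invalid symbol {ch!r} at position {i + 1} in {raw!r}"
            )
    return seq


def reverse_complement(seq: str) -> str:
    """Reverse complement over {A,C,G,T,N}; gaps map to themselves."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GuideTargetPair:
    """One aligned guide/target record, the atomic dataset unit.

    Attributes
    ----------
    guide, target : str
        Equal-length sequences over {A,C,G,T,_}; length 23 (mismatches only)
        or 24 (bulge-aligned).
    label : int or None
        1 = validated off-target activity, 0 = inactive, None = unlabeled.
    source_id : str
        Opaque provenance tag (dataset name, line number, parent guide, ...).
    """

    guide: str
    target: str
    label: int | None = None
    source_id: str = ""

    @classmethod
    def from_raw(
        cls,
        guide: str,
        target: str,
        label: int | None = None,
        source_id: str = "",
    ) -> "GuideTargetPair":
        """Normalize (uppercase, U->T) and validate a raw record."""
        pair = cls(normalize_sequence(guide), normalize_sequence(target), label, source_id)
        pair.validate()
        return pair

    def validate(self) -> None:
        if len(self.guide) != len(self.target):
            raise PairValidationError(
                f"guide length {len(self.guide)} != target length {len(self.target)}"
                f" (source_id={self.source_id!r})"
            )
        if len(self.guide) not in (23, 24):
            raise PairValidationError(
                f"pair length {len(self.guide)} not in (23, 24) (source_id={self.source_id!r})"
            )
        for seq in (self.guide, self.target):
            for i, ch in enumerate(seq):
                if ch not in ALPHABET:
                    raise InvalidAlphabetError(
                        f"invalid symbol {ch!r} at position {i + 1} (source_id={self.source_id!r})"
                    )
        for i, (g, t) in enumerate(zip(self.guide, self.target)):
            if g == "_" and t == "_":
                raise PairValidationError(
                    f"both strands gapped at position {i + 1} (source_id={self.source_id!r})"
                )
        if self.label not in (0, 1, None):
            raise PairValidationError(f"label must be 0/1/None, got {self.label!r}")

    @property
    def has_gap(self) -> bool:
        return "_" in self.guide or "_" in self.target

    @property
    def n_mismatches(self) -> int:
        """Number of positions where guide and target differ (gaps count)."""
        return sum(g != t for g, t in zip(self.guide, self.target))

    def with_label(self, label: int | None) -> "GuideTargetPair":
        return replace(self, label=label)


def dedupe_pairs(pairs: list[GuideTargetPair]) -> list[GuideTargetPair]:
    """Drop exact (guide, target) duplicates, keeping the first occurrence."""
    seen: set[tuple[str, str]] = set()
    out: list[GuideTargetPair] = []
    for p in pairs:
        key = (p.guide, p.target)
        if key not in seen:
            seen.add(key)
            out.append(p)
    return out
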