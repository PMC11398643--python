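"""Position- and base-pair-resolved guide/target activity scoring.

The efficiency score of a 20-nt guide against a 20-nt target is an affine
map of a sum of per-position contributions,

    S = clip(a * sum_i v[i, g_i, t_i] + b, 0, 1),

where ``v`` is a lookup over (position 1..20, guide base, target base).
Published interaction-fingerprint scoring schemes of this family reduce,
after aggregating their molecular features per base pair and position, to
exactly such a table; the CSV format below lets users plug published
values in.  A seeded synthetic table ships for testing: it favors matches,
penalizes PAM-proximal mismatches more than PAM-distal ones, and carries
mild base-pair-type structure plus reproducible noise.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InvalidAlphabetError
from .pairs import DNA_BASES

GUIDE_LENGTH = 20

_BASE_IDX = {b: i for i, b in enumerate(DNA_BASES)}


def _encode20(seq: str) -> np.ndarray:
    if len(seq) != GUIDE_LENGTH:
        raise InvalidAlphabetError(
            f"expected a {GUIDE_LENGTH}-mer, got length {len(seq)}: {seq!r}"
        )
    try:
        return np.array([_BASE_IDX[ch] for ch in seq], dtype=np.int64)
    except KeyError as exc:
        raise InvalidAlphabetError(
            f"invalid symbol {exc.args[0]!r} in {seq!r} (gap-free ACGT required)"
        ) from None


@dataclass(frozen=True)
class ScoreTable:
    """Per-(position, guide base, target base) contributions + affine map.

    Attributes
    ----------
    v : ndarray, shape (20, 4, 4)
        Contribution of base pair (guide_base, target_base) at each of the
        20 protospacer positions (1-based position i stored at v[i-1]);
        bases ordered A, C, G, T.
    a, b : float
        Affine constants mapping the summed contributions into [0, 1]
        (the mapped score is additionally clipped).
    """

    v: np.ndarray
    a: float
    b: float

    def __post_init__(self) -> None:
        if self.v.shape != (GUIDE_LENGTH, 4, 4):
            raise ConfigurationError(f"score table must be (20,4,4), got {self.v.shape}")
        if not np.isfinite(self.v).all():
            raise ConfigurationError("score table contains non-finite entries")
        if self.a <= 0:
            raise ConfigurationError(f"affine scale a must be > 0, got {self.a}")

    # -- construction -----------------------------------------------------

    @classmethod
    def from_values(cls, v: np.ndarray) -> "ScoreTable":
        """Build a table with a, b fitted so attainable sums span [0, 1].

        a = 1/(S_max - S_min), b = -S_min * a over the per-position extrema;
        a degenerate (constant) table maps its single attainable sum to 0.5.
        """
        v = np.asarray(v, dtype=float)
        s_min = float(v.min(axis=(1, 2)).sum())
        s_max = float(v.max(axis=(1, 2)).sum())
        if np.isclose(s_min, s_max):
            return cls(v=v, a=1.0, b=0.5 - s_min)
        a = 1.0 / (s_max - s_min)
        return cls(v=v, a=a, b=-s_min * a)

    @classmethod
    def synthetic(cls, seed: int = 0) -> "ScoreTable":
        """Seeded synthetic table with realistic qualitative structure.

        Matches contribute ~1; mismatches contribute a fraction set by a
        per-position tolerance (high PAM-distal: positions 1-3 and 8-9,
        low PAM-proximal: 10-20) times a base-pair affinity, plus small
        Gaussian noise so single-substitution screens have non-trivial,
        reproducible signal.
        """
        rng = np.random.default_rng(seed)
        tolerance = np.full(GUIDE_LENGTH, 0.45)
        tolerance[0:3] = 0.85        # PAM-distal, well tolerated
        tolerance[7:9] = 0.75
        tolerance[9:] = 0.20         # PAM-proximal, poorly tolerated
        # guide-base x target-base affinity; wobble-like pairs elevated
        affinity = np.full((4, 4), 0.5)
        g, a_, c, t = (_BASE_IDX[b] for b in "GACT")
        affinity[g, a_] = 0.9
        affinity[t, c] = 0.85
        affinity[g, t] = 0.8
        affinity[a_, c] = 0.75
        affinity[g, c] = 0.7
        v = np.empty((GUIDE_LENGTH, 4, 4))
        for i in range(GUIDE_LENGTH):
            v[i] = tolerance[i] * affinity
            np.fill_diagonal(v[i], 1.0)
        v += rng.normal(0.0, 0.03, size=v.shape)
        return cls.from_values(v)

    # -- scoring -----------------------------------------------------------

    def raw_sum(self, guide: str, target: str) -> float:
        gi = _encode20(guide)
        ti = _encode20(target)
        return float(self.v[np.arange(GUIDE_LENGTH), gi, ti].sum())

    def score(self, guide: str, target: str) -> float:
        """Affine-mapped, clipped efficiency score in [0, 1]."""
        return float(np.clip(self.a * self.raw_sum(guide, target) + self.b, 0.0, 1.0))

    # -- serialization ------------------------------------------------------

    def to_csv(self, path: str | Path) -> None:
        """Write the table: '# a:'/'# b:' comment lines + a 400-row CSV."""
        rows = []
        for i in range(GUIDE_LENGTH):
            for gb in DNA_BASES:
                for tb in DNA_BASES:
                    rows.append((i + 1, gb, tb, self.v[i, _BASE_IDX[gb], _BASE_IDX[tb]]))
        frame = pd.DataFrame(rows, columns=["position", "guide_base", "target_base", "score"])
        with open(path, "w") as fh:
            fh.write(f"# a: {self.a!r}\n# b: {self.b!r}\n")
            frame.to_csv(fh, index=False, float_format="%.17g")

    @classmethod
    def from_csv(cls, path: str | Path) -> "ScoreTable":
        a = b = None
        with open(path) as fh:
            lines = fh.readlines()
        data_lines = []
        for line in lines:
            if line.startswith("#"):
                key, _, value = line.lstrip("# ").partition(":")
                if key.strip() == "a":
                    a = float(value)
                elif key.strip() == "b":
                    b = float(value)
            else:
                data_lines.append(line)
        if not data_lines or not data_lines[0].lower().startswith("position"):
            raise ConfigurationError(f"score table {path}: missing header row")
        from io import StringIO

        frame = pd.read_csv(StringIO("".join(data_lines)), float_precision="round_trip")
        required = {"position", "guide_base", "target_base", "score"}
        if not required.issubset(frame.columns):
            raise ConfigurationError(f"score table {path}: columns {required} required")
        v = np.full((GUIDE_LENGTH, 4, 4), np.nan)
        for row in frame.itertuples(index=False):
            pos = int(row.position)
            if not 1 <= pos <= GUIDE_LENGTH:
                raise ConfigurationError(f"score table {path}: position {pos} out of 1..20")
            v[pos - 1, _BASE_IDX[row.guide_base], _BASE_IDX[row.target_base]] = row.score
        if np.isnan(v).any():
            missing = int(np.isnan(v).sum())
            raise ConfigurationError(
                f"score table {path}: incomplete, {missing} (position, pair) entries missing"
            )
        if a is None or b is None:
            return cls.from_values(v)
        return cls(v=v, a=a, b=b)


def crisot_score(guide: str, target: str, table: ScoreTable) -> float:
    """Efficiency score of a gap-free 20-mer guide against a 20-mer target."""
    return table.score(guide, target)
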