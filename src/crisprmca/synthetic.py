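"""Synthetic off-target datasets and toy genomes.

Real genome-wide off-target screens share three statistical signatures
that this generator emulates so every pipeline stage is testable without
external downloads:

* extreme positive:negative imbalance (imbalance ratios from tens to
  thousands),
* poor tolerance of PAM-proximal mismatches — mismatches in validated
  sites concentrate in the PAM-distal half, especially positions 1-3 and
  8-9 of the protospacer,
* non-uniform mismatch-type usage (wobble-like substitutions such as
  G-A, T-C, G-T, A-C are over-represented).

Records are 23-mers (20-nt protospacer + NGG PAM; the guide's PAM
positions copy the target's, so mismatches occur only over positions
1-20).  Labels come from a latent efficiency score (the same score-table
machinery used by the ESB screens) plus Gaussian noise, thresholded at
the quantile that hits the requested imbalance ratio — so positives are
genuinely the high-efficiency pairs and the rebalancing screens have true
signal to find.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import SimulationError
from .pairs import DNA_BASES, GuideTargetPair, reverse_complement
from .scoring import GUIDE_LENGTH, ScoreTable

_BASE_IDX = {b: i for i, b in enumerate(DNA_BASES)}

#: Default per-position mismatch weights over the 20-nt protospacer
#: (1-based positions 1..20, PAM-distal first): high at 1-3 and 8-9,
#: moderate at 4-7, low in the PAM-proximal half.
DEFAULT_POSITION_WEIGHTS = tuple(
    [3.0, 3.0, 3.0] + [1.2] * 4 + [3.0, 3.0] + [0.4] * 11
)

def _default_type_weights() -> np.ndarray:
    w = np.ones((4, 4))
    np.fill_diagonal(w, 0.0)
    g, a, c, t = (_BASE_IDX[b] for b in "GACT")
    w[g, a] = 3.0   # guide G opposite target A
    w[t, c] = 3.0
    w[g, t] = 2.0
    w[a, c] = 2.0
    w[g, c] = 1.5
    return w


@dataclass
class SimConfig:
    """Conditions for one synthetic dataset.

    ``ir_target`` is the desired negatives/positives ratio; generation
    fails if it cannot be achieved within ±10%.  ``seed`` is mandatory —
    every draw comes from one generator seeded with it.
    """

    seed: int
    n_guides: int = 10
    records_per_guide: int = 1000
    ir_target: float = 100.0
    position_weights: tuple[float, ...] = DEFAULT_POSITION_WEIGHTS
    type_weights: np.ndarray = field(default_factory=_default_type_weights)
    max_mismatches: int = 4
    mismatch_count_weights: tuple[float, ...] = (0.0005, 0.03, 0.17, 0.35, 0.45)
    noise_sd: float = 0.05
    score_table: ScoreTable | None = None

    def validate(self) -> None:
        pw = np.asarray(self.position_weights, dtype=float)
        if pw.shape != (GUIDE_LENGTH,) or (pw < 0).any() or pw.sum() <= 0:
            raise SimulationError("position_weights must be 20 nonnegative values summing > 0")
        tw = np.asarray(self.type_weights, dtype=float)
        if tw.shape != (4, 4) or (tw < 0).any():
            raise SimulationError("type_weights must be a nonnegative 4x4 matrix")
        if np.diag(tw).any():
            raise SimulationError("type_weights diagonal must be zero (no self-substitution)")
        if not 0 <= self.max_mismatches <= 6:
            raise SimulationError("max_mismatches must be within 0..6")
        if len(self.mismatch_count_weights) != self.max_mismatches + 1:
            raise SimulationError(
                "mismatch_count_weights must have max_mismatches + 1 entries"
            )


def _random_20mer(rng: np.random.Generator) -> str:
    return "".join(rng.choice(list(DNA_BASES), size=GUIDE_LENGTH))


def _mutate(guide: str, k: int, cfg: SimConfig, rng: np.random.Generator) -> str:
    """Apply k substitutions at positions/types drawn from the config weights."""
    if k == 0:
        return guide
    pw = np.asarray(cfg.position_weights, dtype=float)
    pw = pw / pw.sum()
    positions = rng.choice(GUIDE_LENGTH, size=k, replace=False, p=pw)
    seq = list(guide)
    tw = np.asarray(cfg.type_weights, dtype=float)
    for pos in positions:
        row = tw[_BASE_IDX[seq[pos]]].copy()
        if row.sum() == 0:
            continue
        row /= row.sum()
        seq[pos] = DNA_BASES[rng.choice(4, p=row)]
    return "".join(seq)


def generate_dataset(cfg: SimConfig) -> list[GuideTargetPair]:
    """Draw a labeled guide/target dataset under the configured conditions.

    Deterministic under ``cfg.seed``: the same config yields a
    byte-identical dataset file.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    table = cfg.score_table or ScoreTable.synthetic(cfg.seed)
    count_w = np.asarray(cfg.mismatch_count_weights, dtype=float)
    count_w = count_w / count_w.sum()

    records: list[tuple[str, str, str]] = []
    latents: list[float] = []
    for gi in range(cfg.n_guides):
        guide20 = _random_20mer(rng)
        seen: set[str] = set()
        for rj in range(cfg.records_per_guide):
            # candidate-site lists are unique loci: rejection-sample until the
            # target sequence (incl. PAM) is new for this guide
            for _attempt in range(100):
                k = int(rng.choice(cfg.max_mismatches + 1, p=count_w))
                target20 = _mutate(guide20, k, cfg, rng)
                pam = rng.choice(list(DNA_BASES)) + "GG"
                if target20 + pam not in seen:
                    break
            else:
                raise SimulationError(
                    "could not draw a unique target; mismatch-count weights too "
                    "concentrated for records_per_guide"
                )
            seen.add(target20 + pam)
            records.append((guide20 + pam, target20 + pam, f"g{gi}:r{rj}"))
            latents.append(table.score(guide20, target20) + rng.normal(0.0, cfg.noise_sd))

    n_total = len(records)
    n_pos = int(round(n_total / (1.0 + cfg.ir_target)))
    if n_pos < 1:
        raise SimulationError(
            f"imbalance target {cfg.ir_target} unreachable with {n_total} records "
            "(would require zero positives)"
        )
    achieved = (n_total - n_pos) / n_pos
    if abs(achieved - cfg.ir_target) > 0.1 * cfg.ir_target:
        raise SimulationError(
            f"imbalance target {cfg.ir_target} unreachable; achievable ratio {achieved:.2f}"
        )
    order = np.argsort(np.asarray(latents))[::-1]
    positive_idx = set(order[:n_pos].tolist())
    return [
        GuideTargetPair(
            guide=g, target=t, label=1 if i in positive_idx else 0, source_id=sid
        )
        for i, (g, t, sid) in enumerate(records)
    ]


# ---------------------------------------------------------------------------
# toy genomes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlantedSite:
    """One protospacer+PAM site to embed in a toy genome."""

    guide: str
    n_mismatch: int = 0
    strand: str = "+"


def generate_toy_genome(
    length: int,
    planted: list[PlantedSite | tuple],
    seed: int = 0,
    chrom: str = "chr1",
) -> tuple[dict[str, str], pd.DataFrame]:
    """Random background sequence with recorded protospacer+NGG insertions.

    Returns the genome (single named sequence) and a truth table listing
    each planted site's coordinates, strand, mismatch count and the site
    sequence as written on its own strand.  Sites are placed at random
    non-overlapping starts; an unplaceable request raises
    :class:`~crisprmca.errors.SimulationError`.
    """
    rng = np.random.default_rng(seed)
    sites = [p if isinstance(p, PlantedSite) else PlantedSite(*p) for p in planted]
    site_len = GUIDE_LENGTH + 3
    if length < site_len * len(sites):
        raise SimulationError(f"{len(sites)} sites cannot fit in length {length}")
    background = rng.choice(list(DNA_BASES), size=length)
    occupied: list[tuple[int, int]] = []
    rows = []
    for s in sites:
        proto = list(s.guide)
        if len(proto) != GUIDE_LENGTH:
            raise SimulationError(f"planted guide must be a 20-mer, got {s.guide!r}")
        if s.n_mismatch:
            positions = rng.choice(GUIDE_LENGTH, size=s.n_mismatch, replace=False)
            for pos in positions:
                alternatives = [b for b in DNA_BASES if b != proto[pos]]
                proto[pos] = alternatives[rng.integers(3)]
        site_seq = "".join(proto) + rng.choice(list(DNA_BASES)) + "GG"
        placed = False
        for _ in range(200):
            start = int(rng.integers(0, length - site_len + 1))
            end = start + site_len
            if all(end <= a or start >= b for a, b in occupied):
                occupied.append((start, end))
                placed = True
                break
        if not placed:
            raise SimulationError("could not place planted sites without overlap")
        inserted = site_seq if s.strand == "+" else reverse_complement(site_seq)
        background[start:end] = list(inserted)
        rows.append(
            {
                "chrom": chrom,
                "start": start,
                "strand": s.strand,
                "n_mismatch": s.n_mismatch,
                "site_seq": site_seq,
                "guide": s.guide,
            }
        )
    genome = {chrom: "".join(background)}
    truth = pd.DataFrame(rows, columns=["chrom", "start", "strand", "n_mismatch", "site_seq", "guide"])
    return genome, truth
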