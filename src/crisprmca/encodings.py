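"""One-hot channel encodings of guide/target pairs.

The default scheme (``C3_24x7``) turns an aligned pair into a 24x7 binary
matrix: five *base channels* and two *direction channels* per position.
Each base symbol has a one-hot code over the channel ordering (A, G, C, T, _):

    A = [1,0,0,0,0]   G = [0,1,0,0,0]   C = [0,0,1,0,0]
    T = [0,0,0,1,0]   _ = [0,0,0,0,1]

A position's base channels are the bitwise OR of the guide code and the
target code, so a match keeps that base's own one-hot (one bit) while a
mismatch or bulge sets two bits.  OR alone cannot distinguish 'GA' from
'AG', so two direction channels record which symbol comes first in the
channel ordering: [0,0] for a match, [1,0] when the guide symbol's index
precedes the target's, [0,1] otherwise.

The minimal scheme ``C1`` is the 23x4 OR encoding over (A, G, C, T); it has
no gap symbol and no direction channels.

23-mer pairs encoded under ``C3_24x7`` are padded to 24 rows with one
all-zero row *prepended*, keeping the PAM at the high-index end so that
PAM-proximal positions keep their indices across mismatch-only and bulge
datasets.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidAlphabetError, UnsupportedSchemeError
from .pairs import GuideTargetPair

#: Channel ordering for the base channels, exactly as the codes are enumerated.
CHANNEL_ORDER = "AGCT_"

_INDEX = {ch: i for i, ch in enumerate(CHANNEL_ORDER)}

SCHEMES = ("C1", "C3_24x7")


def _symbol_index(symbol: str) -> int:
    try:
        return _INDEX[symbol]
    except KeyError:
        raise InvalidAlphabetError(f"invalid symbol {symbol!r}") from None


def encode_base_channels(g: str, d: str) -> np.ndarray:
    """Five base channels for one aligned position: OR of the two one-hots.

    Both symbols gapped is rejected (an all-gap column carries no base).
    """
    gi, di = _symbol_index(g), _symbol_index(d)
    if g == "_" and d == "_":
        raise InvalidAlphabetError("both symbols are '_'")
    vec = np.zeros(5, dtype=np.int8)
    vec[gi] = 1
    vec[di] = 1
    return vec


def encode_direction_channels(g: str, d: str) -> np.ndarray:
    """Two direction channels disambiguating mismatch/bulge orientation.

    [0,0] for a match; otherwise [1,0] when the guide symbol's channel index
    is lower than the target's under (A,G,C,T,_), else [0,1].  Generalized
    from the worked examples A-T -> [1,0] and _-G -> [0,1]; isolated here so
    the rule can be swapped without touching the rest of the encoder.
    """
    gi, di = _symbol_index(g), _symbol_index(d)
    if g == "_" and d == "_":
        raise InvalidAlphabetError("both symbols are '_'")
    vec = np.zeros(2, dtype=np.int8)
    if gi < di:
        vec[0] = 1
    elif gi > di:
        vec[1] = 1
    return vec


@dataclass(frozen=True)
class EncodedPair:
    """An L x C binary matrix produced by an encoding scheme."""

    matrix: np.ndarray
    scheme_id: str

    @property
    def L(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_channels(self) -> int:
        return self.matrix.shape[1]


def encode_pair(pair: GuideTargetPair, scheme: str = "C3_24x7") -> EncodedPair:
    """Encode a normalized pair under the given scheme.

    ``C3_24x7``: per-row [5 base channels ++ 2 direction channels]; 23-mers
    are padded with a leading all-zero row to length 24.
    ``C1``: 4-channel OR encoding, gap-free input only, no padding.
    """
    if scheme not in SCHEMES:
        raise UnsupportedSchemeError(f"unknown scheme {scheme!r}; expected one of {SCHEMES}")
    pair.validate()
    if scheme == "C1":
        if pair.has_gap:
            raise UnsupportedSchemeError("scheme C1 cannot encode '_' (bulge) symbols")
        rows = []
        for g, d in zip(pair.guide, pair.target):
            vec = np.zeros(4, dtype=np.int8)
            vec[_symbol_index(g)] = 1
            vec[_symbol_index(d)] = 1
            rows.append(vec)
        return EncodedPair(np.stack(rows), "C1")

    rows = [
        np.concatenate([encode_base_channels(g, d), encode_direction_channels(g, d)])
        for g, d in zip(pair.guide, pair.target)
    ]
    matrix = np.stack(rows).astype(np.int8)
    if matrix.shape[0] == 23:
        matrix = np.vstack([np.zeros((1, 7), dtype=np.int8), matrix])
    return EncodedPair(matrix, "C3_24x7")


def _symbol_indices(seqs: list[str]) -> np.ndarray:
    """(N, L) array of channel indices for equal-length sequences."""
    joined = "".join(seqs)
    codes = np.frombuffer(joined.encode(), dtype=np.uint8).reshape(len(seqs), -1)
    out = np.full(codes.shape, -1, dtype=np.int64)
    for ch, idx in _INDEX.items():
        out[codes == ord(ch)] = idx
    if (out < 0).any():
        raise InvalidAlphabetError("invalid symbol in dataset sequences")
    return out


def encode_dataset(pairs: list[GuideTargetPair], scheme: str = "C3_24x7") -> np.ndarray:
    """Encode a homogeneous list of pairs into an (N, L, C) float32 array.

    Vectorized equivalent of stacking :func:`encode_pair` over the list
    (asserted equivalent in the test suite); pairs must share one length.
    """
    if not pairs:
        raise UnsupportedSchemeError("cannot encode an empty dataset")
    if scheme not in SCHEMES:
        raise UnsupportedSchemeError(f"unknown scheme {scheme!r}; expected one of {SCHEMES}")
    lengths = {len(p.guide) for p in pairs}
    if len(lengths) != 1:
        raise UnsupportedSchemeError("encode_dataset requires uniform-length pairs")
    g_idx = _symbol_indices([p.guide for p in pairs])
    d_idx = _symbol_indices([p.target for p in pairs])
    n, L = g_idx.shape
    if scheme == "C1":
        if (g_idx == 4).any() or (d_idx == 4).any():
            raise UnsupportedSchemeError("scheme C1 cannot encode '_' (bulge) symbols")
        X = np.zeros((n, L, 4), dtype=np.float32)
        rows = np.arange(n)[:, None]
        cols = np.arange(L)[None, :]
        X[rows, cols, g_idx] = 1.0
        X[rows, cols, d_idx] = 1.0
        return X
    both_gap = (g_idx == 4) & (d_idx == 4)
    if both_gap.any():
        raise InvalidAlphabetError("both strands gapped at an aligned position")
    X = np.zeros((n, L, 7), dtype=np.float32)
    rows = np.arange(n)[:, None]
    cols = np.arange(L)[None, :]
    X[rows, cols, g_idx] = 1.0
    X[rows, cols, d_idx] = 1.0
    X[..., 5] = g_idx < d_idx
    X[..., 6] = g_idx > d_idx
    if L == 23:
        X = np.concatenate([np.zeros((n, 1, 7), dtype=np.float32), X], axis=1)
    return X


def encoding_metadata(scheme: str) -> dict:
    """Sidecar metadata describing an encoded array (for serialization)."""
    return {
        "scheme_id": scheme,
        "channel_order": CHANNEL_ORDER if scheme == "C3_24x7" else CHANNEL_ORDER[:4],
        "direction_channels": scheme == "C3_24x7",
        "pad_convention": "prepend all-zero row for 23-mers" if scheme == "C3_24x7" else "none",
    }
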