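"""Sequence feature encoders for m7G substrate prediction.

Six encoding schemes over a fixed-length window centred on a candidate G:

``OH``
    One-hot: each base becomes a 4-bit indicator in channel order A,C,G,U
    (4L features).
``NAC``
    Nucleic-acid (dinucleotide) composition: relative frequencies of the 16
    overlapping dinucleotides AA..UU in lexicographic order (16 features).
``ANF``
    Accumulated nucleotide frequency: at position i, the frequency of the
    base s_i within the prefix s_1..s_i (L features).
``PKC``
    Pseudo k-tuple composition (Type-I PseKNC): normalized overlapping
    k-tuple frequencies augmented with lambda sequence-order correlation
    terms computed from the EIIP property profile (4^k + lambda features).
``CP``
    Chemical property: a 3-bit code per base for ring structure, functional
    group and hydrogen-bonding strength (3L features).
``EIIP``
    Electron-ion interaction pseudopotential: one fixed real value per base
    (L features).

Unknown bases (``N``, used for window padding at transcript ends) are
zero-filled by position-wise encoders and excluded from composition counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from typing import Iterable, Mapping, Sequence

import numpy as np

from .sequence_io import RNASequence, LabeledWindow

BASES = "ACGU"

#: Electron-ion interaction pseudopotential of each ribonucleotide.
EIIP_VALUES: Mapping[str, float] = {"A": 0.1260, "U": 0.1335, "C": 0.1340, "G": 0.0806}

#: 3-bit chemical-property code: (ring structure, functional group, H-bond).
#: Purines (A, G) have two rings; A and C carry an amino group; G:C pairing
#: forms three hydrogen bonds while A:U forms two.
CP_CODES: Mapping[str, tuple[int, int, int]] = {
    "A": (1, 1, 1),
    "C": (0, 1, 0),
    "G": (1, 0, 0),
    "U": (0, 0, 1),
}

#: Canonical encoder order used for every concatenation.
CANONICAL_ORDER = ("OH", "NAC", "ANF", "PKC", "CP", "EIIP")


@dataclass(frozen=True)
class EncoderConfig:
    """Tunable constants shared by the encoders.

    ``pkc_k``, ``pkc_lambda`` and ``pkc_weight`` are the Type-I PseKNC
    tuple size k, correlation depth lambda and weight w; the EIIP profile
    is the single physicochemical property behind the correlation terms.
    """

    eiip_values: Mapping[str, float] = field(default_factory=lambda: dict(EIIP_VALUES))
    cp_codes: Mapping[str, tuple[int, int, int]] = field(
        default_factory=lambda: dict(CP_CODES)
    )
    pkc_k: int = 2
    pkc_lambda: int = 2
    pkc_weight: float = 0.1

    def __post_init__(self) -> None:
        if self.pkc_k < 1:
            raise ValueError("pkc_k must be >= 1")
        if self.pkc_lambda < 0:
            raise ValueError("pkc_lambda must be >= 0")
        if not (0 < self.pkc_weight <= 1):
            raise ValueError("pkc_weight must lie in (0, 1]")


DEFAULT_CONFIG = EncoderConfig()


@dataclass(frozen=True)
class FeatureVector:
    """An encoded window: a flat numeric vector plus its block layout.

    ``blocks`` lists ``(encoder_name, length)`` pairs describing how the
    vector was concatenated; block lengths always sum to ``len(values)``.
    """

    values: np.ndarray
    blocks: tuple[tuple[str, int], ...]

    def __post_init__(self) -> None:
        total = sum(n for _, n in self.blocks)
        if total != self.values.shape[0]:
            raise ValueError(
                f"block lengths sum to {total} but vector has {self.values.shape[0]} entries"
            )

    def __len__(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class FeatureMatrix:
    """A stack of feature vectors sharing one block layout."""

    X: np.ndarray  # (n_windows, n_features)
    blocks: tuple[tuple[str, int], ...]
    y: np.ndarray | None = None  # optional binary labels

    def __post_init__(self) -> None:
        total = sum(n for _, n in self.blocks)
        if total != self.X.shape[1]:
            raise ValueError("block layout inconsistent with matrix width")


def _seq_of(seq: RNASequence | str) -> str:
    return seq.seq if isinstance(seq, RNASequence) else seq


def encode_onehot(seq: RNASequence | str, config: EncoderConfig = DEFAULT_CONFIG) -> FeatureVector:
    """Per-position 4-bit indicator, channels A,C,G,U; N -> (0,0,0,0)."""
    s = _seq_of(seq)
    out = np.zeros(4 * len(s))
    for i, c in enumerate(s):
        j = BASES.find(c)
        if j >= 0:
            out[4 * i + j] = 1.0
    return FeatureVector(out, (("OH", out.shape[0]),))


def encode_nac(seq: RNASequence | str, config: EncoderConfig = DEFAULT_CONFIG) -> FeatureVector:
    """Overlapping dinucleotide relative frequencies AA..UU (16 features).

    Dinucleotides containing N are excluded from both numerator and
    denominator; the vector sums to 1 for N-free input.
    """
    s = _seq_of(seq)
    if len(s) < 2:
        raise ValueError("NAC requires sequence length >= 2")
    counts = np.zeros(16)
    total = 0
    for i in range(len(s) - 1):
        a, b = BASES.find(s[i]), BASES.find(s[i + 1])
        if a >= 0 and b >= 0:
            counts[4 * a + b] += 1
            total += 1
    if total:
        counts /= total
    return FeatureVector(counts, (("NAC", 16),))


def encode_anf(seq: RNASequence | str, config: EncoderConfig = DEFAULT_CONFIG) -> FeatureVector:
    """Accumulated nucleotide frequency (L features).

    Entry i is the count of base s_i among s_1..s_i divided by i;
    N positions are zero-filled.
    """
    s = _seq_of(seq)
    out = np.zeros(len(s))
    running = {b: 0 for b in BASES}
    for i, c in enumerate(s):
        if c in running:
            running[c] += 1
            out[i] = running[c] / (i + 1)
    return FeatureVector(out, (("ANF", out.shape[0]),))


def encode_cp(seq: RNASequence | str, config: EncoderConfig = DEFAULT_CONFIG) -> FeatureVector:
    """Per-position chemical-property triple (3L features); N -> (0,0,0)."""
    s = _seq_of(seq)
    out = np.zeros(3 * len(s))
    for i, c in enumerate(s):
        code = config.cp_codes.get(c)
        if code is not None:
            out[3 * i : 3 * i + 3] = code
    return FeatureVector(out, (("CP", out.shape[0]),))


def encode_eiip(seq: RNASequence | str, config: EncoderConfig = DEFAULT_CONFIG) -> FeatureVector:
    """Per-position EIIP value (L features); N -> 0."""
    s = _seq_of(seq)
    out = np.array([config.eiip_values.get(c, 0.0) for c in s])
    return FeatureVector(out, (("EIIP", out.shape[0]),))


def _ktuple_frequencies(s: str, k: int) -> np.ndarray:
    """Normalized overlapping k-tuple frequencies over ACGU (length 4^k)."""
    idx = {"".join(t): i for i, t in enumerate(product(BASES, repeat=k))}
    counts = np.zeros(4**k)
    for i in range(len(s) - k + 1):
        tup = s[i : i + k]
        j = idx.get(tup)
        if j is not None:
            counts[j] += 1
    total = counts.sum()
    if total:
        counts /= total
    return counts


def encode_pkc(seq: RNASequence | str, config: EncoderConfig = DEFAULT_CONFIG) -> FeatureVector:
    """Type-I pseudo k-tuple composition (4^k + lambda features).

    The first 4^k entries are k-tuple frequencies damped by the
    sequence-order factor, d_u = f_u / (1 + w * sum_j theta_j); the last
    lambda entries are d_{4^k+j} = w * theta_j / (1 + w * sum_j theta_j)
    with theta_j the mean squared EIIP difference between bases j apart:

        theta_j = (1/(L-j)) * sum_{i=1}^{L-j} (EIIP(s_i) - EIIP(s_{i+j}))^2

    N positions take EIIP 0 in the correlation terms and N-containing
    tuples are dropped from the composition counts.  The whole vector sums
    to 1 for N-free input; with lambda = 0 and k = 2 it reduces to NAC.
    """
    s = _seq_of(seq)
    k, lam, w = config.pkc_k, config.pkc_lambda, config.pkc_weight
    L = len(s)
    if L <= k + lam:
        raise ValueError(f"PKC requires sequence length > k + lambda = {k + lam}, got {L}")
    freqs = _ktuple_frequencies(s, k)
    prop = np.array([config.eiip_values.get(c, 0.0) for c in s])
    thetas = np.empty(lam)
    for j in range(1, lam + 1):
        diffs = prop[:-j] - prop[j:]
        thetas[j - 1] = float(np.mean(diffs**2))
    denom = 1.0 + w * thetas.sum()
    out = np.concatenate([freqs / denom, w * thetas / denom])
    return FeatureVector(out, (("PKC", out.shape[0]),))


_ENCODER_FUNCS = {
    "OH": encode_onehot,
    "NAC": encode_nac,
    "ANF": encode_anf,
    "PKC": encode_pkc,
    "CP": encode_cp,
    "EIIP": encode_eiip,
}


def canonicalize_combo(encoders: Iterable[str]) -> tuple[str, ...]:
    """Validate an encoder subset and sort it into canonical order."""
    requested = set(encoders)
    if not requested:
        raise ValueError("encoder combination must be non-empty")
    unknown = requested - set(CANONICAL_ORDER)
    if unknown:
        raise ValueError(f"unknown encoder(s) {sorted(unknown)}; choose from {CANONICAL_ORDER}")
    return tuple(e for e in CANONICAL_ORDER if e in requested)


def encode_combined(
    seq: RNASequence | str,
    encoders: Iterable[str],
    config: EncoderConfig = DEFAULT_CONFIG,
) -> FeatureVector:
    """Concatenate the requested encoders in canonical order.

    The request order is irrelevant: blocks always appear in the order
    OH, NAC, ANF, PKC, CP, EIIP.
    """
    combo = canonicalize_combo(encoders)
    parts = [_ENCODER_FUNCS[name](seq, config) for name in combo]
    values = np.concatenate([p.values for p in parts])
    blocks = tuple((name, len(p)) for name, p in zip(combo, parts))
    return FeatureVector(values, blocks)


def encode_windows(
    windows: Sequence[LabeledWindow],
    encoders: Iterable[str],
    config: EncoderConfig = DEFAULT_CONFIG,
) -> FeatureMatrix:
    """Encode a collection of same-length windows into a feature matrix."""
    if not windows:
        raise ValueError("no windows to encode")
    lengths = {w.length for w in windows}
    if len(lengths) > 1:
        raise ValueError(f"windows have mixed lengths {sorted(lengths)}")
    vecs = [encode_combined(w.window, encoders, config) for w in windows]
    X = np.vstack([v.values for v in vecs])
    y = np.array([w.label for w in windows], dtype=int)
    return FeatureMatrix(X=X, blocks=vecs[0].blocks, y=y)


def feature_names(blocks: Sequence[tuple[str, int]]) -> list[str]:
    """Column names of the form ``ENCODER_i`` matching a block layout."""
    names: list[str] = []
    for name, n in blocks:
        names.extend(f"{name}_{i + 1}" for i in range(n))
    return names
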