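"""Benchmark dataset construction: windows, negatives, de-redundancy, split.

The pipeline mirrors the standard design for modification-site predictors:
positive guanine sites come from a site table; negatives are drawn 1:1 from
other guanines on the same transcript; windows of odd length L centred on
each site are extracted (N-padded at transcript ends); near-duplicate
windows are removed by greedy identity clustering; and the survivors are
split 80/20 into stratified train/test partitions.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .sequence_io import (
    NEGATIVE,
    POSITIVE,
    LabeledWindow,
    RNASequence,
    SiteRecord,
)


@dataclass
class DatasetSplit:
    """Train/test partitions of labelled windows plus a manifest.

    The manifest records every parameter and count needed to reproduce the
    split byte-for-byte: regulator, window length, seed, identity
    threshold, per-class counts before/after de-redundancy and per
    partition, and a content hash.
    """

    train: list[LabeledWindow]
    test: list[LabeledWindow]
    manifest: dict = field(default_factory=dict)

    def counts(self) -> dict:
        def tally(part: Sequence[LabeledWindow]) -> dict:
            pos = sum(1 for w in part if w.label == POSITIVE)
            return {"positive": pos, "negative": len(part) - pos}

        return {"train": tally(self.train), "test": tally(self.test)}


def extract_window(transcript: RNASequence, position: int, L: int) -> RNASequence:
    """Extract the odd-length window centred on a 1-based G position.

    Positions outside [1, len(transcript)] are padded with N, so sites near
    transcript ends are kept rather than discarded.
    """
    if L % 2 == 0 or L < 1:
        raise ValueError(f"window length must be a positive odd integer, got {L}")
    n = len(transcript)
    if not (1 <= position <= n):
        raise ValueError(
            f"position {position} outside transcript {transcript.id!r} of length {n}"
        )
    centre = transcript.seq[position - 1]
    if centre != "G":
        raise ValueError(
            f"site {transcript.id}:{position}: centre base is {centre!r}, expected G"
        )
    half = (L - 1) // 2
    lo, hi = position - 1 - half, position + half  # 0-based [lo, hi)
    left_pad = max(0, -lo)
    right_pad = max(0, hi - n)
    body = transcript.seq[max(lo, 0) : min(hi, n)]
    return RNASequence(
        id=f"{transcript.id}:{position}",
        seq="N" * left_pad + body + "N" * right_pad,
    )


def g_positions(transcript: RNASequence) -> list[int]:
    """All 1-based guanine positions on a transcript."""
    return [i + 1 for i, c in enumerate(transcript.seq) if c == "G"]


def sample_negatives(
    transcript: RNASequence,
    positive_positions: Iterable[int],
    n: int,
    seed: int,
) -> set[int]:
    """Sample up to ``n`` negative G positions on the same transcript.

    Candidates are guanines not in ``positive_positions``; sampling is
    uniform without replacement and deterministic under ``seed``.  If fewer
    than ``n`` candidates exist all are returned and a shortfall warning is
    issued.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    excluded = set(positive_positions)
    candidates = [p for p in g_positions(transcript) if p not in excluded]
    if len(candidates) < n:
        warnings.warn(
            f"transcript {transcript.id!r}: only {len(candidates)} negative G "
            f"candidates for {n} requested (shortfall)",
            stacklevel=2,
        )
        return set(candidates)
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(candidates), size=n, replace=False)
    return {candidates[i] for i in chosen}


def _identity_fraction(a: str, b: str) -> float:
    """Ungapped identity: matching positions / length (equal lengths)."""
    return sum(x == y for x, y in zip(a, b)) / len(a)


def dedupe_greedy(
    windows: Sequence[LabeledWindow],
    identity_threshold: float = 0.9,
) -> list[LabeledWindow]:
    """Greedy redundancy removal on fixed-length windows.

    Windows are scanned in input order; one is kept iff its ungapped
    identity to every previously kept window is strictly below the
    threshold.  This approximates alignment-based clustering (cd-hit-est
    style, default threshold 0.9) for equal-length short windows.
    """
    if not windows:
        return []
    if not (0 < identity_threshold <= 1):
        raise ValueError("identity_threshold must lie in (0, 1]")
    lengths = {w.length for w in windows}
    if len(lengths) > 1:
        raise ValueError(f"dedupe requires equal window lengths, got {sorted(lengths)}")
    L = lengths.pop()
    # byte matrix of kept windows for vectorized identity against each candidate
    kept: list[LabeledWindow] = []
    kept_mat = np.empty((0, L), dtype="S1")
    for w in windows:
        row = np.frombuffer(w.window.seq.encode(), dtype="S1")
        if kept_mat.shape[0]:
            identities = (kept_mat == row).mean(axis=1)
            if float(identities.max()) >= identity_threshold:
                continue
        kept.append(w)
        kept_mat = np.vstack([kept_mat, row[None, :]])
    return kept


def split_train_test(
    windows: Sequence[LabeledWindow],
    train_fraction: float = 0.8,
    seed: int = 0,
) -> DatasetSplit:
    """Stratified random train/test split.

    Each class contributes ``round(train_fraction * n_c)`` windows to the
    training partition (banker's rounding), clamped so neither partition is
    empty for either class.  Assignment is deterministic under ``seed``.
    """
    if not (0 < train_fraction < 1):
        raise ValueError("train_fraction must lie strictly between 0 and 1")
    by_class: dict[int, list[LabeledWindow]] = {POSITIVE: [], NEGATIVE: []}
    for w in windows:
        by_class[w.label].append(w)
    for label, group in by_class.items():
        if len(group) < 2:
            raise ValueError(
                f"class {label} has {len(group)} window(s); need >= 2 to split"
            )
    rng = np.random.default_rng(seed)
    train: list[LabeledWindow] = []
    test: list[LabeledWindow] = []
    for label in (POSITIVE, NEGATIVE):
        group = by_class[label]
        n = len(group)
        n_train = int(round(train_fraction * n))
        n_train = min(max(n_train, 1), n - 1)
        order = rng.permutation(n)
        train.extend(group[i] for i in order[:n_train])
        test.extend(group[i] for i in order[n_train:])
    split = DatasetSplit(train=train, test=test)
    split.manifest = {
        "train_fraction": train_fraction,
        "seed": seed,
        "counts": split.counts(),
    }
    return split


def _content_hash(windows: Iterable[LabeledWindow]) -> str:
    h = hashlib.sha256()
    for w in windows:
        h.update(f"{w.window.seq}|{w.label}|{w.origin}\n".encode())
    return h.hexdigest()


def build_dataset(
    transcripts: Sequence[RNASequence],
    sites: Sequence[SiteRecord],
    L: int = 61,
    seed: int = 0,
    identity_threshold: float = 0.9,
    train_fraction: float = 0.8,
    exclude_sites: Sequence[SiteRecord] = (),
) -> DatasetSplit:
    """Full benchmark construction for one regulator.

    Steps: 1:1 negative sampling per transcript, window extraction with
    N-padding, joint greedy de-redundancy (positives first), stratified
    train/test split.  The manifest records all parameters, pre- and
    post-dedupe class counts and a content hash; reruns with the same seed
    are byte-identical.

    ``exclude_sites`` lists additional guanines (e.g. positives of *other*
    regulators) barred from negative sampling without counting as
    positives here.
    """
    if not sites:
        raise ValueError("no positive sites provided")
    regs = {s.regulator for s in sites}
    if len(regs) > 1:
        raise ValueError(f"sites span multiple regulators {sorted(regs)}; build one at a time")
    if any(s.label != POSITIVE for s in sites):
        raise ValueError("build_dataset expects positive-labelled sites only")
    regulator = regs.pop()
    tx_by_id = {t.id: t for t in transcripts}
    missing = {s.transcript_id for s in sites} - set(tx_by_id)
    if missing:
        raise ValueError(f"site table references unknown transcript(s) {sorted(missing)}")

    pos_by_tx: dict[str, list[int]] = {}
    for s in sites:
        pos_by_tx.setdefault(s.transcript_id, []).append(s.position)
    excluded_by_tx: dict[str, set[int]] = {}
    for s in exclude_sites:
        excluded_by_tx.setdefault(s.transcript_id, set()).add(s.position)

    rng = np.random.default_rng(seed)
    positives: list[LabeledWindow] = []
    negatives: list[LabeledWindow] = []
    for tx_id in sorted(pos_by_tx):
        tx = tx_by_id[tx_id]
        pos_positions = sorted(set(pos_by_tx[tx_id]))
        for p in pos_positions:
            positives.append(
                LabeledWindow(extract_window(tx, p, L), POSITIVE, origin=(tx_id, p))
            )
        neg_seed = int(rng.integers(0, 2**31 - 1))
        barred = set(pos_positions) | excluded_by_tx.get(tx_id, set())
        for p in sorted(sample_negatives(tx, barred, len(pos_positions), neg_seed)):
            negatives.append(
                LabeledWindow(extract_window(tx, p, L), NEGATIVE, origin=(tx_id, p))
            )

    pre_dedupe = {"positive": len(positives), "negative": len(negatives)}
    kept = dedupe_greedy(positives + negatives, identity_threshold)
    post_dedupe = {
        "positive": sum(1 for w in kept if w.label == POSITIVE),
        "negative": sum(1 for w in kept if w.label == NEGATIVE),
    }
    split = split_train_test(kept, train_fraction=train_fraction, seed=seed)
    split.manifest = {
        "regulator": regulator,
        "window_length": L,
        "seed": seed,
        "identity_threshold": identity_threshold,
        "train_fraction": train_fraction,
        "counts_pre_dedupe": pre_dedupe,
        "counts_post_dedupe": post_dedupe,
        "counts": split.counts(),
        "content_hash": _content_hash(split.train + split.test),
    }
    return split


def manifest_json(split: DatasetSplit) -> str:
    """Canonical JSON form of a manifest (stable key order)."""
    return json.dumps(split.manifest, sort_keys=True, indent=2)
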