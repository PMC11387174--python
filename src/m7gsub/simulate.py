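"""Synthetic transcripts with planted regulator-style motifs.

Real substrate sets come from CLIP/RIP binding regions intersected with
transcriptome-wide m7G maps; this module emulates their essential
structure so the whole pipeline is testable offline: i.i.d. background
transcripts carrying positive G-sites whose flanks contain a short
regulator motif (e.g. ``GxAG`` for the writer METTL1, where ``x`` is any
base), against negatives that are ordinary guanines on the same
transcripts.  A configurable fraction of positives (``noise_rate``) is
generated without the motif, mimicking binding regions with no detectable
sequence preference.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataset import DatasetSplit, build_dataset
from .sequence_io import POSITIVE, RNASequence, SiteRecord

BASES = "ACGU"


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of a synthetic substrate benchmark.

    ``motif`` is over ``{A,C,G,U,x}``; ``x`` positions draw from the
    background composition.  ``motif_offset`` is where the motif starts
    relative to the central G (0 = the motif's first base sits on the
    site itself, the layout of the writer motifs).  ``noise_rate`` is the
    fraction of positives planted without the motif.
    """

    n_transcripts: int = 50
    transcript_length: int = 2000
    n_positive_sites: int = 500
    motif: str = "GxAG"
    motif_offset: int = 0
    background_composition: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    noise_rate: float = 0.1
    regulator: str = "METTL1"
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.motif:
            raise ValueError("motif must be non-empty")
        bad = set(self.motif.upper()) - set("ACGUX")
        if bad:
            raise ValueError(f"motif characters must be in A,C,G,U,x; got {sorted(bad)}")
        comp = np.asarray(self.background_composition, dtype=float)
        if comp.shape != (4,) or abs(comp.sum() - 1.0) > 1e-9 or (comp < 0).any():
            raise ValueError("background_composition must be 4 probabilities summing to 1")
        if not (0.0 <= self.noise_rate <= 1.0):
            raise ValueError("noise_rate must lie in [0, 1]")
        if self.n_transcripts < 1 or self.n_positive_sites < 1:
            raise ValueError("need at least one transcript and one positive site")
        # if the motif covers the central position, that character must be
        # G (or x, which is forced to G there)
        centre_in_motif = -self.motif_offset
        if 0 <= centre_in_motif < len(self.motif):
            c = self.motif.upper()[centre_in_motif]
            if c not in ("G", "X"):
                raise ValueError(
                    f"motif character over the central site must be G or x, got {c!r}"
                )


def generate(
    spec: SyntheticSpec,
) -> tuple[list[RNASequence], list[SiteRecord], pd.DataFrame]:
    """Generate transcripts, a positive site table, and a truth table.

    Positive sites are spaced so planted motifs never overlap; the truth
    table records which positives actually carry the motif (the noisy
    fraction does not).  Output is byte-identical under a fixed spec.
    """
    rng = np.random.default_rng(spec.seed)
    comp = np.asarray(spec.background_composition, dtype=float)
    motif = spec.motif.upper()
    m = len(motif)

    # motif span relative to the 1-based site position
    span_lo = spec.motif_offset
    span_hi = spec.motif_offset + m - 1
    margin_left = max(0, -span_lo)
    margin_right = max(0, span_hi)
    slot = margin_left + margin_right + 2  # minimal room for one site + motif

    # distribute sites across transcripts as evenly as possible
    base_n, extra = divmod(spec.n_positive_sites, spec.n_transcripts)
    per_tx = [base_n + (1 if i < extra else 0) for i in range(spec.n_transcripts)]

    transcripts: list[RNASequence] = []
    sites: list[SiteRecord] = []
    truth_rows: list[dict] = []
    for t, n_sites in enumerate(per_tx):
        tx_id = f"syn_tx{t + 1:04d}"
        seq = rng.choice(list(BASES), size=spec.transcript_length, p=comp)
        if n_sites:
            usable = spec.transcript_length - margin_left - margin_right
            chunk = usable // n_sites
            if chunk < slot:
                raise ValueError(
                    f"cannot pack {n_sites} sites with motif span {m} into a "
                    f"{spec.transcript_length}-nt transcript"
                )
            for s_i in range(n_sites):
                lo = margin_left + s_i * chunk
                hi = lo + chunk - margin_right - 1
                pos0 = int(rng.integers(lo, hi))  # 0-based site index
                seq[pos0] = "G"
                has_motif = bool(rng.random() >= spec.noise_rate)
                if has_motif:
                    for j, c in enumerate(motif):
                        at = pos0 + spec.motif_offset + j
                        if at == pos0:
                            seq[at] = "G"
                        elif c == "X":
                            seq[at] = rng.choice(list(BASES), p=comp)
                        else:
                            seq[at] = c
                sites.append(
                    SiteRecord(
                        transcript_id=tx_id,
                        position=pos0 + 1,
                        regulator=spec.regulator,
                        label=POSITIVE,
                    )
                )
                truth_rows.append(
                    {"transcript_id": tx_id, "position": pos0 + 1, "has_motif": has_motif}
                )
        transcripts.append(RNASequence(id=tx_id, seq="".join(seq)))

    truth = pd.DataFrame(truth_rows, columns=["transcript_id", "position", "has_motif"])
    return transcripts, sites, truth


def make_benchmark(
    spec: SyntheticSpec,
    L: int = 61,
    identity_threshold: float = 0.9,
    train_fraction: float = 0.8,
) -> DatasetSplit:
    """Generate synthetic data and run the full dataset pipeline on it.

    The canonical end-to-end fixture: motif-planted positives, 1:1
    sampled negatives, greedy de-redundancy, stratified 80/20 split.
    """
    transcripts, sites, _ = generate(spec)
    return build_dataset(
        transcripts,
        sites,
        L=L,
        seed=spec.seed,
        identity_threshold=identity_threshold,
        train_fraction=train_fraction,
    )
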