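"""Selection loops: feature-combination search, window-length sweep,
algorithm comparison, and cross-prediction between regulator models.

The combination search scores every non-empty subset of the six encoders
(2^6 - 1 = 63 models) on the independent test partition, the protocol the
reference tables use; the window sweep rebuilds the dataset at each length
with the same seed so site sets stay aligned.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .dataset import DatasetSplit, build_dataset
from .encoders import (
    CANONICAL_ORDER,
    DEFAULT_CONFIG,
    EncoderConfig,
    FeatureMatrix,
    encode_windows,
)
from .models import (
    EvalReport,
    HyperparameterGrid,
    TrainedModel,
    auroc,
    evaluate,
    grid_search_svm,
    predict,
    train,
)
from .sequence_io import POSITIVE, LabeledWindow, RNASequence, SiteRecord

#: Final-model defaults: dinucleotide composition + EIIP + chemical property
#: over 61-nt windows, RBF-kernel SVM.
DEFAULT_COMBO = ("NAC", "EIIP", "CP")
DEFAULT_WINDOW = 61


@dataclass(frozen=True)
class ComboResult:
    """One evaluated encoder subset: combo, held-out AUROC, rank (1 = best)."""

    combo: tuple[str, ...]
    auroc: float
    rank: int


def all_combos() -> list[tuple[str, ...]]:
    """The 63 non-empty subsets of the six encoders, in canonical order."""
    out: list[tuple[str, ...]] = []
    for r in range(1, len(CANONICAL_ORDER) + 1):
        out.extend(combinations(CANONICAL_ORDER, r))
    return out


def _block_cache(
    windows: Sequence[LabeledWindow], config: EncoderConfig
) -> tuple[dict[str, FeatureMatrix], np.ndarray]:
    """Encode each single encoder once; combos are assembled by stacking."""
    cache = {name: encode_windows(windows, (name,), config) for name in CANONICAL_ORDER}
    y = cache["OH"].y
    return cache, y


def _assemble(cache: Mapping[str, FeatureMatrix], combo: Sequence[str], y: np.ndarray) -> FeatureMatrix:
    mats = [cache[name] for name in combo]
    X = np.hstack([m.X for m in mats])
    blocks = tuple(b for m in mats for b in m.blocks)
    return FeatureMatrix(X=X, blocks=blocks, y=y)


def search_feature_combos(
    dataset: DatasetSplit,
    algorithm: str = "SVM_RBF",
    seed: int = 0,
    hyperparameters: dict | None = None,
    config: EncoderConfig = DEFAULT_CONFIG,
) -> list[ComboResult]:
    """Train and evaluate one model per non-empty encoder subset (63 total).

    Results are sorted by test AUROC descending; ties break toward fewer
    encoders, then canonical order.
    """
    train_cache, y_train = _block_cache(dataset.train, config)
    test_cache, y_test = _block_cache(dataset.test, config)
    scored: list[tuple[tuple[str, ...], float]] = []
    for combo in all_combos():
        fm_train = _assemble(train_cache, combo, y_train)
        fm_test = _assemble(test_cache, combo, y_test)
        model = train(algorithm, fm_train, hyperparameters=hyperparameters, seed=seed)
        scored.append((combo, evaluate(model, fm_test).auroc))

    order_index = {name: i for i, name in enumerate(CANONICAL_ORDER)}
    scored.sort(key=lambda t: (-t[1], len(t[0]), tuple(order_index[e] for e in t[0])))
    return [ComboResult(combo=c, auroc=a, rank=i + 1) for i, (c, a) in enumerate(scored)]


def combo_table(results: Sequence[ComboResult]) -> pd.DataFrame:
    """Tabular form of a combination search (one row per combo)."""
    return pd.DataFrame(
        {
            "rank": [r.rank for r in results],
            "combo": ["+".join(r.combo) for r in results],
            "n_encoders": [len(r.combo) for r in results],
            "auroc": [r.auroc for r in results],
        }
    )


def train_on_split(
    dataset: DatasetSplit,
    combo: Sequence[str] = DEFAULT_COMBO,
    algorithm: str = "SVM_RBF",
    hyperparameters: dict | None = None,
    seed: int = 0,
    config: EncoderConfig = DEFAULT_CONFIG,
) -> TrainedModel:
    """Encode the training partition with a combo and fit one model."""
    fm = encode_windows(dataset.train, combo, config)
    L = dataset.train[0].length
    return train(algorithm, fm, hyperparameters=hyperparameters, seed=seed, window_length=L)


def evaluate_on_split(
    model: TrainedModel,
    dataset: DatasetSplit,
    threshold: float = 0.5,
    config: EncoderConfig = DEFAULT_CONFIG,
) -> EvalReport:
    """Evaluate a trained model on a dataset's test partition."""
    fm = encode_windows(dataset.test, model.encoder_combo, config)
    return evaluate(model, fm, threshold=threshold)


def sweep_window_lengths(
    transcripts: Sequence[RNASequence],
    sites: Sequence[SiteRecord],
    lengths: Sequence[int] = (21, 41, 61, 81),
    combo: Sequence[str] = DEFAULT_COMBO,
    algorithm: str = "SVM_RBF",
    seed: int = 0,
    identity_threshold: float = 0.9,
    hyperparameters: dict | None = None,
    config: EncoderConfig = DEFAULT_CONFIG,
) -> tuple[dict[int, EvalReport], int]:
    """Rebuild, train and evaluate at each window length.

    The dataset (negative sampling, dedupe, split) is reconstructed per
    length under the same seed, so the underlying site sets stay aligned
    and only L varies.  Returns per-length reports and the argmax length.
    """
    for L in lengths:
        if L % 2 == 0:
            raise ValueError(f"window lengths must be odd, got {L}")
    reports: dict[int, EvalReport] = {}
    for L in lengths:
        ds = build_dataset(
            transcripts, sites, L=L, seed=seed, identity_threshold=identity_threshold
        )
        model = train_on_split(
            ds, combo=combo, algorithm=algorithm, hyperparameters=hyperparameters, seed=seed,
            config=config,
        )
        reports[L] = evaluate_on_split(model, ds, config=config)
    best_L = max(reports, key=lambda L: reports[L].auroc)
    return reports, best_L


def compare_algorithms(
    dataset: DatasetSplit,
    combo: Sequence[str] = DEFAULT_COMBO,
    seed: int = 0,
    grid: HyperparameterGrid | None = None,
    cv: int = 5,
    config: EncoderConfig = DEFAULT_CONFIG,
) -> dict[str, EvalReport]:
    """One tuned model per algorithm on identical train/test data.

    The SVM is tuned by cross-validated grid search on the training
    partition; the other algorithms use their documented defaults with a
    fixed seed.  All four reports are computed on the same test matrix.
    """
    fm_train = encode_windows(dataset.train, combo, config)
    fm_test = encode_windows(dataset.test, combo, config)
    reports: dict[str, EvalReport] = {}
    for algorithm in ("SVM_RBF", "RF", "GLM", "GBT"):
        hp = None
        if algorithm == "SVM_RBF":
            gs = grid_search_svm(fm_train, grid=grid, cv=cv, seed=seed)
            hp = {"C": gs.best_C, "gamma": gs.best_gamma}
        model = train(algorithm, fm_train, hyperparameters=hp, seed=seed)
        reports[algorithm] = evaluate(model, fm_test)
    return reports


@dataclass
class CrossPredictionMatrix:
    """Every model applied to every regulator's substrate windows.

    ``auroc``: model (row) evaluated on each regulator's held-out test
    windows (column).  ``positive_rate``: fraction of each regulator's
    positive test windows the row model calls positive at the threshold.
    The diagonal of ``auroc`` is each model's own independent-test AUROC.
    """

    auroc: pd.DataFrame
    positive_rate: pd.DataFrame
    threshold: float


def cross_predict(
    models: Mapping[str, TrainedModel],
    datasets: Mapping[str, DatasetSplit],
    threshold: float = 0.5,
    config: EncoderConfig = DEFAULT_CONFIG,
) -> CrossPredictionMatrix:
    """Cross-apply regulator models to each other's substrate test sets.

    All models must share window length and encoder combo so one encoding
    per dataset serves every row.
    """
    regs = list(models)
    if set(datasets) != set(regs):
        raise ValueError("models and datasets must cover the same regulators")
    combos = {m.encoder_combo for m in models.values()}
    lengths = {m.window_length for m in models.values()}
    if len(combos) > 1 or len(lengths) > 1:
        raise ValueError(
            f"cross-prediction requires a shared combo and window length; "
            f"got combos {combos}, lengths {lengths}"
        )
    combo = combos.pop()

    encoded = {r: encode_windows(datasets[r].test, combo, config) for r in regs}
    auc = pd.DataFrame(index=regs, columns=regs, dtype=float)
    pos_rate = pd.DataFrame(index=regs, columns=regs, dtype=float)
    for ri in regs:
        for rj in regs:
            fm = encoded[rj]
            auc.loc[ri, rj] = evaluate(models[ri], fm, threshold=threshold).auroc
            pos_mask = fm.y == POSITIVE
            scores = predict(models[ri], fm)[pos_mask]
            pos_rate.loc[ri, rj] = float((scores >= threshold).mean())
    return CrossPredictionMatrix(auroc=auc, positive_rate=pos_rate, threshold=threshold)
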