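"""Cross-validation and leave-one-timepoint-out evaluation of the dynamics net.

Tenfold cross-validation randomly partitions the training pairs into ten
near-equal folds, trains on nine and scores the tenth with the mean absolute
percentage error (MAPE). The leave-one-timepoint-out test removes the pair
targeting one randomly chosen day per diet, retrains, predicts each held-out
profile from its predecessor, and summarises accuracy as per-taxon absolute
differences (percentage points) and Bray-Curtis similarity
(1 - dissimilarity) between predicted and measured abundances.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .diversity_stats import bray_curtis_pair
from .dynamics_ann import (
    AnnModel,
    NetworkTopology,
    TrainingConfig,
    TrainingPair,
    forward,
    init_model,
    make_training_pairs,
    pairs_to_arrays,
    train,
)
from .taxon_tables import DietSeries

#: Taxa measured at or below this abundance are excluded from MAPE terms
#: (a zero denominator makes the percentage error unbounded).
EPSILON_MAPE = 1e-4


@dataclass
class CvResult:
    fold_mapes: list[float]
    mean_mape: float
    pooled_mape: float
    fold_assignments: dict[int, int]  # pair index -> fold
    k: int
    seed: int


@dataclass
class HoldoutResult:
    """Per-diet predicted/measured vectors and overall similarity."""

    per_diet: dict[str, dict]
    bray_curtis_similarity: float
    mean_aggregated_similarity: float
    per_diet_similarity: dict[str, float]
    max_abs_diff: float  # percentage points
    held_out: dict[str, int]
    seed: int


def mape(
    predicted: np.ndarray,
    actual: np.ndarray,
    epsilon: float = EPSILON_MAPE,
) -> float:
    """Mean |pred - actual| / actual * 100 over entries with actual > epsilon."""
    predicted = np.asarray(predicted, float)
    actual = np.asarray(actual, float)
    mask = actual > epsilon
    if not mask.any():
        raise ValueError("no entries above the MAPE denominator guard")
    return float(
        np.mean(np.abs(predicted[mask] - actual[mask]) / actual[mask]) * 100.0
    )


def _child_seed(seed: int, index: int) -> int:
    ss = np.random.SeedSequence(seed).spawn(index + 1)[index]
    return int(ss.generate_state(1)[0] % (2 ** 31))


def kfold_cv(
    pairs: Sequence[TrainingPair],
    topology: NetworkTopology,
    config: TrainingConfig,
    taxon_names: Sequence[str],
    substrate_names: Sequence[str],
    k: int = 10,
    seed: int = 0,
) -> CvResult:
    """Seeded k-fold cross-validation; MAPE per validation fold.

    The headline ``mean_mape`` averages the per-fold MAPEs; ``pooled_mape``
    pools every (pair, taxon) percentage-error term across folds.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > len(pairs):
        raise ValueError(f"k={k} exceeds the number of pairs ({len(pairs)})")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(pairs))
    folds = np.array_split(perm, k)
    fold_assignments = {
        int(i): f for f, idx in enumerate(folds) for i in idx
    }
    fold_mapes: list[float] = []
    pooled_terms: list[np.ndarray] = []
    for f, val_idx in enumerate(folds):
        val_set = {int(i) for i in val_idx}
        train_pairs = [pairs[i] for i in perm if int(i) not in val_set]
        val_pairs = [pairs[i] for i in val_idx]
        cfg = TrainingConfig(**{**config.__dict__, "seed": _child_seed(seed, f)})
        model = init_model(topology, taxon_names, substrate_names, cfg)
        train(model, train_pairs, cfg)
        X, T = pairs_to_arrays(val_pairs)
        from .dynamics_ann import forward_batch

        Y = forward_batch(model, X)
        mask = T > EPSILON_MAPE
        terms = np.abs(Y[mask] - T[mask]) / T[mask] * 100.0
        pooled_terms.append(terms)
        fold_mapes.append(float(terms.mean()))
    pooled = float(np.concatenate(pooled_terms).mean())
    return CvResult(
        fold_mapes=fold_mapes,
        mean_mape=float(np.mean(fold_mapes)),
        pooled_mape=pooled,
        fold_assignments=fold_assignments,
        k=k,
        seed=seed,
    )


def choose_held_out_days(
    series: Sequence[DietSeries], seed: int = 0
) -> dict[str, int]:
    """One random held-out day per diet, excluding each series' first day."""
    rng = np.random.default_rng(seed)
    held = {}
    for s in series:
        candidates = [p.day for p in s.profiles[1:]]
        held[s.diet] = int(rng.choice(candidates))
    return held


def leave_one_timepoint_out(
    series: Sequence[DietSeries],
    topology: NetworkTopology,
    config: TrainingConfig,
    held_out: Mapping[str, int] | None = None,
    seed: int = 0,
) -> HoldoutResult:
    """Train with one pair per diet held out and predict the held-out days.

    The headline similarity is 1 minus the Bray-Curtis dissimilarity of the
    concatenated (all diets) predicted vs measured vectors; the similarity of
    the mean-aggregated vectors and per-diet similarities are also reported.
    """
    if held_out is None:
        held_out = choose_held_out_days(series, seed)
    by_diet = {s.diet: s for s in series}
    for diet, day in held_out.items():
        if diet not in by_diet:
            raise ValueError(f"unknown diet {diet!r}")
        days = by_diet[diet].days
        if day == days[0]:
            raise ValueError(
                f"held-out day {day} is the first day of series {diet!r}"
            )
        if day not in days:
            raise ValueError(f"day {day} not sampled for diet {diet!r}")
    all_pairs = make_training_pairs(series)
    train_pairs = [
        p for p in all_pairs
        if not (p.diet in held_out and p.target_day == held_out[p.diet])
    ]
    cfg = TrainingConfig(**{**config.__dict__, "seed": _child_seed(seed, 0)})
    taxon_names = series[0].profiles[0].taxon_names
    model = init_model(topology, taxon_names, series[0].substrate_names, cfg)
    train(model, train_pairs, cfg)

    per_diet: dict[str, dict] = {}
    per_diet_sim: dict[str, float] = {}
    preds, meas = [], []
    for diet, day in held_out.items():
        s = by_diet[diet]
        i = s.days.index(day)
        predecessor = s.profiles[i - 1]
        measured = s.profiles[i].abundances
        x = np.concatenate([predecessor.abundances, s.substrate_flags])
        predicted = forward(model, x)
        diff_pp = np.abs(predicted - measured) * 100.0
        per_diet[diet] = {
            "day": day,
            "predicted": predicted,
            "measured": measured,
            "abs_diff_pp": diff_pp,
        }
        per_diet_sim[diet] = 1.0 - bray_curtis_pair(predicted, measured)
        preds.append(predicted)
        meas.append(measured)
    pred_cat = np.concatenate(preds)
    meas_cat = np.concatenate(meas)
    pred_mean = np.mean(np.stack(preds), axis=0)
    meas_mean = np.mean(np.stack(meas), axis=0)
    return HoldoutResult(
        per_diet=per_diet,
        bray_curtis_similarity=1.0 - bray_curtis_pair(pred_cat, meas_cat),
        mean_aggregated_similarity=1.0 - bray_curtis_pair(pred_mean, meas_mean),
        per_diet_similarity=per_diet_sim,
        max_abs_diff=float(
            max(d["abs_diff_pp"].max() for d in per_diet.values())
        ),
        held_out=dict(held_out),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Writers
# ---------------------------------------------------------------------------


def write_cv_result(result: CvResult, path: str | Path) -> None:
    doc = {
        "k": result.k,
        "seed": result.seed,
        "fold_mapes": result.fold_mapes,
        "mean_mape": result.mean_mape,
        "pooled_mape": result.pooled_mape,
    }
    Path(path).write_text(json.dumps(doc, indent=2) + "\n")


def write_holdout_result(
    result: HoldoutResult, taxon_names: Sequence[str], path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write("diet\tday\ttaxon\tmeasured\tpredicted\tabs_diff_pp\n")
        for diet, d in result.per_diet.items():
            for name, m, p, diff in zip(
                taxon_names, d["measured"], d["predicted"], d["abs_diff_pp"]
            ):
                fh.write(
                    f"{diet}\t{d['day']}\t{name}\t{m:.6g}\t{p:.6g}\t{diff:.6g}\n"
                )
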