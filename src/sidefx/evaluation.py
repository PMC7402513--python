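"""Cross-validated evaluation and the experiment grid.

Each side-effect is evaluated with stratified 5-fold cross-validation over
its gold-standard set (positives plus selected negatives): each fold serves
once as the test set, fold predictions are pooled into one confusion table
per side-effect, and precision / recall / F1 are computed on the pooled
counts.  Macro metrics are unweighted means across side-effects.

A *situation* is one point of the experiment grid: similarity channels and
integration method x balance mode x negative-selection method x classifier.
Stochastic situations (random negatives, positive subsampling) are repeated
with independent seeds and metric means reported.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np

from .io import Dataset
from ._rng import substream, substream_seed
from .classify import ClassifierSpec, TrainingSet, build_training_set, fit_predict, vectorize
from .negatives import GoldStandard, select_random_negatives, select_reliable_negatives
from .similarity import SimilarityMatrix, build_similarity_matrix

__all__ = [
    "ConfusionCounts",
    "SituationConfig",
    "MetricsReport",
    "kfold_split",
    "compute_metrics",
    "macro_average",
    "evaluate_side_effect",
    "run_situation",
    "rank_predictions",
    "predict_side_effect",
]


@dataclass
class ConfusionCounts:
    tp: int = 0
    fp: int = 0
    fn: int = 0
    tn: int = 0

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(
            self.tp + other.tp, self.fp + other.fp, self.fn + other.fn, self.tn + other.tn
        )

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def compute_metrics(counts: ConfusionCounts) -> tuple[float, float, float]:
    """(precision, recall, F1) with the 0-for-0/0 convention.

    precision = TP/(TP+FP), recall = TP/(TP+FN), F1 = 2PR/(P+R); any
    undefined ratio is reported as 0 so side-effects with empty predicted or
    actual positive sets still contribute a number to the macro average.
    """
    p = counts.tp / (counts.tp + counts.fp) if counts.tp + counts.fp else 0.0
    r = counts.tp / (counts.tp + counts.fn) if counts.tp + counts.fn else 0.0
    f1 = 2.0 * p * r / (p + r) if p + r else 0.0
    return p, r, f1


def macro_average(
    per_side_effect: Mapping[str, tuple[float, float, float]]
) -> tuple[float, float, float]:
    """Unweighted mean of (precision, recall, F1) across side-effects."""
    if not per_side_effect:
        raise ValueError("macro_average needs at least one side-effect")
    arr = np.asarray(list(per_side_effect.values()), dtype=float)
    means = arr.mean(axis=0)
    return float(means[0]), float(means[1]), float(means[2])


def kfold_split(
    drug_ids: list[str], labels: Mapping[str, int] | np.ndarray, k: int = 5, seed: int = 0
) -> list[list[str]]:
    """Seeded stratified k-fold partition of the gold-standard drugs.

    Positives and negatives are shuffled independently and dealt round-robin,
    with the negative deal offset so fold sizes differ by at most one and
    each fold's positive count deviates from proportionality by at most one.
    """
    if len(drug_ids) < k:
        raise ValueError(f"cannot split {len(drug_ids)} drugs into {k} folds")
    if isinstance(labels, np.ndarray):
        labels = dict(zip(drug_ids, labels))
    pos = [d for d in drug_ids if labels[d]]
    neg = [d for d in drug_ids if not labels[d]]
    rng = substream(seed, "kfold")
    pos = [pos[i] for i in rng.permutation(len(pos))]
    neg = [neg[i] for i in rng.permutation(len(neg))]
    folds: list[list[str]] = [[] for _ in range(k)]
    for i, d in enumerate(pos):
        folds[i % k].append(d)
    offset = len(pos) % k
    for i, d in enumerate(neg):
        folds[(offset + i) % k].append(d)
    return folds


def rank_predictions(scores: Mapping[str, float], top_n: int) -> list[str]:
    """Drugs ranked by descending score, ties by drug id; at most top_n."""
    ranked = sorted(scores, key=lambda d: (-scores[d], d))
    return ranked[: max(top_n, 0)]


@dataclass(frozen=True)
class SituationConfig:
    """One point of the experiment grid."""

    channels: tuple = ("chem", "tar", "sub", "thera")
    integration: str = "max"
    balance: str = "balanced"
    negative_method: str = "reliable"  # reliable | random
    classifier: ClassifierSpec = field(default_factory=ClassifierSpec)
    n_folds: int = 5

    @property
    def name(self) -> str:
        chan = "Com" if set(self.channels) == {"chem", "tar", "sub", "thera"} else (
            "".join(c.capitalize() for c in self.channels)
        )
        neg = "Negative" if self.negative_method == "reliable" else "Random"
        bal = "Bal" if self.balance == "balanced" else "Unbal"
        return f"{self.classifier.kind.upper()}{chan}{neg}{bal}"

    @property
    def is_stochastic(self) -> bool:
        return self.negative_method == "random"


@dataclass
class MetricsReport:
    """Per-side-effect and macro-averaged metrics for one situation.

    For repeated (stochastic) situations the stored metrics are means over
    repeats; the per-repeat macro triples are retained in ``per_repeat``.
    """

    situation: str
    per_side_effect: dict[str, dict]
    macro_precision: float
    macro_recall: float
    macro_f1: float
    repeats: int
    seeds: list[int]
    per_repeat: list[dict] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "situation": self.situation,
            "per_side_effect": self.per_side_effect,
            "macro_precision": self.macro_precision,
            "macro_recall": self.macro_recall,
            "macro_f1": self.macro_f1,
            "repeats": self.repeats,
            "seeds": self.seeds,
            "per_repeat": self.per_repeat,
        }

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "MetricsReport":
        with open(path, "r", encoding="utf-8") as fh:
            d = json.load(fh)
        return cls(
            situation=d["situation"],
            per_side_effect=d["per_side_effect"],
            macro_precision=d["macro_precision"],
            macro_recall=d["macro_recall"],
            macro_f1=d["macro_f1"],
            repeats=d["repeats"],
            seeds=d["seeds"],
            per_repeat=d.get("per_repeat", []),
        )

    def to_tsv(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("side_effect_id\tprecision\trecall\tf1\ttp\tfp\tfn\ttn\n")
            for se in sorted(self.per_side_effect):
                m = self.per_side_effect[se]
                fh.write(
                    f"{se}\t{m['precision']:.6f}\t{m['recall']:.6f}\t{m['f1']:.6f}"
                    f"\t{m['tp']:.2f}\t{m['fp']:.2f}\t{m['fn']:.2f}\t{m['tn']:.2f}\n"
                )
            fh.write(
                f"MACRO\t{self.macro_precision:.6f}\t{self.macro_recall:.6f}"
                f"\t{self.macro_f1:.6f}\t-\t-\t-\t-\n"
            )


def _gold_for(
    dataset: Dataset, se_id: str, S: SimilarityMatrix, config: SituationConfig, seed: int
) -> GoldStandard | None:
    positives = dataset.positives(se_id)
    candidates = dataset.candidates(se_id)
    if config.balance == "unbalanced":
        # all unlabeled drugs serve as negatives; no selection step
        return GoldStandard(se_id, positives, candidates, "all-unlabeled")
    n_s = min(len(positives), len(candidates))
    if n_s < 1:
        return None
    if config.negative_method == "reliable":
        return select_reliable_negatives(dataset, se_id, S, n_s)
    if config.negative_method == "random":
        return select_random_negatives(dataset, se_id, n_s, seed)
    raise ValueError(f"unknown negative method {config.negative_method!r}")


def evaluate_side_effect(
    dataset: Dataset,
    se_id: str,
    S: SimilarityMatrix,
    config: SituationConfig,
    seed: int,
) -> ConfusionCounts:
    """Pooled cross-validated confusion counts for one side-effect."""
    gold = _gold_for(dataset, se_id, S, config, seed)
    if gold is None:
        raise ValueError(f"{se_id}: empty gold standard")
    train_full = build_training_set(
        dataset, se_id, S, gold, balance=config.balance, seed=seed
    )
    members = train_full.ids
    truth = {d: int(lbl) for d, lbl in zip(members, train_full.y)}
    X_all = {d: x for d, x in zip(members, train_full.X)}
    folds = kfold_split(members, truth, k=config.n_folds, seed=substream_seed(seed, "cv", se_id))
    counts = ConfusionCounts()
    for fold_idx, test_ids in enumerate(folds):
        test_set = set(test_ids)
        tr_pos = [d for d in members if truth[d] and d not in test_set]
        tr_neg = [d for d in members if not truth[d] and d not in test_set]
        if not tr_pos or not tr_neg:
            # degenerate fold split (tiny gold set); train on what exists
            tr_pos = tr_pos or [d for d in members if truth[d]]
            tr_neg = tr_neg or [d for d in members if not truth[d]]
        train = TrainingSet(
            side_effect_id=se_id,
            X_pos=np.stack([X_all[d] for d in tr_pos]),
            X_neg=np.stack([X_all[d] for d in tr_neg]),
            pos_ids=tr_pos,
            neg_ids=tr_neg,
            balance_mode="cv-train",
            n_s=min(len(tr_pos), len(tr_neg)),
        )
        X_test = np.stack([X_all[d] for d in test_ids])
        spec = config.classifier.with_seed(substream_seed(seed, "clf", se_id, fold_idx))
        _, labels = fit_predict(spec, train, X_test)
        for d, pred in zip(test_ids, labels):
            if truth[d] and pred:
                counts.tp += 1
            elif truth[d] and not pred:
                counts.fn += 1
            elif not truth[d] and pred:
                counts.fp += 1
            else:
                counts.tn += 1
    return counts


def run_situation(
    dataset: Dataset,
    config: SituationConfig,
    repeats: int = 1,
    seed: int = 0,
    S: SimilarityMatrix | None = None,
    side_effect_ids: Iterable[str] | None = None,
) -> MetricsReport:
    """Evaluate one situation over all (or selected) side-effects.

    Per repeat, both the negative draw and the CV folds are re-randomized
    from an independent substream of the master seed.  Reported per-side-
    effect metrics and macro values are means over repeats.
    """
    if repeats < 1:
        raise ValueError("repeats must be >= 1")
    if S is None:
        S = build_similarity_matrix(dataset, config.channels, config.integration)
    se_ids = list(side_effect_ids) if side_effect_ids is not None else list(dataset.side_effect_ids)
    if not se_ids:
        raise ValueError("no side-effects to evaluate")

    repeat_seeds = [substream_seed(seed, "repeat", r) for r in range(repeats)]
    per_repeat_metrics: list[dict[str, dict]] = []
    per_repeat_macros: list[dict] = []
    for rs in repeat_seeds:
        per_se: dict[str, dict] = {}
        for se_id in se_ids:
            counts = evaluate_side_effect(dataset, se_id, S, config, rs)
            p, r, f1 = compute_metrics(counts)
            per_se[se_id] = {
                "precision": p, "recall": r, "f1": f1,
                "tp": counts.tp, "fp": counts.fp, "fn": counts.fn, "tn": counts.tn,
            }
        mp, mr, mf1 = macro_average(
            {se: (m["precision"], m["recall"], m["f1"]) for se, m in per_se.items()}
        )
        per_repeat_metrics.append(per_se)
        per_repeat_macros.append(
            {"macro_precision": mp, "macro_recall": mr, "macro_f1": mf1}
        )

    mean_per_se: dict[str, dict] = {}
    for se_id in se_ids:
        keys = ("precision", "recall", "f1", "tp", "fp", "fn", "tn")
        mean_per_se[se_id] = {
            k: float(np.mean([rep[se_id][k] for rep in per_repeat_metrics])) for k in keys
        }
    return MetricsReport(
        situation=config.name,
        per_side_effect=mean_per_se,
        macro_precision=float(np.mean([m["macro_precision"] for m in per_repeat_macros])),
        macro_recall=float(np.mean([m["macro_recall"] for m in per_repeat_macros])),
        macro_f1=float(np.mean([m["macro_f1"] for m in per_repeat_macros])),
        repeats=repeats,
        seeds=repeat_seeds,
        per_repeat=per_repeat_macros,
    )


def predict_side_effect(
    dataset: Dataset,
    se_id: str,
    config: SituationConfig,
    seed: int = 0,
    top_n: int = 50,
    S: SimilarityMatrix | None = None,
) -> list[tuple[str, float]]:
    """Rank unlabeled drugs by predicted propensity to cause the side-effect.

    Trains on the full gold standard for ``se_id`` and scores every
    candidate drug, returning the ``top_n`` highest-scoring (score desc,
    id asc) — the shortlisting step used for case-study review.
    """
    if S is None:
        S = build_similarity_matrix(dataset, config.channels, config.integration)
    gold = _gold_for(dataset, se_id, S, config, seed)
    if gold is None:
        raise ValueError(f"{se_id}: empty gold standard")
    train = build_training_set(dataset, se_id, S, gold, balance=config.balance, seed=seed)
    candidates = dataset.candidates(se_id)
    X_test = np.stack([vectorize(d, S) for d in candidates])
    spec = config.classifier.with_seed(substream_seed(seed, "predict", se_id))
    scores, _ = fit_predict(spec, train, X_test)
    score_map = {d: float(s) for d, s in zip(candidates, scores)}
    ranked = rank_predictions(score_map, top_n)
    return [(d, score_map[d]) for d in ranked]
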