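"""Model / Results front-end over the prediction pipeline.

``SideEffectPredictor`` is configured from a :class:`~sidefx.io.Dataset`
(or a directory of tables) and a situation choice; ``fit`` runs the
cross-validated evaluation and returns :class:`SideEffectResults`, which
carries the per-side-effect metrics, macro averages with across-repeat
spread, a ``summary()`` table, ranking of novel candidate drugs, and
scatter-comparison plotting against another fitted situation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import Dataset, load_dataset
from .classify import ClassifierSpec
from .evaluation import (
    MetricsReport,
    SituationConfig,
    predict_side_effect,
    run_situation,
)
from .similarity import SimilarityMatrix, build_similarity_matrix

__all__ = ["SideEffectPredictor", "SideEffectResults"]


class SideEffectPredictor:
    """Per-side-effect binary prediction with integrated drug similarities.

    Parameters
    ----------
    dataset : Dataset
        Aligned drug profiles and label matrix.
    channels : tuple of str
        Similarity channels to enable, subset of ``("chem","tar","sub","thera")``.
    integration : {"max", "mean", "gm"}
        Consensus rule fusing the channels into S_com.
    classifier : ClassifierSpec
        Learner and hyperparameters (KNN by default, k=50).
    balance : {"balanced", "unbalanced"}
        Whether training sets are balanced to n_s = min(#labeled, #unlabeled).
    negative_method : {"reliable", "random"}
        Reliable negatives by ascending accumulative similarity, or the
        random baseline.
    """

    def __init__(
        self,
        dataset: Dataset,
        channels: tuple = ("chem", "tar", "sub", "thera"),
        integration: str = "max",
        classifier: ClassifierSpec | None = None,
        balance: str = "balanced",
        negative_method: str = "reliable",
        n_folds: int = 5,
    ):
        self.dataset = dataset
        self.config = SituationConfig(
            channels=tuple(channels),
            integration=integration,
            balance=balance,
            negative_method=negative_method,
            classifier=classifier or ClassifierSpec(),
            n_folds=n_folds,
        )
        self._S: SimilarityMatrix | None = None

    @classmethod
    def from_tables(cls, directory, fingerprint_length: int = 1024, **kwargs) -> "SideEffectPredictor":
        """Build a predictor from a directory holding the six standard tables."""
        channels = kwargs.get("channels", ("chem", "tar", "sub", "thera"))
        dataset, _ = load_dataset(directory, channels=channels, fingerprint_length=fingerprint_length)
        return cls(dataset, **kwargs)

    @property
    def similarity(self) -> SimilarityMatrix:
        """The comprehensive similarity matrix (computed once, cached)."""
        if self._S is None:
            self._S = build_similarity_matrix(
                self.dataset, self.config.channels, self.config.integration
            )
        return self._S

    def fit(self, seed: int = 0, repeats: int = 1) -> "SideEffectResults":
        """Run the cross-validated evaluation and return the results."""
        report = run_situation(
            self.dataset, self.config, repeats=repeats, seed=seed, S=self.similarity
        )
        return SideEffectResults(model=self, report=report, seed=seed)

    def rank_candidates(self, side_effect_id: str, top_n: int = 50, seed: int = 0):
        """Shortlist unlabeled drugs most likely to cause the side-effect."""
        return predict_side_effect(
            self.dataset, side_effect_id, self.config, seed=seed, top_n=top_n, S=self.similarity
        )


@dataclass
class SideEffectResults:
    """Fitted evaluation results for one situation."""

    model: SideEffectPredictor
    report: MetricsReport
    seed: int

    @property
    def macro_f1(self) -> float:
        return self.report.macro_f1

    @property
    def macro_precision(self) -> float:
        return self.report.macro_precision

    @property
    def macro_recall(self) -> float:
        return self.report.macro_recall

    @property
    def per_side_effect(self) -> pd.DataFrame:
        """Per-side-effect metrics as a DataFrame indexed by side-effect id."""
        df = pd.DataFrame.from_dict(self.report.per_side_effect, orient="index")
        df.index.name = "side_effect_id"
        return df.sort_index()

    def macro_spread(self) -> dict:
        """Std of the macro metrics across repeats (0.0 for a single run)."""
        if len(self.report.per_repeat) < 2:
            return {"macro_precision": 0.0, "macro_recall": 0.0, "macro_f1": 0.0}
        return {
            key: float(np.std([m[key] for m in self.report.per_repeat], ddof=1))
            for key in ("macro_precision", "macro_recall", "macro_f1")
        }

    def summary(self) -> str:
        """Human-readable summary table."""
        cfg = self.model.config
        spread = self.macro_spread()
        df = self.per_side_effect
        lines = [
            "Side-effect prediction results",
            "=" * 46,
            f"situation:        {self.report.situation}",
            f"channels:         {','.join(cfg.channels)} (integration: {cfg.integration})",
            f"classifier:       {cfg.classifier.kind}",
            f"balance:          {cfg.balance}   negatives: {cfg.negative_method}",
            f"drugs:            {self.model.dataset.n_drugs}",
            f"side-effects:     {self.model.dataset.n_side_effects}",
            f"cv folds:         {cfg.n_folds}   repeats: {self.report.repeats}   seed: {self.seed}",
            "-" * 46,
            f"macro precision:  {self.macro_precision:.4f} (+/- {spread['macro_precision']:.4f})",
            f"macro recall:     {self.macro_recall:.4f} (+/- {spread['macro_recall']:.4f})",
            f"macro F1:         {self.macro_f1:.4f} (+/- {spread['macro_f1']:.4f})",
            f"per-SE F1 range:  [{df['f1'].min():.4f}, {df['f1'].max():.4f}]",
            "=" * 46,
        ]
        return "\n".join(lines)

    def scatter_data(self, other: "SideEffectResults") -> pd.DataFrame:
        """Per-side-effect F1 pairs for comparing two situations."""
        a = self.per_side_effect["f1"].rename(self.report.situation)
        b = other.per_side_effect["f1"].rename(other.report.situation)
        return pd.concat([b, a], axis=1, join="inner")

    def plot_comparison(self, other: "SideEffectResults", ax=None):
        """Scatter of per-side-effect F1: this situation (y) vs another (x)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(4.5, 4.5))
        data = self.scatter_data(other)
        x, y = data.iloc[:, 0], data.iloc[:, 1]
        ax.scatter(x, y, s=18, alpha=0.7, edgecolor="none")
        ax.plot([0, 1], [0, 1], lw=1, color="grey", label="y = x")
        ax.set_xlim(0, 1)
        ax.set_ylim(0, 1)
        ax.set_xlabel(f"F1 ({other.report.situation})")
        ax.set_ylabel(f"F1 ({self.report.situation})")
        ax.legend(frameon=False)
        return ax
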