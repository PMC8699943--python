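"""Model/Results facade over the diagnostic-accuracy machinery.

:class:`FliValidation` is built from data (scores + reference labels, or
a cohort DataFrame); its :meth:`~FliValidation.fit` runs the ROC sweep,
Youden-optimal cutoff search and fixed-cutoff validation and returns a
:class:`FliValidationResults` carrying estimates, intervals and a
``summary()`` table, in the style of statsmodels model objects.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import accuracy
from ._utils import round_half_up
from .indices import add_fli_column
from .reference import build_reference_labels


class FliValidation:
    """Diagnostic-accuracy validation of the fatty liver index.

    Parameters
    ----------
    scores : array-like
        FLI scores (0-100), one per subject.
    labels : array-like of bool
        Reference-standard steatosis labels aligned with the scores.
    stratum : str
        Name for this sample in reports (e.g. "total", "male").

    Examples
    --------
    >>> from flindex import simulate, FliValidation
    >>> cohort = simulate.generate_cohort(simulate.default_config(seed=7))
    >>> res = FliValidation.from_dataframe(cohort, reference="us").fit()
    >>> round(res.auc, 2) >= 0.7
    True
    """

    def __init__(self, scores, labels, stratum: str = "total"):
        scores = np.asarray(scores, dtype=float)
        labels = np.asarray(labels, dtype=bool)
        keep = ~np.isnan(scores)
        self.scores = scores[keep]
        self.labels = labels[keep]
        self.n_unscored = int((~keep).sum())
        self.stratum = stratum

    @classmethod
    def from_dataframe(cls, cohort: pd.DataFrame, reference: str = "us",
                       cap_threshold: float = 248.0,
                       score_column: str = "fli",
                       stratum: str = "total") -> "FliValidation":
        """Build from a cohort table, computing FLI scores if absent."""
        if score_column not in cohort.columns:
            cohort = add_fli_column(cohort, column=score_column)
        ref = build_reference_labels(cohort, reference=reference,
                                     cap_threshold=cap_threshold)
        scores = cohort.loc[ref.index, score_column].to_numpy(dtype=float)
        model = cls(scores, ref.labels, stratum=stratum)
        model.reference = reference
        model.n_unlabeled = ref.n_dropped
        return model

    def fit(self, grid: str = "integer", cutoffs=(30.0, 60.0),
            ci_method: str = "delong", level: float = 0.95,
            n_boot: int = 2000, seed=None) -> "FliValidationResults":
        """Run the cutoff optimization and fixed-cutoff validation."""
        opt = accuracy.optimal_cutoff_youden(
            self.scores, self.labels, grid=grid, ci_method=ci_method,
            level=level, n_boot=n_boot, seed=seed, stratum=self.stratum)
        fixed = accuracy.evaluate_fixed_cutoffs(
            self.scores, self.labels, cutoffs=cutoffs,
            prevalence=float(self.labels.mean()))
        return FliValidationResults(model=self, optimal=opt,
                                    fixed_cutoffs=fixed, level=level)


@dataclass
class FliValidationResults:
    """Fitted validation results: ROC, optimal cutoff, fixed-cutoff table."""

    model: FliValidation
    optimal: accuracy.CutoffResult
    fixed_cutoffs: pd.DataFrame
    level: float

    @property
    def auc(self) -> float:
        return self.optimal.roc.auc

    @property
    def auc_ci(self) -> tuple:
        return self.optimal.roc.auc_ci

    @property
    def optimal_cutoff(self) -> float:
        return self.optimal.optimal_cutoff

    @property
    def metrics(self) -> accuracy.DiagnosticMetrics:
        return self.optimal.metrics

    @property
    def prevalence(self) -> float:
        return self.optimal.prevalence

    def roc_frame(self) -> pd.DataFrame:
        return self.optimal.roc.to_frame()

    def summary(self) -> str:
        """Human-readable report, percentages rounded half-up to 1 decimal."""
        m = self.metrics
        pct = lambda x: f"{round_half_up(100 * x, 1):.1f}%"
        lo, hi = self.auc_ci
        lines = [
            "Fatty liver index validation",
            "=" * 46,
            f"stratum:            {self.optimal.stratum}",
            f"n subjects:         {self.optimal.n}",
            f"prevalence:         {pct(self.prevalence)}",
            f"AUC ({int(self.level * 100)}% CI):       "
            f"{self.auc:.2f} ({lo:.2f}-{hi:.2f})  [{self.optimal.roc.ci_method}]",
            f"optimal cutoff:     {self.optimal_cutoff:g}",
            f"  Youden J:         {m.youden_j:.3f}",
            f"  sensitivity:      {pct(m.se)}",
            f"  specificity:      {pct(m.sp)}",
            f"  PPV / NPV:        {pct(m.ppv)} / {pct(m.npv)}",
            f"  LR+ / LR-:        {round_half_up(m.plr, 1):g} / "
            f"{round_half_up(m.nlr, 1):g}",
            "",
            "fixed cutoffs:",
        ]
        for _, row in self.fixed_cutoffs.iterrows():
            lines.append(
                f"  >= {row['cutoff']:g}: se {pct(row['se'])}, "
                f"sp {pct(row['sp'])}, ppv {pct(row['ppv'])}, "
                f"npv {pct(row['npv'])}, LR+ {round_half_up(row['plr'], 1):g}"
            )
        return "\n".join(lines)

    def plot_roc(self, ax=None):
        """ROC staircase with the chance diagonal; returns the axes."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(4.5, 4.5))
        frame = self.roc_frame()
        ax.plot(frame["fpr"], frame["se"], drawstyle="steps-post",
                label=f"AUC = {self.auc:.2f}")
        ax.plot([0, 1], [0, 1], ls="--", color="grey", lw=0.8)
        ax.set_xlabel("1 - specificity")
        ax.set_ylabel("sensitivity")
        ax.set_title(f"FLI ROC — {self.optimal.stratum}")
        ax.legend(loc="lower right")
        return ax
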