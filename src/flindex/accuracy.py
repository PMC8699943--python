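"""Diagnostic test accuracy: confusion metrics, ROC, AUC, Youden cutoffs.

Conventions
-----------
* Test-positive means ``score >= cutoff`` (a high fatty liver index
  predicts steatosis; the rule-out phrasing "FLI < 30" is its complement).
* The AUC is the Mann-Whitney estimator: the probability that a random
  diseased subject outscores a random non-diseased one, ties counted 1/2.
  It equals the trapezoidal area under the empirical ROC staircase.
* AUC confidence intervals: DeLong (default, deterministic) or a
  stratified percentile bootstrap.
* Youden's J = sensitivity + specificity - 1; the optimal cutoff
  maximizes J over a grid, ties broken toward the smallest cutoff
  (which maximizes sensitivity at equal J).
* Infinite likelihood ratios are carried as ``inf``, undefined
  quantities as ``nan`` — never as silent sentinel numbers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata

from .indices import add_fli_column
from .reference import build_reference_labels

INTEGER_GRID = np.arange(0.0, 101.0)


class DegenerateLabelsError(ValueError):
    """Labels contain only one class; accuracy metrics are undefined."""


# ---------------------------------------------------------------------------
# containers


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def n_positive(self) -> int:
        return self.tp + self.fn

    @property
    def n_negative(self) -> int:
        return self.tn + self.fp

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class DiagnosticMetrics:
    """Se/Sp/PPV/NPV/LR+/LR-/Youden J, optionally tagged with a cutoff.

    Proportions are on [0, 1]; ``plr`` may be ``inf`` (sp = 1 with
    se > 0) and any undefined quantity is ``nan``.
    """

    se: float
    sp: float
    ppv: float = np.nan
    npv: float = np.nan
    plr: float = np.nan
    nlr: float = np.nan
    youden_j: float = np.nan
    cutoff: float | None = None

    @property
    def plr_infinite(self) -> bool:
        return np.isinf(self.plr)

    def to_dict(self) -> dict:
        d = {
            "se": self.se, "sp": self.sp, "ppv": self.ppv, "npv": self.npv,
            "plr": self.plr, "nlr": self.nlr, "youden_j": self.youden_j,
        }
        if self.cutoff is not None:
            d = {"cutoff": self.cutoff, **d}
        return d


@dataclass
class RocResult:
    """The full cutoff sweep: (se, sp) per cutoff, AUC and its CI."""

    cutoffs: np.ndarray
    se: np.ndarray
    sp: np.ndarray
    auc: float
    auc_ci: tuple
    ci_method: str
    n_positive: int = 0
    n_negative: int = 0

    def to_frame(self) -> pd.DataFrame:
        """Vertices as a table with an ROC-space (1-sp, se) column pair."""
        return pd.DataFrame({
            "cutoff": self.cutoffs,
            "fpr": 1.0 - self.sp,
            "se": self.se,
            "sp": self.sp,
        })


@dataclass
class CutoffResult:
    optimal_cutoff: float
    metrics: DiagnosticMetrics
    roc: RocResult
    stratum: str = "total"
    n: int = 0
    prevalence: float = np.nan


# ---------------------------------------------------------------------------
# validation and counting


def _validate(scores, labels):
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be 1-D and the same length")
    if np.isnan(scores).any():
        raise ValueError("scores contain NaN; drop unscored subjects first")
    if labels.all() or not labels.any():
        raise DegenerateLabelsError("labels contain a single class")
    return scores, labels


def confusion_at_cutoff(scores, labels, cutoff: float) -> ConfusionCounts:
    """Tally the 2x2 table for the rule score >= cutoff."""
    scores, labels = _validate(scores, labels)
    test_pos = scores >= cutoff
    return ConfusionCounts(
        tp=int(np.sum(test_pos & labels)),
        fp=int(np.sum(test_pos & ~labels)),
        tn=int(np.sum(~test_pos & ~labels)),
        fn=int(np.sum(~test_pos & labels)),
    )


def _ratios(se: float, sp: float) -> tuple:
    if sp < 1.0:
        plr = se / (1.0 - sp)
    else:
        plr = np.inf if se > 0 else np.nan
    nlr = (1.0 - se) / sp if sp > 0 else np.nan
    return plr, nlr


def metrics_from_counts(counts: ConfusionCounts,
                        cutoff: float | None = None) -> DiagnosticMetrics:
    """Empirical Se/Sp/PPV/NPV/LR/J from a confusion table."""
    if counts.n_positive == 0 or counts.n_negative == 0:
        raise DegenerateLabelsError("need at least one positive and one negative")
    se = counts.tp / counts.n_positive
    sp = counts.tn / counts.n_negative
    n_test_pos = counts.tp + counts.fp
    n_test_neg = counts.tn + counts.fn
    ppv = counts.tp / n_test_pos if n_test_pos else np.nan
    npv = counts.tn / n_test_neg if n_test_neg else np.nan
    plr, nlr = _ratios(se, sp)
    return DiagnosticMetrics(se=se, sp=sp, ppv=ppv, npv=npv, plr=plr,
                             nlr=nlr, youden_j=se + sp - 1.0, cutoff=cutoff)


def metrics_from_rates(se: float, sp: float, prevalence: float | None = None,
                       cutoff: float | None = None) -> DiagnosticMetrics:
    """Derive LRs, J and (given a prevalence) predictive values from rates.

    Bayes' rule links the printed sensitivity/specificity of a test to
    its post-test probabilities at any disease prevalence p:

        PPV = se*p / (se*p + (1-sp)*(1-p))
        NPV = sp*(1-p) / ((1-se)*p + sp*(1-p))

    With p equal to the sample prevalence these reproduce the empirical
    predictive values exactly.
    """
    for name, v in (("se", se), ("sp", sp)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must be in [0, 1]")
    ppv = npv = np.nan
    if prevalence is not None:
        if not 0.0 <= prevalence <= 1.0:
            raise ValueError("prevalence must be in [0, 1]")
        p = prevalence
        denom_p = se * p + (1.0 - sp) * (1.0 - p)
        denom_n = (1.0 - se) * p + sp * (1.0 - p)
        ppv = se * p / denom_p if denom_p > 0 else np.nan
        npv = sp * (1.0 - p) / denom_n if denom_n > 0 else np.nan
    plr, nlr = _ratios(se, sp)
    return DiagnosticMetrics(se=se, sp=sp, ppv=ppv, npv=npv, plr=plr,
                             nlr=nlr, youden_j=se + sp - 1.0, cutoff=cutoff)


# ---------------------------------------------------------------------------
# AUC and confidence intervals


def auc_mann_whitney(scores, labels) -> float:
    """AUC as the Mann-Whitney U statistic normalized by m*n, ties 1/2."""
    scores, labels = _validate(scores, labels)
    m = int(labels.sum())
    n = labels.size - m
    ranks = rankdata(scores)  # midranks
    return float((ranks[labels].sum() - m * (m + 1) / 2.0) / (m * n))


def _delong_variance(scores, labels):
    """DeLong placement-value variance of the Mann-Whitney AUC."""
    pos = scores[labels]
    neg = scores[~labels]
    m, n = pos.size, neg.size
    tz = rankdata(np.concatenate([pos, neg]))
    tx = rankdata(pos)
    ty = rankdata(neg)
    auc = (tz[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v_pos = (tz[:m] - tx) / n            # placement of each positive
    v_neg = 1.0 - (tz[m:] - ty) / m      # placement of each negative
    s_pos = v_pos.var(ddof=1) if m > 1 else 0.0
    s_neg = v_neg.var(ddof=1) if n > 1 else 0.0
    return float(auc), s_pos / m + s_neg / n


def auc_ci(scores, labels, method: str = "delong", level: float = 0.95,
           n_boot: int = 2000, seed=None) -> tuple:
    """Two-sided confidence interval for the AUC.

    ``delong`` uses the asymptotic placement-value variance (clipped to
    [0, 1]); ``bootstrap`` resamples positives and negatives separately
    (so no resample can be single-class) and takes percentile bounds.
    Deterministic given ``seed``.
    """
    scores, labels = _validate(scores, labels)
    if method == "delong":
        auc, var = _delong_variance(scores, labels)
        z = norm.ppf(0.5 + level / 2.0)
        half = z * np.sqrt(var)
        return (max(0.0, auc - half), min(1.0, auc + half))
    if method == "bootstrap":
        if n_boot < 100:
            raise ValueError("n_boot must be at least 100")
        rng = np.random.default_rng(seed)
        pos = scores[labels]
        neg = scores[~labels]
        m, n = pos.size, neg.size
        stats = np.empty(n_boot)
        for b in range(n_boot):
            bs = np.concatenate([rng.choice(pos, m), rng.choice(neg, n)])
            bl = np.concatenate([np.ones(m, bool), np.zeros(n, bool)])
            stats[b] = auc_mann_whitney(bs, bl)
        alpha = 1.0 - level
        lo, hi = np.quantile(stats, [alpha / 2.0, 1.0 - alpha / 2.0])
        return (float(lo), float(hi))
    raise ValueError(f"unknown CI method {method!r}")


# ---------------------------------------------------------------------------
# ROC sweep and cutoff optimization


def _se_sp_at(scores, labels, cutoffs):
    """Vectorized sensitivity/specificity at each cutoff (rule: >= cutoff)."""
    pos = np.sort(scores[labels])
    neg = np.sort(scores[~labels])
    cutoffs = np.asarray(cutoffs, dtype=float)
    se = 1.0 - np.searchsorted(pos, cutoffs, side="left") / pos.size
    sp = np.searchsorted(neg, cutoffs, side="left") / neg.size
    return se, sp


def roc_curve(scores, labels, ci_method: str = "delong", level: float = 0.95,
              n_boot: int = 2000, seed=None) -> RocResult:
    """Empirical ROC over every distinct score plus -inf/+inf sentinels."""
    scores, labels = _validate(scores, labels)
    cutoffs = np.concatenate([[-np.inf], np.unique(scores), [np.inf]])
    se, sp = _se_sp_at(scores, labels, cutoffs)
    auc = auc_mann_whitney(scores, labels)
    ci = auc_ci(scores, labels, method=ci_method, level=level,
                n_boot=n_boot, seed=seed)
    return RocResult(cutoffs=cutoffs, se=se, sp=sp, auc=auc, auc_ci=ci,
                     ci_method=ci_method, n_positive=int(labels.sum()),
                     n_negative=int((~labels).sum()))


def optimal_cutoff_youden(scores, labels, grid: str = "integer",
                          ci_method: str = "delong", level: float = 0.95,
                          n_boot: int = 2000, seed=None,
                          stratum: str = "total") -> CutoffResult:
    """Cutoff maximizing Youden's J over a grid.

    ``grid='integer'`` scans 0..100 in steps of 1 (the scale the index
    is reported on); ``grid='observed'`` scans every distinct score. On
    ties the smallest cutoff wins.
    """
    scores, labels = _validate(scores, labels)
    if grid == "integer":
        grid_values = INTEGER_GRID
    elif grid == "observed":
        grid_values = np.unique(scores)
    else:
        raise ValueError(f"unknown grid {grid!r}")
    se, sp = _se_sp_at(scores, labels, grid_values)
    j = se + sp - 1.0
    best = int(np.argmax(j))  # first (= smallest) cutoff at the max
    cutoff = float(grid_values[best])
    metrics = metrics_from_counts(confusion_at_cutoff(scores, labels, cutoff),
                                  cutoff=cutoff)
    roc = roc_curve(scores, labels, ci_method=ci_method, level=level,
                    n_boot=n_boot, seed=seed)
    return CutoffResult(
        optimal_cutoff=cutoff, metrics=metrics, roc=roc, stratum=stratum,
        n=scores.size, prevalence=float(labels.mean()),
    )


def evaluate_fixed_cutoffs(scores, labels, cutoffs=(30.0, 60.0),
                           prevalence: float | None = None) -> pd.DataFrame:
    """Validate pre-specified cutoffs; one metrics row per cutoff.

    If an external ``prevalence`` is supplied, prevalence-adjusted
    predictive values (``ppv_adj``, ``npv_adj``) are reported alongside
    the empirical ones.
    """
    scores, labels = _validate(scores, labels)
    rows = []
    for c in cutoffs:
        m = metrics_from_counts(confusion_at_cutoff(scores, labels, c),
                                cutoff=float(c))
        row = m.to_dict()
        if prevalence is not None:
            adj = metrics_from_rates(m.se, m.sp, prevalence=prevalence)
            row["ppv_adj"] = adj.ppv
            row["npv_adj"] = adj.npv
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# cohort-level orchestration


def stratified_analysis(
    cohort: pd.DataFrame,
    reference: str = "us",
    strata: str = "by_sex",
    grid: str = "integer",
    ci_method: str = "delong",
    level: float = 0.95,
    n_boot: int = 2000,
    seed=None,
    cap_threshold: float = 248.0,
    score_column: str = "fli",
) -> list:
    """Youden-optimal cutoff analysis per stratum.

    ``strata='total'`` analyzes the pooled cohort; ``'by_sex'`` adds a
    separate male and female analysis after the pooled one. Strata with
    a single label class are skipped with a warning. FLI scores are
    computed on the fly when the cohort lacks a score column.
    """
    if score_column not in cohort.columns:
        cohort = add_fli_column(cohort, column=score_column)
    ref = build_reference_labels(cohort, reference=reference,
                                 cap_threshold=cap_threshold)
    sub = cohort.loc[ref.index]
    scores = sub[score_column].to_numpy(dtype=float)
    labels = ref.labels
    scored = ~np.isnan(scores)
    sub, scores, labels = sub[scored], scores[scored], labels[scored]

    groups = [("total", np.ones(len(sub), dtype=bool))]
    if strata == "by_sex":
        groups += [(s, (sub["sex"] == s).to_numpy()) for s in ("male", "female")]
    elif strata != "total":
        raise ValueError(f"unknown strata {strata!r}")

    results = []
    for name, mask in groups:
        s, l = scores[mask], labels[mask]
        if s.size == 0 or l.all() or not l.any():
            warnings.warn(f"stratum {name!r} skipped: single-class or empty",
                          stacklevel=2)
            continue
        results.append(
            optimal_cutoff_youden(s, l, grid=grid, ci_method=ci_method,
                                  level=level, n_boot=n_boot, seed=seed,
                                  stratum=name)
        )
    return results
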