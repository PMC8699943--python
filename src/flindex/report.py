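"""Pipeline driver and report tables.

``baseline_table`` produces the sex- and status-stratified descriptive
table (mean +/- SD, median (IQR) for skewed variables, count (%) for
flags, two-group p-values). ``run_pipeline`` chains
read -> exclude -> score -> label -> evaluate -> stratify and writes a
reproducible report bundle: exclusion log, baseline table, fixed-cutoff
and optimal-cutoff tables, ROC vertex files and a JSON manifest.

Report-layer formatting rounds percentages and likelihood ratios
half-up to one decimal; all stored intermediates keep full precision.

In the fixed-cutoff table the per-row AUC is that of the *dichotomized*
test (score >= cutoff as a binary marker), which equals (Se + Sp) / 2 —
the quantity conventionally printed next to fixed-cutoff rows — whereas
the optimal-cutoff table carries the full-ROC AUC.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency, ttest_ind

from . import __version__, accuracy
from ._utils import round_half_up
from .cohort import apply_exclusions, derive_comorbidities, read_cohort, write_cohort
from .indices import add_fli_column, add_gfr_column
from .simulate import SyntheticConfig, default_config, generate_cohort

#: Continuous variables summarized as mean +/- SD, compared by t-test.
NORMAL_VARS = ("age", "sbp", "dbp", "bmi", "wc", "ast", "alt", "ggt", "gfr")
#: Right-skewed variables summarized as median (Q1, Q3), compared by
#: t-test on the log scale.
SKEWED_VARS = ("tg", "cap")
#: Categorical flags summarized as n (%), compared by chi-square.
FLAG_VARS = ("diabetes", "hypertension")


def two_group_ttest(x0, x1):
    """Pooled-variance two-sample t-test; returns (t, p)."""
    x0 = np.asarray(x0, dtype=float)
    x1 = np.asarray(x1, dtype=float)
    x0, x1 = x0[~np.isnan(x0)], x1[~np.isnan(x1)]
    if len(x0) < 2 or len(x1) < 2:
        return np.nan, np.nan
    res = ttest_ind(x0, x1, equal_var=True)
    return float(res.statistic), float(res.pvalue)


def chi_square_test(flags0, flags1):
    """Pearson chi-square (no continuity correction) on a 2x2 table."""
    f0 = pd.Series(flags0).dropna().astype(bool)
    f1 = pd.Series(flags1).dropna().astype(bool)
    if len(f0) == 0 or len(f1) == 0:
        return np.nan
    table = np.array([[(~f0).sum(), f0.sum()], [(~f1).sum(), f1.sum()]])
    if (table.sum(axis=0) == 0).any():
        return np.nan
    return float(chi2_contingency(table, correction=False)[1])


def _fmt_mean_sd(x) -> str:
    x = np.asarray(x, dtype=float)
    x = x[~np.isnan(x)]
    return f"{x.mean():.1f} ± {x.std(ddof=1):.1f}" if x.size > 1 else "NA"


def _fmt_median_iqr(x) -> str:
    x = np.asarray(x, dtype=float)
    x = x[~np.isnan(x)]
    if x.size == 0:
        return "NA"
    q1, med, q3 = np.percentile(x, [25, 50, 75])
    return f"{med:.0f} ({q1:.0f}, {q3:.0f})"


def _fmt_count_pct(flags) -> str:
    f = pd.Series(flags).dropna().astype(bool)
    if len(f) == 0:
        return "NA"
    return f"{int(f.sum())} ({round_half_up(100 * f.mean(), 1):.1f})"


def baseline_table(cohort: pd.DataFrame, reference: str = "us",
                   cap_threshold: float = 248.0) -> pd.DataFrame:
    """Descriptive table stratified by sex and steatosis status.

    One row per (sex, variable); columns carry the formatted group
    summaries, numeric group means and the two-group p-value.
    """
    df = cohort.copy()
    if "hypertension" not in df.columns:
        df = derive_comorbidities(df)
    if "gfr" not in df.columns and df["creatinine"].notna().any():
        df = add_gfr_column(df)
    if reference == "us":
        status = df["us_steatosis"].astype("boolean")
    else:
        status = pd.Series(pd.NA, index=df.index, dtype="boolean")
        have = df["cap"].notna()
        status[have] = (df.loc[have, "cap"] >= cap_threshold)

    rows = []
    for sex in ("male", "female"):
        sel = df["sex"] == sex
        g0 = df[sel & (status == False)]  # noqa: E712 (nullable boolean)
        g1 = df[sel & (status == True)]   # noqa: E712
        if len(g0) < 2 or len(g1) < 2:
            continue
        for var in NORMAL_VARS:
            if var not in df.columns or df[var].isna().all():
                continue
            _, p = two_group_ttest(g0[var], g1[var])
            rows.append((sex, var, _fmt_mean_sd(g0[var]), _fmt_mean_sd(g1[var]),
                         float(np.nanmean(g0[var])), float(np.nanmean(g1[var])), p))
        for var in SKEWED_VARS:
            if var not in df.columns or df[var].isna().all():
                continue
            with np.errstate(invalid="ignore", divide="ignore"):
                _, p = two_group_ttest(np.log(g0[var]), np.log(g1[var]))
            rows.append((sex, var, _fmt_median_iqr(g0[var]),
                         _fmt_median_iqr(g1[var]),
                         float(np.nanmedian(g0[var])),
                         float(np.nanmedian(g1[var])), p))
        for var in FLAG_VARS:
            if var not in df.columns:
                continue
            p = chi_square_test(g0[var], g1[var])
            m0 = float(pd.Series(g0[var]).dropna().astype(bool).mean())
            m1 = float(pd.Series(g1[var]).dropna().astype(bool).mean())
            rows.append((sex, var, _fmt_count_pct(g0[var]),
                         _fmt_count_pct(g1[var]), m0, m1, p))
    return pd.DataFrame(rows, columns=[
        "sex", "variable", "no_nafld", "nafld",
        "mean_no_nafld", "mean_nafld", "p_value",
    ])


# ---------------------------------------------------------------------------
# pipeline


@dataclass
class RunConfig:
    """Everything one pipeline run needs; serializable for the manifest."""

    input_path: str | None = None
    synthetic: dict | None = None     # kwargs for default_config()
    references: tuple = ("us", "cap")
    cutoffs: tuple = (30.0, 60.0)
    grid: str = "integer"
    ci_method: str = "delong"
    level: float = 0.95
    n_boot: int = 2000
    seed: int = 0
    strata: str = "by_sex"
    output_dir: str = "flindex_run"
    male_alcohol_max: float = 20.0
    female_alcohol_max: float = 10.0

    def __post_init__(self) -> None:
        if not self.references:
            raise ValueError("select at least one reference standard")
        if self.input_path is None and self.synthetic is None:
            self.synthetic = {}

    def to_dict(self) -> dict:
        d = asdict(self)
        d["references"] = list(self.references)
        d["cutoffs"] = list(self.cutoffs)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        d["references"] = tuple(d.get("references", ("us", "cap")))
        d["cutoffs"] = tuple(d.get("cutoffs", (30.0, 60.0)))
        return cls(**d)


@dataclass
class PipelineReport:
    """Paths of the artifacts a run produced, plus headline numbers."""

    output_dir: Path
    artifacts: dict = field(default_factory=dict)
    exclusion_log: dict = field(default_factory=dict)
    results: dict = field(default_factory=dict)


def _fixed_cutoff_table(scores, labels, cutoffs, ci_method, level, n_boot,
                        seed, reference):
    prevalence = float(np.mean(labels))
    table = accuracy.evaluate_fixed_cutoffs(scores, labels, cutoffs=cutoffs,
                                            prevalence=prevalence)
    rows = []
    for _, r in table.iterrows():
        binarized = (np.asarray(scores) >= r["cutoff"]).astype(float)
        auc_b = accuracy.auc_mann_whitney(binarized, labels)
        lo, hi = accuracy.auc_ci(binarized, labels, method=ci_method,
                                 level=level, n_boot=n_boot, seed=seed)
        rows.append({
            "reference": reference,
            "cutoff": r["cutoff"],
            "sensitivity_pct": round_half_up(100 * r["se"], 1),
            "specificity_pct": round_half_up(100 * r["sp"], 1),
            "ppv_pct": round_half_up(100 * r["ppv"], 1),
            "npv_pct": round_half_up(100 * r["npv"], 1),
            "auc": round_half_up(auc_b, 2),
            "auc_ci_low": round_half_up(lo, 2),
            "auc_ci_high": round_half_up(hi, 2),
            "plr": round_half_up(r["plr"], 1),
            "nlr": round_half_up(r["nlr"], 1),
        })
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig) -> PipelineReport:
    """Execute the whole validation pipeline and write the report bundle.

    Outputs (under ``config.output_dir``): ``cohort_scored.csv``,
    ``exclusion_log.json``, ``baseline_table.tsv``,
    ``fixed_cutoffs.tsv``, ``optimal_cutoffs.tsv``,
    ``roc_<reference>_<stratum>.tsv`` and ``manifest.json``. Rerunning
    with the same config (and seed) reproduces every file byte for byte.
    On any stage failure the partial outputs are removed and the error
    re-raised with the stage name.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    report = PipelineReport(output_dir=out)

    def _write_tsv(df: pd.DataFrame, name: str) -> None:
        path = out / name
        df.to_csv(path, sep="\t", index=False, float_format="%.6g")
        written.append(path)
        report.artifacts[name] = str(path)

    stage = "read"
    try:
        if config.input_path is not None:
            cohort, parse_report = read_cohort(config.input_path)
            parse_info = {"n_rows": parse_report.n_rows,
                          "n_bad_cells": parse_report.n_bad_cells}
        else:
            syn: SyntheticConfig = default_config(
                seed=config.seed, **{k: v for k, v in config.synthetic.items()
                                     if k != "seed"})
            cohort = generate_cohort(syn)
            parse_info = {"n_rows": len(cohort), "n_bad_cells": 0}

        stage = "exclude"
        cohort, xlog = apply_exclusions(
            cohort, male_alcohol_max=config.male_alcohol_max,
            female_alcohol_max=config.female_alcohol_max)
        report.exclusion_log = xlog.to_dict()
        path = out / "exclusion_log.json"
        xlog.to_json(path)
        written.append(path)
        report.artifacts["exclusion_log.json"] = str(path)

        stage = "score"
        cohort = add_fli_column(cohort)
        if cohort["creatinine"].notna().any():
            cohort = add_gfr_column(cohort)
        cohort = derive_comorbidities(cohort)
        path = out / "cohort_scored.csv"
        write_cohort(cohort, path)
        written.append(path)
        report.artifacts["cohort_scored.csv"] = str(path)

        stage = "baseline"
        base = pd.concat(
            [baseline_table(cohort, reference=r).assign(reference=r)
             for r in config.references],
            ignore_index=True,
        )
        _write_tsv(base, "baseline_table.tsv")

        stage = "evaluate"
        fixed_blocks = []
        optimal_rows = []
        from .reference import build_reference_labels

        for ref_name in config.references:
            ref = build_reference_labels(cohort, reference=ref_name)
            scores = cohort.loc[ref.index, "fli"].to_numpy(dtype=float)
            keep = ~np.isnan(scores)
            scores, labels = scores[keep], ref.labels[keep]
            fixed_blocks.append(
                _fixed_cutoff_table(scores, labels, config.cutoffs,
                                    config.ci_method, config.level,
                                    config.n_boot, config.seed, ref_name))

            stage = "stratify"
            for res in accuracy.stratified_analysis(
                    cohort, reference=ref_name, strata=config.strata,
                    grid=config.grid, ci_method=config.ci_method,
                    level=config.level, n_boot=config.n_boot,
                    seed=config.seed):
                m = res.metrics
                lo, hi = res.roc.auc_ci
                optimal_rows.append({
                    "reference": ref_name,
                    "stratum": res.stratum,
                    "n": res.n,
                    "prevalence_pct": round_half_up(100 * res.prevalence, 1),
                    "cutoff": res.optimal_cutoff,
                    "auc": round_half_up(res.roc.auc, 2),
                    "auc_ci_low": round_half_up(lo, 2),
                    "auc_ci_high": round_half_up(hi, 2),
                    "youden_j": round_half_up(m.youden_j, 3),
                    "sensitivity_pct": round_half_up(100 * m.se, 1),
                    "specificity_pct": round_half_up(100 * m.sp, 1),
                    "ppv_pct": round_half_up(100 * m.ppv, 1),
                    "npv_pct": round_half_up(100 * m.npv, 1),
                })
                _write_tsv(res.roc.to_frame(),
                           f"roc_{ref_name}_{res.stratum}.tsv")
                report.results[f"{ref_name}_{res.stratum}"] = {
                    "cutoff": res.optimal_cutoff, "auc": res.roc.auc,
                    "youden_j": m.youden_j, "prevalence": res.prevalence,
                }

        _write_tsv(pd.concat(fixed_blocks, ignore_index=True),
                   "fixed_cutoffs.tsv")
        _write_tsv(pd.DataFrame(optimal_rows), "optimal_cutoffs.tsv")

        stage = "manifest"
        manifest = {
            "package": "flindex",
            "version": __version__,
            "library_versions": {"numpy": np.__version__,
                                 "pandas": pd.__version__},
            "config": config.to_dict(),
            "parse": parse_info,
            "exclusions": report.exclusion_log,
        }
        path = out / "manifest.json"
        with open(path, "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        written.append(path)
        report.artifacts["manifest.json"] = str(path)
    except Exception as err:
        for p in written:
            p.unlink(missing_ok=True)
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {err}") from err
    return report


def run_from_manifest(manifest_path, output_dir=None) -> PipelineReport:
    """Reproduce a run exactly from its manifest."""
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    config = RunConfig.from_dict(manifest["config"])
    if output_dir is not None:
        config.output_dir = str(output_dir)
    return run_pipeline(config)
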