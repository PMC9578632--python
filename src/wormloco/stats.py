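"""Yoked-trial statistics for the transgenerational intoxication assay.

The experimental unit is a *yoked pair*: a control-line group and an
EtOH-line group assayed side by side on one plate, each recorded at
baseline and again on ethanol.  The analysis layer computes

* normalised locomotion L = on-EtOH score / baseline score per group
  (1 = no change, < 1 = intoxication);
* the yoked difference D = L_etoh_line - L_control_line per pair, in
  which shared plate-level variation cancels;
* a three-factor fixed-effects ANOVA (generation x lineage x condition,
  all interactions, Type III sums of squares with sum-to-zero contrasts
  by default) on the raw scores, with Tukey HSD post-hoc comparisons;
* per-generation two-sided paired t-tests on (L_etoh, L_control) and
  the algebraically equivalent one-sample t-tests of D against 0, with
  Cohen's d on the difference scale (mean(D)/sd(D));
* a Shapiro-Wilk normality gate on each generation's D distribution,
  reported (and warned about) but never silently switching the analysis.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm
from statsmodels.stats.multicomp import pairwise_tukeyhsd

logger = logging.getLogger("wormloco")

__all__ = [
    "TTestResult",
    "NormalityGate",
    "StatsReport",
    "validate_trial_records",
    "normalize_to_baseline",
    "yoked_difference",
    "build_yoked_table",
    "one_sample_t",
    "paired_t",
    "cohens_d",
    "cohens_d_from_stats",
    "three_factor_anova",
    "tukey_hsd",
    "shapiro_wilk_gate",
    "analyze_experiment",
]

GENERATIONS = ("F1", "F2", "F3")
REQUIRED_COLUMNS = {"pair_id", "generation", "lineage", "condition",
                    "n_worms", "area_per_worm"}


def validate_trial_records(records: pd.DataFrame) -> pd.DataFrame:
    """Check the trial-record schema and uniqueness invariants."""
    missing = REQUIRED_COLUMNS - set(records.columns)
    if missing:
        raise ValueError(f"trial records missing columns: {sorted(missing)}")
    if (records["area_per_worm"] < 0).any():
        raise ValueError("area_per_worm must be >= 0")
    dup = records.duplicated(subset=["pair_id", "lineage", "condition"])
    if dup.any():
        raise ValueError(
            f"duplicate (pair_id, lineage, condition) rows: "
            f"{records.loc[dup, 'pair_id'].unique().tolist()}")
    bad_gen = set(records["generation"]) - set(GENERATIONS)
    if bad_gen:
        raise ValueError(f"unknown generation labels: {sorted(bad_gen)}")
    return records


def normalize_to_baseline(etoh_score: float, baseline_score: float,
                          trial: str = "?") -> float:
    """On-EtOH score divided by baseline score for the same group.

    Values below 1 indicate depressed locomotion under ethanol.
    """
    if baseline_score <= 0:
        raise ValueError(
            f"trial {trial}: baseline score must be > 0 to normalize "
            f"(got {baseline_score})")
    return etoh_score / baseline_score


def yoked_difference(normalized_etoh: float, normalized_control: float) -> float:
    """D = EtOH-line normalised locomotion minus control-line's.

    Positive D means relative resistance of the EtOH line, negative D
    relative hypersensitivity.
    """
    return normalized_etoh - normalized_control


def build_yoked_table(records: pd.DataFrame) -> pd.DataFrame:
    """Assemble per-pair normalised values and yoked differences.

    Returns one row per pair_id with columns generation,
    normalized_control, normalized_etoh, yoked_difference.
    """
    validate_trial_records(records)
    gen_counts = records.groupby("pair_id")["generation"].nunique()
    mixed = gen_counts[gen_counts > 1]
    if not mixed.empty:
        raise ValueError(f"pairs spanning several generations: {mixed.index.tolist()}")
    pivot = records.pivot_table(index=["pair_id", "generation"],
                                columns=["lineage", "condition"],
                                values="area_per_worm", aggfunc="first")
    needed = [("control", "baseline"), ("control", "etoh"),
              ("etoh", "baseline"), ("etoh", "etoh")]
    for col in needed:
        if col not in pivot.columns:
            raise ValueError(f"all pairs are missing their {col} trial")
    pivot = pivot[needed]
    incomplete = pivot.index[pivot.isna().any(axis=1)]
    if len(incomplete):
        raise ValueError(
            f"pairs missing a lineage/condition member: "
            f"{[p for p, _ in incomplete]}")
    for lineage in ("control", "etoh"):
        bad = pivot.index[pivot[(lineage, "baseline")] <= 0]
        if len(bad):
            raise ValueError(
                f"baseline score must be > 0 to normalize; offending trials: "
                f"{[f'{p}/{lineage}' for p, _ in bad]}")
    out = pd.DataFrame({
        "pair_id": pivot.index.get_level_values("pair_id"),
        "generation": pivot.index.get_level_values("generation"),
        "normalized_control": (pivot[("control", "etoh")]
                               / pivot[("control", "baseline")]).to_numpy(),
        "normalized_etoh": (pivot[("etoh", "etoh")]
                            / pivot[("etoh", "baseline")]).to_numpy(),
    })
    out["yoked_difference"] = out["normalized_etoh"] - out["normalized_control"]
    return out.reset_index(drop=True)


# ---------------------------------------------------------------------------
# t-tests and effect sizes
# ---------------------------------------------------------------------------

@dataclass
class TTestResult:
    kind: str           # "paired_two_sided" | "one_sample_two_sided"
    t: float
    df: int
    p: float
    mean: float
    sd: float
    n: int
    cohens_d: float

    def significant(self, alpha: float = 0.05) -> bool:
        return self.p < alpha


def one_sample_t(values, mu0: float = 0.0) -> TTestResult:
    """Two-sided one-sample t-test against a hypothesised mean.

    t = (mean - mu0) / (sd / sqrt(n)), df = n - 1, with Cohen's d on the
    same scale, d = (mean - mu0)/sd.  Written out explicitly so the
    paired-test equivalence can be asserted against an independent
    implementation.
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < 3:
        raise ValueError(f"need at least 3 values, got {n}")
    mean = float(x.mean())
    sd = float(x.std(ddof=1))
    if sd == 0:
        raise ValueError("sample standard deviation is 0; t undefined")
    t = (mean - mu0) / (sd / np.sqrt(n))
    df = n - 1
    p = 2.0 * float(scipy.stats.t.sf(abs(t), df))
    return TTestResult(kind="one_sample_two_sided", t=float(t), df=df, p=p,
                       mean=mean, sd=sd, n=n, cohens_d=(mean - mu0) / sd)


def paired_t(a_values, b_values) -> TTestResult:
    """Two-sided paired t-test; equivalent to one_sample_t(a - b, 0)."""
    a = np.asarray(a_values, dtype=float)
    b = np.asarray(b_values, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    if a.size < 3:
        raise ValueError(f"need at least 3 pairs, got {a.size}")
    d = a - b
    sd = float(d.std(ddof=1))
    if sd == 0:
        raise ValueError("all differences equal; t undefined")
    res = scipy.stats.ttest_rel(a, b)
    mean = float(d.mean())
    return TTestResult(kind="paired_two_sided", t=float(res.statistic),
                       df=int(a.size - 1), p=float(res.pvalue), mean=mean,
                       sd=sd, n=int(a.size), cohens_d=mean / sd)


def cohens_d(values, mu0: float = 0.0) -> float:
    """Cohen's d for a one-sample / paired design: (mean - mu0) / sd."""
    x = np.asarray(values, dtype=float)
    sd = float(x.std(ddof=1))
    if sd == 0:
        raise ValueError("standard deviation is 0; d undefined")
    return (float(x.mean()) - mu0) / sd


def cohens_d_from_stats(mean: float, sd: float, mu0: float = 0.0) -> float:
    """Cohen's d from summary statistics (mean and SD of differences)."""
    if sd <= 0:
        raise ValueError("sd must be > 0")
    return (mean - mu0) / sd


# ---------------------------------------------------------------------------
# Factorial ANOVA, Tukey HSD, normality gate
# ---------------------------------------------------------------------------

ANOVA_TERMS = {
    "C(generation, Sum)": "Generation",
    "C(lineage, Sum)": "Lineage",
    "C(condition, Sum)": "Condition",
    "C(generation, Sum):C(lineage, Sum)": "Generation:Lineage",
    "C(generation, Sum):C(condition, Sum)": "Generation:Condition",
    "C(lineage, Sum):C(condition, Sum)": "Lineage:Condition",
    "C(generation, Sum):C(lineage, Sum):C(condition, Sum)":
        "Generation:Lineage:Condition",
}


def three_factor_anova(records: pd.DataFrame, ss_type: int = 3) -> pd.DataFrame:
    """Fixed-effects factorial ANOVA on raw area-per-worm scores.

    Factors generation, lineage and condition with all interactions.
    Defaults to Type III sums of squares with sum-to-zero contrasts
    (appropriate for the unbalanced pair counts); Type I is available
    via ``ss_type=1``.  Returns a table with one row per term plus the
    residual: term, sum_sq, df, F, p.
    """
    validate_trial_records(records)
    data = records.copy()
    for col, min_levels in (("generation", 2), ("lineage", 2), ("condition", 2)):
        if data[col].nunique() < min_levels:
            raise ValueError(f"factor {col!r} needs >= {min_levels} levels")
    if ss_type == 3:
        cells = data.groupby(["generation", "lineage", "condition"],
                             observed=True).size()
        n_expected = (data["generation"].nunique() * data["lineage"].nunique()
                      * data["condition"].nunique())
        if len(cells) < n_expected:
            present = set(cells.index)
            all_cells = {(g, l, c) for g in data["generation"].unique()
                         for l in data["lineage"].unique()
                         for c in data["condition"].unique()}
            raise ValueError(
                f"empty design cells make Type III inestimable: "
                f"{sorted(all_cells - present)}")
    model = smf.ols(
        "area_per_worm ~ C(generation, Sum) * C(lineage, Sum) * C(condition, Sum)",
        data=data).fit()
    if model.df_resid <= 0:
        raise ValueError("no residual degrees of freedom")
    scale = max(model.centered_tss, float(np.sum(model.model.endog ** 2)), 1e-300)
    if model.ssr <= 1e-12 * scale:
        raise ValueError("residual sum of squares is 0; F undefined")
    table = anova_lm(model, typ=ss_type)
    table = table.rename(index=ANOVA_TERMS)
    if "Intercept" in table.index:
        table = table.drop(index="Intercept")
    table = table.rename(columns={"PR(>F)": "p", "F": "F"})
    table.index.name = "term"
    return table[["sum_sq", "df", "F", "p"]]


def tukey_hsd(values, group_labels, alpha: float = 0.05) -> pd.DataFrame:
    """Tukey HSD pairwise comparisons (Tukey-Kramer for unequal n).

    Returns a table of pairwise mean differences with studentized-range
    adjusted p-values.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(group_labels)
    groups, counts = np.unique(labels, return_counts=True)
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    small = groups[counts < 2]
    if small.size:
        raise ValueError(f"groups with fewer than 2 observations: {small.tolist()}")
    res = pairwise_tukeyhsd(values, labels, alpha=alpha)
    frame = pd.DataFrame(res.summary().data[1:],
                         columns=[c.strip() for c in res.summary().data[0]])
    frame = frame.rename(columns={"p-adj": "p_adj", "meandiff": "mean_diff"})
    frame["p_adj"] = np.asarray(res.pvalues, dtype=float)
    frame["mean_diff"] = np.asarray(res.meandiffs, dtype=float)
    return frame[["group1", "group2", "mean_diff", "p_adj", "reject"]]


@dataclass
class NormalityGate:
    group: str
    W: float
    p: float
    passed: bool
    alpha: float = 0.05


def shapiro_wilk_gate(values, group: str = "", alpha: float = 0.05) -> NormalityGate:
    """Shapiro-Wilk normality test as a reported (non-blocking) gate."""
    x = np.asarray(values, dtype=float)
    if not 3 <= x.size <= 5000:
        raise ValueError(f"Shapiro-Wilk requires 3 <= n <= 5000, got {x.size}")
    if np.ptp(x) == 0:
        raise ValueError("constant values; W undefined")
    W, p = scipy.stats.shapiro(x)
    passed = bool(p >= alpha)
    if not passed:
        logger.warning("group %s failed Shapiro-Wilk normality (W=%.4f, p=%.4g); "
                       "analysis proceeds, result is flagged", group, W, p)
    return NormalityGate(group=group, W=float(W), p=float(p), passed=passed,
                         alpha=alpha)


# ---------------------------------------------------------------------------
# Full experiment analysis
# ---------------------------------------------------------------------------

@dataclass
class GenerationResult:
    generation: str
    n_pairs: int
    normality: Optional[NormalityGate]
    paired: Optional[TTestResult]
    one_sample: Optional[TTestResult]
    cohens_d: Optional[float]
    notes: list = field(default_factory=list)


@dataclass
class StatsReport:
    """Machine-readable result of the full yoked analysis."""

    anova: pd.DataFrame
    tukey_generation: Optional[pd.DataFrame]
    per_generation: dict
    yoked: pd.DataFrame
    alpha: float
    ss_type: int
    n_tests_run: int
    flags: list = field(default_factory=list)

    def to_dict(self) -> dict:
        def tt(res):
            return None if res is None else asdict(res)
        return {
            "alpha": self.alpha,
            "ss_type": self.ss_type,
            "n_tests_run": self.n_tests_run,
            "flags": list(self.flags),
            "anova": [
                {"term": term, "sum_sq": float(row["sum_sq"]),
                 "df": float(row["df"]),
                 "F": None if np.isnan(row["F"]) else float(row["F"]),
                 "p": None if np.isnan(row["p"]) else float(row["p"])}
                for term, row in self.anova.iterrows()
            ],
            "tukey_generation": (
                None if self.tukey_generation is None
                else self.tukey_generation.to_dict(orient="records")),
            "per_generation": {
                gen: {
                    "n_pairs": g.n_pairs,
                    "normality": None if g.normality is None else asdict(g.normality),
                    "paired_t": tt(g.paired),
                    "one_sample_t": tt(g.one_sample),
                    "cohens_d": g.cohens_d,
                    "notes": list(g.notes),
                }
                for gen, g in self.per_generation.items()
            },
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True, **kwargs)

    def format_table(self) -> str:
        """Human-readable summary table (term, F or t, p, Significant?)."""
        lines = ["Three-factor ANOVA on raw area-per-worm scores",
                 f"{'term':<36}{'F':>10}{'p':>12}  Significant?"]
        for term, row in self.anova.iterrows():
            if term == "Residual":
                continue
            sig = "Yes" if row["p"] < self.alpha else "No"
            lines.append(f"{term:<36}{row['F']:>10.4g}{row['p']:>12.4g}  {sig}")
        lines.append("")
        lines.append("Per-generation tests on normalised locomotion / yoked differences")
        lines.append(f"{'generation':<12}{'paired t':>10}{'one-sample t':>14}"
                     f"{'p':>12}{'Cohen d':>10}  Significant?")
        for gen, g in self.per_generation.items():
            if g.one_sample is None:
                lines.append(f"{gen:<12}{'—':>10}{'—':>14}{'—':>12}{'—':>10}  "
                             f"(skipped: {'; '.join(g.notes)})")
                continue
            sig = "Yes" if g.one_sample.p < self.alpha else "No"
            lines.append(
                f"{gen:<12}{g.paired.t:>10.4g}{g.one_sample.t:>14.4g}"
                f"{g.one_sample.p:>12.4g}{g.cohens_d:>10.3g}  {sig}")
        if self.tukey_generation is not None:
            lines.append("")
            lines.append("Tukey HSD on the generation main effect")
            for _, row in self.tukey_generation.iterrows():
                lines.append(f"  {row['group1']} vs {row['group2']}: "
                             f"diff={row['mean_diff']:.4g}, p={row['p_adj']:.3g}")
        if self.flags:
            lines.append("")
            lines.append("Flags: " + "; ".join(self.flags))
        return "\n".join(lines)

    def significant_generations(self) -> list:
        return [gen for gen, g in self.per_generation.items()
                if g.one_sample is not None and g.one_sample.p < self.alpha]


def analyze_experiment(records: pd.DataFrame, alpha: float = 0.05,
                       ss_type: int = 3) -> StatsReport:
    """Run the full yoked statistical analysis on a trial-record table.

    Raw scores get the three-factor ANOVA (plus Tukey HSD on the
    generation main effect when it is significant); normalised values
    get per-generation paired t-tests, the equivalent one-sample t-test
    of the yoked differences against 0, Cohen's d, and a Shapiro-Wilk
    normality gate.  Degenerate generations (too few pairs, zero
    variance) are flagged rather than silently dropped.
    """
    validate_trial_records(records)
    for lineage in ("control", "etoh"):
        if lineage not in set(records["lineage"]):
            raise ValueError(f"records contain no {lineage!r} lineage trials")
    for condition in ("baseline", "etoh"):
        if condition not in set(records["condition"]):
            raise ValueError(f"records contain no {condition!r} condition trials")

    yoked = build_yoked_table(records)
    flags: list = []
    n_tests = 0

    try:
        anova = three_factor_anova(records, ss_type=ss_type)
        n_tests += len(anova.index) - 1  # residual row is not a test
    except ValueError as exc:
        anova = pd.DataFrame(columns=["sum_sq", "df", "F", "p"])
        anova.index.name = "term"
        flags.append(f"ANOVA not run ({exc})")
        logger.warning("ANOVA not run: %s", exc)

    tukey_gen = None
    gen_p = anova.loc["Generation", "p"] if "Generation" in anova.index else np.nan
    if np.isfinite(gen_p) and gen_p < alpha and records["generation"].nunique() >= 2:
        tukey_gen = tukey_hsd(records["area_per_worm"].to_numpy(),
                              records["generation"].to_numpy(), alpha=alpha)
        n_tests += len(tukey_gen)

    per_gen: dict = {}
    for gen in GENERATIONS:
        sub = yoked[yoked["generation"] == gen]
        if sub.empty:
            continue
        d = sub["yoked_difference"].to_numpy()
        result = GenerationResult(generation=gen, n_pairs=len(sub),
                                  normality=None, paired=None, one_sample=None,
                                  cohens_d=None)
        try:
            result.normality = shapiro_wilk_gate(d, group=gen, alpha=alpha)
            if not result.normality.passed:
                result.notes.append("failed normality gate")
                flags.append(f"{gen}: yoked differences failed Shapiro-Wilk")
        except ValueError as exc:
            result.notes.append(f"normality gate not applicable: {exc}")
        try:
            result.paired = paired_t(sub["normalized_etoh"].to_numpy(),
                                     sub["normalized_control"].to_numpy())
            result.one_sample = one_sample_t(d, 0.0)
            result.cohens_d = cohens_d(d, 0.0)
            n_tests += 2
        except ValueError as exc:
            result.notes.append(f"t-tests not run: {exc}")
            flags.append(f"{gen}: t-tests not run ({exc})")
        per_gen[gen] = result

    return StatsReport(anova=anova, tukey_generation=tukey_gen,
                       per_generation=per_gen, yoked=yoked, alpha=alpha,
                       ss_type=ss_type, n_tests_run=n_tests, flags=flags)
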