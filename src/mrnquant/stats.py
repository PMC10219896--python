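"""Cohort-level statistical analysis plan.

The plan mirrors standard practice for two-group quantitative nerve-imaging
studies: Mann-Whitney tests for (i) case-vs-control, (ii) proximal-vs-distal
and (iii) left-vs-right comparisons of every marker, Pearson correlations
between markers and demographic/clinical/electrophysiologic covariates, and
a three-group one-way ANOVA (controls vs short- vs long-duration cases, cut
at 3 years since diagnosis) with Tukey HSD post hoc tests.  All tests are
two-tailed at alpha = 0.05 with no multiple-testing correction (the number
of tests run is recorded instead); descriptives are mean ± SEM.

Mann-Whitney p-values use the exact U distribution when the smaller group
has at most 8 observations and no ties are present, and the normal
approximation with tie and continuity corrections otherwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import InvalidParameterError, UndefinedCorrelationError

#: marker name -> region-summary column
MARKER_COLUMNS = {
    "t2_app": "t2_app_ms",
    "rho": "rho_au",
    "t2w_signal": "t2w_signal_au",
    "csa": "csa_mm2",
}

#: covariates entering the correlation matrix (cases)
CORRELATION_COVARIATES = [
    "age", "sex", "height", "weight", "bmi", "edss", "duration",
    "tibial_cmap", "tibial_ncv", "tibial_fwave", "tibial_dml",
    "peroneal_cmap", "peroneal_ncv", "peroneal_fwave", "peroneal_dml",
    "sural_snap", "sural_ncv",
]

EXACT_MAX_N = 8


@dataclass
class GroupComparisonResult:
    marker: str
    region: str
    contrast: str
    group_a: str
    group_b: str
    group_a_mean: float
    group_a_sem: float
    group_b_mean: float
    group_b_sem: float
    u_statistic: float
    p_value: float
    n_a: int
    n_b: int
    method: str = "mann-whitney"


@dataclass
class CorrelationResult:
    marker: str
    region: str
    covariate: str
    r: float
    p_value: float
    n: int


@dataclass
class AnovaResult:
    marker: str
    region: str
    groups: tuple
    f_statistic: float
    p_value: float
    posthoc: dict = field(default_factory=dict)
    posthoc_method: str = "tukey-hsd"


def _mean_sem(x: np.ndarray) -> tuple[float, float]:
    n = len(x)
    sem = float(np.std(x, ddof=1) / math.sqrt(n)) if n > 1 else math.nan
    return float(np.mean(x)), sem


def mann_whitney(values_a, values_b, marker: str = "", region: str = "",
                 contrast: str = "", group_a: str = "a", group_b: str = "b"
                 ) -> GroupComparisonResult:
    """Two-tailed Mann-Whitney U comparison with mean ± SEM attached.

    Exact p (full U distribution) when ``min(n_a, n_b) <= 8`` and the pooled
    sample is tie-free; otherwise the normal approximation with tie and
    continuity corrections.  The reported U is the smaller of the two group
    statistics.  When the two U statistics coincide the two-sided p is
    exactly 1 by symmetry.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise InvalidParameterError("both groups must be non-empty")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise InvalidParameterError("group values must be finite")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    exact = (not has_ties) and min(a.size, b.size) <= EXACT_MAX_N
    method = "exact" if exact else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method,
                           use_continuity=True)
    u1 = float(res.statistic)
    u2 = a.size * b.size - u1
    p = float(res.pvalue)
    if u1 == u2:
        p = 1.0  # two-sided symmetry; the CC'd normal approximation undershoots
    elif math.isnan(p):
        p = 1.0  # zero rank variance: both groups one identical constant
    mean_a, sem_a = _mean_sem(a)
    mean_b, sem_b = _mean_sem(b)
    return GroupComparisonResult(
        marker=marker, region=region, contrast=contrast,
        group_a=group_a, group_b=group_b,
        group_a_mean=mean_a, group_a_sem=sem_a,
        group_b_mean=mean_b, group_b_sem=sem_b,
        u_statistic=min(u1, u2), p_value=min(p, 1.0),
        n_a=int(a.size), n_b=int(b.size),
        method=f"mann-whitney/{method}",
    )


def wilcoxon_paired(values_a, values_b, marker: str = "", region: str = "",
                    contrast: str = "", group_a: str = "a", group_b: str = "b"
                    ) -> GroupComparisonResult:
    """Paired alternative (Wilcoxon signed-rank) for location comparisons."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size != b.size or a.size < 1:
        raise InvalidParameterError("paired samples must match and be non-empty")
    res = sps.wilcoxon(a, b, alternative="two-sided")
    mean_a, sem_a = _mean_sem(a)
    mean_b, sem_b = _mean_sem(b)
    return GroupComparisonResult(
        marker=marker, region=region, contrast=contrast,
        group_a=group_a, group_b=group_b,
        group_a_mean=mean_a, group_a_sem=sem_a,
        group_b_mean=mean_b, group_b_sem=sem_b,
        u_statistic=float(res.statistic), p_value=float(res.pvalue),
        n_a=int(a.size), n_b=int(b.size), method="wilcoxon-signed-rank",
    )


def pearson(x, y, marker: str = "", region: str = "", covariate: str = ""
            ) -> CorrelationResult:
    """Pearson product-moment correlation with two-tailed p (t transform).

    Binary covariates coded 0/1 make this the point-biserial correlation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise InvalidParameterError("need matched samples with n >= 3")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise InvalidParameterError("correlation inputs must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError(
            f"zero variance in correlation input ({marker or 'x'} vs "
            f"{covariate or 'y'})"
        )
    r, p = sps.pearsonr(x, y)
    return CorrelationResult(marker=marker, region=region,
                             covariate=covariate, r=float(r),
                             p_value=float(p), n=int(x.size))


def three_group_anova(values_by_group: dict, marker: str = "",
                      region: str = "") -> AnovaResult:
    """One-way fixed-effects ANOVA over exactly three groups + Tukey HSD.

    F is 0 when the three group means coincide.  Post hoc pairwise p-values
    (Tukey's honestly-significant-difference test) are computed when every
    group has at least two observations.
    """
    if len(values_by_group) != 3:
        raise InvalidParameterError("exactly three groups required")
    groups = tuple(values_by_group)
    arrays = [np.asarray(values_by_group[g], dtype=float) for g in groups]
    if any(a.size == 0 for a in arrays):
        raise InvalidParameterError("all three groups must be non-empty")
    grand = np.concatenate(arrays)
    means = [a.mean() for a in arrays]
    if np.ptp(means) == 0:
        f, p = 0.0, 1.0  # no between-group variability at all
    else:
        f, p = sps.f_oneway(*arrays)
        f, p = float(f), float(p)
    posthoc: dict = {}
    if all(a.size >= 2 for a in arrays) and np.ptp(grand) > 0:
        from statsmodels.stats.multicomp import pairwise_tukeyhsd
        labels = np.concatenate([[g] * a.size for g, a in zip(groups, arrays)])
        tk = pairwise_tukeyhsd(grand, labels)
        for (g1, g2), pv in zip(
                [(r[0], r[1]) for r in tk.summary().data[1:]],
                tk.pvalues):
            posthoc[f"{g1}_vs_{g2}"] = float(pv)
    return AnovaResult(marker=marker, region=region, groups=groups,
                       f_statistic=f, p_value=p, posthoc=posthoc)


def duration_split(clinical_table: pd.DataFrame,
                   threshold_months: float = 36.0) -> pd.Series:
    """Partition cases at 3 years since diagnosis; controls pass through.

    ``duration < threshold`` → ``case_short_duration``; durations at or
    above the boundary (including exactly 36 months) are ``long``.
    """
    groups = clinical_table["group"]
    duration = clinical_table["duration"]
    if ((groups == "case") & duration.isna()).any():
        raise InvalidParameterError("every case needs a symptom duration")
    out = pd.Series("control", index=clinical_table.index, dtype=object)
    is_case = groups == "case"
    out[is_case & (duration < threshold_months)] = "case_short_duration"
    out[is_case & (duration >= threshold_months)] = "case_long_duration"
    return out


@dataclass
class AnalysisResults:
    """Full result set of :func:`analysis_battery`."""

    group_comparisons: list = field(default_factory=list)
    location_comparisons: list = field(default_factory=list)
    side_comparisons: list = field(default_factory=list)
    demographic_comparisons: list = field(default_factory=list)
    correlations: list = field(default_factory=list)
    anovas: list = field(default_factory=list)
    alpha: float = 0.05
    paired_locations: bool = False
    n_correlations_skipped: int = 0

    @property
    def n_tests(self) -> int:
        return (len(self.group_comparisons) + len(self.location_comparisons)
                + len(self.side_comparisons) + len(self.demographic_comparisons)
                + len(self.correlations) + len(self.anovas))

    def to_frame(self) -> pd.DataFrame:
        """Flat table: one row per test (ANOVA post hoc rows included)."""
        rows = []
        for kind, results in [
            ("group", self.group_comparisons),
            ("location", self.location_comparisons),
            ("side", self.side_comparisons),
            ("demographic", self.demographic_comparisons),
        ]:
            for r in results:
                rows.append(dict(
                    analysis=kind, marker=r.marker, region=r.region,
                    contrast=r.contrast, group_a=r.group_a, group_b=r.group_b,
                    n_a=r.n_a, n_b=r.n_b, mean_a=r.group_a_mean,
                    sem_a=r.group_a_sem, mean_b=r.group_b_mean,
                    sem_b=r.group_b_sem, statistic=r.u_statistic,
                    statistic_name="U", p_value=r.p_value, method=r.method,
                    significant=bool(r.p_value < self.alpha),
                ))
        for c in self.correlations:
            rows.append(dict(
                analysis="correlation", marker=c.marker, region=c.region,
                contrast=c.covariate, n_a=c.n, statistic=c.r,
                statistic_name="r", p_value=c.p_value, method="pearson",
                significant=bool(c.p_value < self.alpha),
            ))
        for a in self.anovas:
            rows.append(dict(
                analysis="anova", marker=a.marker, region=a.region,
                contrast="|".join(a.groups), statistic=a.f_statistic,
                statistic_name="F", p_value=a.p_value, method="one-way-anova",
                significant=bool(a.p_value < self.alpha),
            ))
            for pair, pv in a.posthoc.items():
                rows.append(dict(
                    analysis="posthoc", marker=a.marker, region=a.region,
                    contrast=pair, statistic=math.nan, statistic_name="",
                    p_value=pv, method=a.posthoc_method,
                    significant=bool(pv < self.alpha),
                ))
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        df = self.to_frame()
        return {
            "alpha": self.alpha,
            "paired_locations": self.paired_locations,
            "n_tests": self.n_tests,
            "n_correlations_skipped": self.n_correlations_skipped,
            "tests": df.replace({math.nan: None}).to_dict(orient="records"),
        }


def analysis_battery(region_summaries: pd.DataFrame,
                     clinical_table: pd.DataFrame,
                     alpha: float = 0.05,
                     paired_locations: bool = False) -> AnalysisResults:
    """Run the complete analysis plan over region summaries and covariates.

    Inputs are the region-summary table (one row per participant × region,
    columns as written by :mod:`mrnquant.aggregate`) and the clinical table.
    Correlations are evaluated within the case group, where the clinical and
    electrophysiologic covariates exist; covariate pairs with fewer than
    three complete observations or zero variance are skipped and counted.
    """
    res = AnalysisResults(alpha=alpha, paired_locations=paired_locations)
    rs = region_summaries

    def values(group: str, region: str, column: str) -> np.ndarray:
        sel = rs[(rs["group"] == group) & (rs["region"] == region)]
        return sel.sort_values("participant_id")[column].to_numpy()

    # (i) case vs control per marker x region
    for marker, col in MARKER_COLUMNS.items():
        for region in ("thigh", "lower_leg"):
            res.group_comparisons.append(mann_whitney(
                values("case", region, col), values("control", region, col),
                marker=marker, region=region, contrast="case_vs_control",
                group_a="case", group_b="control",
            ))

    # (ii) proximal vs distal within each group
    for group in ("case", "control"):
        for marker, col in MARKER_COLUMNS.items():
            a = values(group, "thigh", col)
            b = values(group, "lower_leg", col)
            fn = wilcoxon_paired if paired_locations else mann_whitney
            res.location_comparisons.append(fn(
                a, b, marker=marker, region="thigh_vs_lower_leg",
                contrast=f"proximal_vs_distal:{group}",
                group_a="thigh", group_b="lower_leg",
            ))

    # (iii) left vs right mid-to-distal thigh within each group
    if (rs["region"] == "right_midthigh").any():
        for group in ("case", "control"):
            for marker, col in MARKER_COLUMNS.items():
                res.side_comparisons.append(mann_whitney(
                    values(group, "left_midthigh", col),
                    values(group, "right_midthigh", col),
                    marker=marker, region="midthigh",
                    contrast=f"left_vs_right:{group}",
                    group_a="left", group_b="right",
                ))

    # demographic comparability of the groups
    for cov in ("age", "weight", "height"):
        a = clinical_table.loc[clinical_table["group"] == "case", cov]
        b = clinical_table.loc[clinical_table["group"] == "control", cov]
        res.demographic_comparisons.append(mann_whitney(
            a.dropna(), b.dropna(), marker=cov, region="",
            contrast="case_vs_control", group_a="case", group_b="control",
        ))

    # correlations: markers vs covariates, case group
    clin = clinical_table.copy()
    clin["sex"] = (clin["sex"] == "M").astype(float)
    clin["bmi"] = clin["weight"] / (clin["height"] / 100.0) ** 2
    cases = clin[clin["group"] == "case"]
    for marker, col in MARKER_COLUMNS.items():
        for region in ("thigh", "lower_leg"):
            mv = rs[(rs["group"] == "case") & (rs["region"] == region)]
            merged = mv.merge(cases, on="participant_id", suffixes=("", "_c"))
            for cov in CORRELATION_COVARIATES:
                pair = merged[[col, cov]].dropna()
                if len(pair) < 3:
                    res.n_correlations_skipped += 1
                    continue
                try:
                    res.correlations.append(pearson(
                        pair[col], pair[cov], marker=marker, region=region,
                        covariate=cov,
                    ))
                except UndefinedCorrelationError:
                    res.n_correlations_skipped += 1

    # duration-split three-group ANOVA
    labels = duration_split(clinical_table)
    label_of = dict(zip(clinical_table["participant_id"], labels))
    if len(set(label_of.values())) == 3:
        for marker, col in MARKER_COLUMNS.items():
            for region in ("thigh", "lower_leg"):
                sel = rs[rs["region"] == region]
                grouped: dict = {"control": [], "case_short_duration": [],
                                 "case_long_duration": []}
                for pid, v in zip(sel["participant_id"], sel[col]):
                    grouped[label_of[pid]].append(v)
                res.anovas.append(three_group_anova(grouped, marker=marker,
                                                    region=region))
    return res
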