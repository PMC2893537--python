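"""Group-comparison statistics for pupillometry cohorts.

Mirrors the published analysis: per-parameter mean ± SD by group, one-way
ANOVA with Bonferroni post-hoc t-tests (pooled within-group variance) for
the healthy-vs-diabetic contrasts, and a Kruskal–Wallis test for the
diabetic-without-CAN vs diabetic-with-CAN contrast.  p < 0.05 is the
significance level; no correction is applied across parameters.

The classical formulas are implemented explicitly (between/within sums of
squares; rank sums with tie correction) so the test suite can cross-check
them against scipy's implementations as an independent oracle.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2 as chi2_dist
from scipy.stats import f as f_dist
from scipy.stats import t as t_dist

from .synthetic import GROUP_LABELS

logger = logging.getLogger(__name__)

# significance markers as printed in the source tables
_STARS = ((0.001, "$"), (0.01, "#"), (0.05, "*"))


def significance_marker(p: float | None, alpha: float = 0.05) -> str:
    if p is None or np.isnan(p):
        return "-"
    for cut, mark in _STARS:
        if p < cut and cut <= alpha:
            return mark
    return "*" if p < alpha else "ns"


@dataclass(frozen=True)
class StatResult:
    """One parameter's row of the results table."""

    parameter: str
    group_means: dict
    group_sds: dict
    group_ns: dict
    anova_F: float
    anova_p: float
    pairwise_p: dict          # Bonferroni-adjusted, keyed by (group, group)
    kruskal_H: float | None
    kruskal_p: float | None
    p1: float | None          # healthy vs diabetic_no_CAN (Bonferroni)
    p2: float | None          # healthy vs diabetic_CAN (Bonferroni)
    p3: float | None          # diabetic_no_CAN vs diabetic_CAN (KW)
    markers: tuple[str, str, str]


def _validate_groups(groups) -> list[np.ndarray]:
    arrs = [np.asarray(g, dtype=float).ravel() for g in groups]
    if len(arrs) < 2:
        raise ValueError("at least two groups are required")
    for a in arrs:
        if a.size < 2:
            raise ValueError("each group needs at least two values")
        if not np.isfinite(a).all():
            raise ValueError("group values must be finite")
    return arrs


def one_way_anova(groups) -> tuple[float, float]:
    """Classical one-way ANOVA: (F statistic, p-value).

    F is the ratio of between-group to within-group mean squares, with
    (k-1, N-k) degrees of freedom.  The degenerate all-constant input uses
    the convention F = 0, p = 1.
    """
    arrs = _validate_groups(groups)
    k = len(arrs)
    ns = np.array([a.size for a in arrs])
    n_total = int(ns.sum())
    grand = np.concatenate(arrs).mean()
    ss_between = float(sum(n * (a.mean() - grand) ** 2
                           for n, a in zip(ns, arrs)))
    ss_within = float(sum(((a - a.mean()) ** 2).sum() for a in arrs))
    df_b, df_w = k - 1, n_total - k
    if ss_within == 0.0:
        if ss_between == 0.0:
            return 0.0, 1.0
        return float("inf"), 0.0
    F = (ss_between / df_b) / (ss_within / df_w)
    p = float(f_dist.sf(F, df_b, df_w))
    return float(F), p


def bonferroni_pairwise(groups, labels=None) -> dict:
    """Post-hoc pairwise t-tests with Bonferroni adjustment.

    Each pair uses the pooled within-group variance over *all* groups
    (MSW on N-k degrees of freedom, the classical post-hoc convention);
    two-sided p-values are multiplied by the number of pairs, capped at 1.
    """
    arrs = _validate_groups(groups)
    k = len(arrs)
    if labels is None:
        labels = list(range(k))
    ns = np.array([a.size for a in arrs])
    df_w = int(ns.sum()) - k
    msw = sum(((a - a.mean()) ** 2).sum() for a in arrs) / df_w
    n_pairs = k * (k - 1) // 2
    out = {}
    for i, j in itertools.combinations(range(k), 2):
        se = np.sqrt(msw * (1.0 / ns[i] + 1.0 / ns[j]))
        if se == 0.0:
            p_raw = 1.0 if arrs[i].mean() == arrs[j].mean() else 0.0
        else:
            t_stat = (arrs[i].mean() - arrs[j].mean()) / se
            p_raw = 2.0 * float(t_dist.sf(abs(t_stat), df_w))
        out[(labels[i], labels[j])] = min(1.0, p_raw * n_pairs)
    return out


def kruskal_wallis(*groups) -> tuple[float, float]:
    """Kruskal–Wallis rank test with tie correction: (H statistic, p-value).

    Implemented in its general k-group form; the published comparison uses
    it with exactly two groups.  All-identical input returns H = 0, p = 1.
    """
    arrs = _validate_groups(groups)
    k = len(arrs)
    pooled = np.concatenate(arrs)
    n = pooled.size
    order = np.argsort(pooled, kind="mergesort")
    ranks = np.empty(n)
    sorted_vals = pooled[order]
    # midranks for ties
    i = 0
    while i < n:
        j = i
        while j + 1 < n and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        ranks[order[i:j + 1]] = 0.5 * (i + j) + 1.0
        i = j + 1
    start = 0
    ssum = 0.0
    for a in arrs:
        rsum = ranks[start:start + a.size].sum()
        ssum += rsum ** 2 / a.size
        start += a.size
    H = 12.0 / (n * (n + 1)) * ssum - 3.0 * (n + 1)
    # tie correction
    _, counts = np.unique(sorted_vals, return_counts=True)
    ties = float(((counts ** 3) - counts).sum())
    denom = 1.0 - ties / (n ** 3 - n)
    if denom == 0.0:
        return 0.0, 1.0
    H /= denom
    p = float(chi2_dist.sf(H, k - 1))
    return float(H), p


def build_results_table(cohort: pd.DataFrame,
                        parameters=None,
                        alpha: float = 0.05) -> list[StatResult]:
    """Per-parameter group comparison over a cohort table.

    ``cohort`` holds one row per subject with a ``group`` column (labels
    from ``healthy / diabetic_no_CAN / diabetic_CAN``) and one numeric
    column per pupillometry parameter.  For each parameter: mean ± SD per
    group (sample SD, n-1), ANOVA + Bonferroni across the three groups
    (p1: healthy vs without CAN, p2: healthy vs with CAN) and
    Kruskal–Wallis between the diabetic groups (p3).
    """
    if cohort is None or len(cohort) == 0:
        raise ValueError("empty cohort")
    if "group" not in cohort.columns:
        raise ValueError("cohort needs a 'group' column")
    bad = set(cohort["group"]) - set(GROUP_LABELS)
    if bad:
        raise ValueError(f"unknown group labels: {sorted(bad)}")
    present = [g for g in GROUP_LABELS if (cohort["group"] == g).any()]
    if len(present) < 2:
        raise ValueError("need at least two groups")
    if parameters is None:
        skip = {"group", "subject_id"}
        parameters = [c for c in cohort.columns
                      if c not in skip and
                      pd.api.types.is_numeric_dtype(cohort[c])]
    results: list[StatResult] = []
    for param in parameters:
        if param not in cohort.columns:
            logger.warning("parameter column %r missing; skipped", param)
            continue
        sub = cohort[["group", param]].dropna()
        samples = {g: sub.loc[sub["group"] == g, param].to_numpy(float)
                   for g in present}
        if any(len(v) < 2 for v in samples.values()):
            logger.warning("parameter %r: fewer than 2 values in a group; "
                           "skipped", param)
            continue
        groups = [samples[g] for g in present]
        F, p_anova = one_way_anova(groups)
        pairwise = bonferroni_pairwise(groups, labels=present)
        p1 = pairwise.get(("healthy", "diabetic_no_CAN"))
        p2 = pairwise.get(("healthy", "diabetic_CAN"))
        kH = kp = p3 = None
        if "diabetic_no_CAN" in samples and "diabetic_CAN" in samples:
            kH, kp = kruskal_wallis(samples["diabetic_no_CAN"],
                                    samples["diabetic_CAN"])
            p3 = kp
        results.append(StatResult(
            parameter=param,
            group_means={g: float(v.mean()) for g, v in samples.items()},
            group_sds={g: float(v.std(ddof=1)) for g, v in samples.items()},
            group_ns={g: int(v.size) for g, v in samples.items()},
            anova_F=F, anova_p=p_anova, pairwise_p=pairwise,
            kruskal_H=kH, kruskal_p=kp, p1=p1, p2=p2, p3=p3,
            markers=(significance_marker(p1, alpha),
                     significance_marker(p2, alpha),
                     significance_marker(p3, alpha)),
        ))
    return results


def results_to_frame(results: list[StatResult]) -> pd.DataFrame:
    """Flatten StatResults into a table shaped like the published ones."""
    rows = []
    for r in results:
        row = {"parameter": r.parameter}
        for g in GROUP_LABELS:
            if g in r.group_means:
                row[f"{g}_mean"] = r.group_means[g]
                row[f"{g}_sd"] = r.group_sds[g]
                row[f"{g}_n"] = r.group_ns[g]
        row.update({"anova_F": r.anova_F, "anova_p": r.anova_p,
                    "p1": r.p1, "p2": r.p2, "p3": r.p3,
                    "sig_p1": r.markers[0], "sig_p2": r.markers[1],
                    "sig_p3": r.markers[2]})
        rows.append(row)
    return pd.DataFrame(rows)
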