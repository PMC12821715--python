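"""Per-protein univariate statistics across strain × stress groups.

One classical equal-variance one-way ANOVA is run per protein across the
seven groups; Benjamini-Hochberg adjusted q-values are flagged against the
two working thresholds (0.05 for a broad set, 0.001 for the stringent set
carried into the pattern screen). Tukey HSD (Tukey-Kramer when unbalanced)
supplies the directional pairwise contrasts, and paired / Welch t-tests
cover targeted two-group comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from arspattern.data_io import StudyDesign
from arspattern.normalization import NormalizedMatrix

DIRECTION_UP = "up"
DIRECTION_DOWN = "down"
DIRECTION_TIE = "tie"


def oneway_anova(groups: Sequence[np.ndarray]) -> tuple[float, float]:
    """Equal-variance one-way ANOVA F and upper-tail p.

    Degenerate inputs are resolved by convention rather than NaN: if every
    observation across all groups is identical, (F, p) = (0, 1); if the
    within-group variance is exactly zero but group means differ, the
    separation is infinitely strong, so (F, p) = (inf, 0).
    """
    arrs = [np.asarray(g, dtype=float) for g in groups]
    if len(arrs) < 2:
        raise ValueError("ANOVA needs at least 2 groups")
    if any(a.size < 1 for a in arrs):
        raise ValueError("every group needs at least 1 observation")
    ns = np.array([a.size for a in arrs])
    total_n = int(ns.sum())
    k = len(arrs)
    if total_n - k < 1:
        raise ValueError("no residual degrees of freedom")
    means = np.array([a.mean() for a in arrs])
    grand = np.concatenate(arrs).mean()
    ssb = float((ns * (means - grand) ** 2).sum())
    ssw = float(sum(((a - m) ** 2).sum() for a, m in zip(arrs, means)))
    df_b, df_w = k - 1, total_n - k
    if ssw == 0.0:
        if ssb == 0.0:
            return 0.0, 1.0
        return float("inf"), 0.0
    f = (ssb / df_b) / (ssw / df_w)
    p = float(stats.f.sf(f, df_b, df_w))
    return float(f), p


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values, input order preserved."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def anova_table(
    normalized: NormalizedMatrix | pd.DataFrame,
    design: StudyDesign,
    thresholds: tuple[float, float] = (0.05, 0.001),
) -> pd.DataFrame:
    """Per-protein one-way ANOVA across all design groups, BH-adjusted.

    Vectorized over proteins. Proteins without ≥2 groups having ≥2
    observations are skipped (q = NaN, reason recorded) but retained in
    the output for completeness; BH adjustment runs over tested proteins
    only. Returns a frame indexed by accession with columns F, p, q,
    significant_005, significant_0001, n_groups_tested, skipped, reason.
    """
    df = normalized.data if isinstance(normalized, NormalizedMatrix) else normalized
    groups = design.groups()
    missing = [s for g in groups.values() for s in g if s not in df.columns]
    if missing:
        raise ValueError(f"design samples absent from matrix: {missing}")

    arr = df.to_numpy(dtype=float)
    usable = [g for g, samples in groups.items() if len(samples) >= 2]
    idx_by_group = {g: [df.columns.get_loc(s) for s in groups[g]] for g in groups}

    n_prot = arr.shape[0]
    if len(usable) < 2:
        out = pd.DataFrame(
            {
                "F": np.nan,
                "p": np.nan,
                "q": np.nan,
                "significant_005": False,
                "significant_0001": False,
                "n_groups_tested": 0,
                "skipped": True,
                "reason": "fewer than 2 groups with ≥2 observations",
            },
            index=df.index,
        )
        return out

    ns = np.array([len(idx_by_group[g]) for g in usable])
    total_n = int(ns.sum())
    k = len(usable)
    gmeans = np.column_stack([arr[:, idx_by_group[g]].mean(axis=1) for g in usable])
    all_cols = [j for g in usable for j in idx_by_group[g]]
    grand = arr[:, all_cols].mean(axis=1)
    ssb = ((gmeans - grand[:, None]) ** 2 * ns[None, :]).sum(axis=1)
    ssw = np.zeros(n_prot)
    for gi, g in enumerate(usable):
        block = arr[:, idx_by_group[g]]
        ssw += ((block - gmeans[:, gi][:, None]) ** 2).sum(axis=1)
    df_b, df_w = k - 1, total_n - k

    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ssb / df_b) / (ssw / df_w)
    degenerate_null = (ssw == 0) & (ssb == 0)
    degenerate_sep = (ssw == 0) & (ssb > 0)
    f = np.where(degenerate_null, 0.0, f)
    f = np.where(degenerate_sep, np.inf, f)
    p = stats.f.sf(np.where(np.isfinite(f), f, 0.0), df_b, df_w)
    p = np.where(degenerate_sep, 0.0, p)
    p = np.where(degenerate_null, 1.0, p)

    q = bh_adjust(p)
    t_broad, t_strict = thresholds
    out = pd.DataFrame(
        {
            "F": f,
            "p": p,
            "q": q,
            "significant_005": q < t_broad,
            "significant_0001": q < t_strict,
            "n_groups_tested": k,
            "skipped": False,
            "reason": "",
        },
        index=df.index,
    )
    out.index.name = "accession"
    return out


@dataclass(frozen=True)
class PairwiseResult:
    """One Tukey HSD contrast: group1 vs group2 for a single protein."""

    group1: str
    group2: str
    mean_difference: float  # group1 − group2
    q_statistic: float
    p: float
    direction: str
    passes_cutoff: bool


def tukey_hsd(
    groups: Sequence[np.ndarray],
    labels: Sequence[str] | None = None,
    cutoff: float = 0.001,
) -> list[PairwiseResult]:
    """All-pairs Tukey HSD (Tukey-Kramer for unbalanced designs).

    The studentized-range statistic for pair (i, j) is
    ``|m_i − m_j| / sqrt(MSW · (1/n_i + 1/n_j) / 2)`` with p-values from
    the studentized range distribution on (k, N−k). When MSW is zero the
    comparison is degenerate: pairs with unequal means get p = 0 and equal
    means get p = 1.
    """
    arrs = [np.asarray(g, dtype=float) for g in groups]
    if labels is None:
        labels = [f"group{i}" for i in range(len(arrs))]
    if len(labels) != len(arrs):
        raise ValueError("labels must match groups")
    if len(arrs) < 2:
        raise ValueError("Tukey HSD needs at least 2 groups")
    ns = np.array([a.size for a in arrs])
    k = len(arrs)
    total_n = int(ns.sum())
    df_w = total_n - k
    if df_w < 1:
        raise ValueError("no residual degrees of freedom")
    means = np.array([a.mean() for a in arrs])
    ssw = float(sum(((a - m) ** 2).sum() for a, m in zip(arrs, means)))
    msw = ssw / df_w

    results: list[PairwiseResult] = []
    for i, j in combinations(range(k), 2):
        diff = float(means[i] - means[j])
        if msw == 0.0:
            qstat = float("inf") if diff != 0 else 0.0
            p = 0.0 if diff != 0 else 1.0
        else:
            se = np.sqrt(msw * (1.0 / ns[i] + 1.0 / ns[j]) / 2.0)
            qstat = abs(diff) / se
            p = float(stats.studentized_range.sf(qstat, k, df_w))
        if diff > 0:
            direction = DIRECTION_UP
        elif diff < 0:
            direction = DIRECTION_DOWN
        else:
            direction = DIRECTION_TIE
        results.append(
            PairwiseResult(
                group1=labels[i],
                group2=labels[j],
                mean_difference=diff,
                q_statistic=float(qstat),
                p=p,
                direction=direction,
                passes_cutoff=p < cutoff,
            )
        )
    return results


def tukey_table(
    normalized: NormalizedMatrix | pd.DataFrame,
    design: StudyDesign,
    accessions: Sequence[str] | None = None,
    cutoff: float = 0.001,
) -> pd.DataFrame:
    """Tukey HSD contrasts for each requested protein, as a long table."""
    df = normalized.data if isinstance(normalized, NormalizedMatrix) else normalized
    if accessions is None:
        accessions = list(df.index)
    groups = design.groups()
    labels = list(groups)
    rows = []
    for acc in accessions:
        vals = [df.loc[acc, groups[g]].to_numpy() for g in labels]
        for r in tukey_hsd(vals, labels, cutoff=cutoff):
            rows.append(
                {
                    "accession": acc,
                    "group1": r.group1,
                    "group2": r.group2,
                    "mean_difference": r.mean_difference,
                    "q_statistic": r.q_statistic,
                    "p": r.p,
                    "direction": r.direction,
                    "passes_cutoff": r.passes_cutoff,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "accession",
            "group1",
            "group2",
            "mean_difference",
            "q_statistic",
            "p",
            "direction",
            "passes_cutoff",
        ],
    )


def pairwise_ttest(
    group1: Sequence[float], group2: Sequence[float], mode: str = "welch"
) -> tuple[float, float]:
    """Two-sided t-test between two groups.

    ``paired`` pairs observations by replicate index (differences, df=n−1);
    ``welch`` is the unequal-variance test with Welch-Satterthwaite df and
    is the recommended default for independent cultures.
    """
    a = np.asarray(group1, dtype=float)
    b = np.asarray(group2, dtype=float)
    if mode == "paired":
        if a.size != b.size:
            raise ValueError("paired mode requires equal-length groups")
        if a.size < 2:
            raise ValueError("paired t-test needs n ≥ 2")
        d = a - b
        if np.std(d, ddof=1) == 0:
            raise ValueError("undefined t: zero-variance differences in paired mode")
        res = stats.ttest_rel(a, b)
    elif mode == "welch":
        if a.size < 2 or b.size < 2:
            raise ValueError("welch t-test needs n ≥ 2 per group")
        res = stats.ttest_ind(a, b, equal_var=False)
    else:
        raise ValueError(f"unknown t-test mode {mode!r}")
    return float(res.statistic), float(res.pvalue)


def group_summaries(
    normalized: NormalizedMatrix | pd.DataFrame,
    design: StudyDesign,
    accessions: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Boxplot-style five-number summaries plus the mean, per protein × group.

    Quartiles use linear interpolation (the numpy default), matching the
    convention of standard boxplot implementations.
    """
    df = normalized.data if isinstance(normalized, NormalizedMatrix) else normalized
    if accessions is None:
        accessions = list(df.index)
    groups = design.groups()
    for g, samples in groups.items():
        if len(samples) == 0:
            raise ValueError(f"group {g!r} has no samples")
    rows = []
    for acc in accessions:
        for g, samples in groups.items():
            v = df.loc[acc, samples].to_numpy(dtype=float)
            q1, med, q3 = np.percentile(v, [25, 50, 75])
            rows.append(
                {
                    "accession": acc,
                    "group": g,
                    "min": float(v.min()),
                    "q1": float(q1),
                    "median": float(med),
                    "q3": float(q3),
                    "max": float(v.max()),
                    "mean": float(v.mean()),
                    "n": int(v.size),
                }
            )
    return pd.DataFrame(rows)
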