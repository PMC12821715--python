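"""The directional "ArsR-dependent" pattern classifier and screen.

A protein shows the pattern of interest when its mean abundance is higher
wherever ArsR is present than in the arsRBC deletion mutant (AW3110), in
the control condition, the arsenite condition, or both:

* control branch:  mean(arsR-complement control) > mean(AW3110 control)
  AND mean(K-12 control) > mean(AW3110 control)
* arsenite branch: mean(arsR-complement high) > mean(AW3110 high)
  AND (mean(K-12 low) > mean(AW3110 high) OR mean(K-12 high) > mean(AW3110 high))

Inequalities are strict; ties never fire. Under exchangeable (null) group
means the rule alone fires with probability 11/18 — the control branch
requires the AW3110 mean to be the minimum of three iid means (P = 1/3)
and the arsenite branch holds for 10 of the 24 orderings of four iid means
(P = 5/12) — so the rule is only meaningful downstream of the ANOVA
significance prefilter, which is what controls false discoveries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from arspattern.data_io import (
    GROUP_ARSR_C,
    GROUP_ARSR_H,
    GROUP_AW_C,
    GROUP_AW_H,
    GROUP_K12_C,
    GROUP_K12_H,
    GROUP_K12_L,
    REFERENCE_GROUPS,
    StudyDesign,
)
from arspattern.normalization import NormalizedMatrix

BRANCH_CONTROL = "control"
BRANCH_ARSENITE = "arsenite"
BRANCH_BOTH = "both"
BRANCH_NONE = "none"
# deterministic report order: strongest evidence class first
BRANCH_ORDER = {BRANCH_BOTH: 0, BRANCH_CONTROL: 1, BRANCH_ARSENITE: 2, BRANCH_NONE: 3}


@dataclass(frozen=True)
class PatternCall:
    """Verdict of the inclusion rule for one protein."""

    accession: str
    included: bool
    branch: str
    control_margin: float  # min(arsR_C − AW_C, K12_C − AW_C)
    arsenite_margin: float  # min(arsR_H − AW_H, max(K12_L, K12_H) − AW_H)


def compute_group_means(
    normalized: NormalizedMatrix | pd.DataFrame, design: StudyDesign
) -> pd.DataFrame:
    """Arithmetic mean normalized abundance per protein × group.

    Requires all seven reference groups to be present in the design with
    at least one sample each.
    """
    df = normalized.data if isinstance(normalized, NormalizedMatrix) else normalized
    groups = design.groups()
    missing = [g for g in REFERENCE_GROUPS if g not in groups or not groups[g]]
    if missing:
        raise ValueError(f"design is missing reference groups: {missing}")
    out = pd.DataFrame(
        {g: df[groups[g]].mean(axis=1) for g in REFERENCE_GROUPS}, index=df.index
    )
    out.index.name = "accession"
    return out


def classify_arsr_dependent(means: pd.DataFrame, margin: float = 0.0) -> pd.DataFrame:
    """Apply the inclusion rule to a protein × group-mean frame.

    ``margin`` is an optional robustness buffer in normalized units: a
    branch fires only if every required difference exceeds it (default 0,
    i.e. plain strict inequality). Returns a frame indexed by accession
    with columns included, branch, control_margin, arsenite_margin.
    """
    required = set(REFERENCE_GROUPS)
    missing = required - set(means.columns)
    if missing:
        raise ValueError(f"group means missing columns: {sorted(missing)}")

    arsr_c = means[GROUP_ARSR_C].to_numpy(dtype=float)
    aw_c = means[GROUP_AW_C].to_numpy(dtype=float)
    k12_c = means[GROUP_K12_C].to_numpy(dtype=float)
    arsr_h = means[GROUP_ARSR_H].to_numpy(dtype=float)
    aw_h = means[GROUP_AW_H].to_numpy(dtype=float)
    k12_l = means[GROUP_K12_L].to_numpy(dtype=float)
    k12_h = means[GROUP_K12_H].to_numpy(dtype=float)

    control_margin = np.minimum(arsr_c - aw_c, k12_c - aw_c)
    arsenite_margin = np.minimum(arsr_h - aw_h, np.maximum(k12_l, k12_h) - aw_h)
    control_fires = control_margin > margin
    arsenite_fires = arsenite_margin > margin

    branch = np.full(len(means), BRANCH_NONE, dtype=object)
    branch[control_fires & ~arsenite_fires] = BRANCH_CONTROL
    branch[~control_fires & arsenite_fires] = BRANCH_ARSENITE
    branch[control_fires & arsenite_fires] = BRANCH_BOTH

    out = pd.DataFrame(
        {
            "included": control_fires | arsenite_fires,
            "branch": branch,
            "control_margin": control_margin,
            "arsenite_margin": arsenite_margin,
        },
        index=means.index,
    )
    out.index.name = "accession"
    return out


def classify_one(means: pd.Series | dict, accession: str = "", margin: float = 0.0) -> PatternCall:
    """Single-protein convenience wrapper around :func:`classify_arsr_dependent`."""
    frame = pd.DataFrame([dict(means)], index=[accession or "protein"])
    row = classify_arsr_dependent(frame, margin=margin).iloc[0]
    return PatternCall(
        accession=accession or "protein",
        included=bool(row["included"]),
        branch=str(row["branch"]),
        control_margin=float(row["control_margin"]),
        arsenite_margin=float(row["arsenite_margin"]),
    )


def screen(
    anova: pd.DataFrame,
    calls: pd.DataFrame,
    fdr_threshold: float = 0.001,
) -> list[str]:
    """Intersect the ANOVA-significant set with the pattern-positive set.

    The prerequisite is q < ``fdr_threshold`` (default the stringent 0.001
    set). The two inputs must be keyed by the same accessions — a mismatch
    means the pipeline stages were run on different matrices, a hard
    error. The result is sorted deterministically: by branch (both,
    control, arsenite), then by descending minimum firing margin, then by
    accession.
    """
    a_idx, c_idx = set(anova.index), set(calls.index)
    if a_idx != c_idx:
        odd = sorted(a_idx.symmetric_difference(c_idx))[:5]
        raise ValueError(f"misaligned pipeline: accessions differ between inputs {odd}")

    sig = anova["q"] < fdr_threshold
    hit = calls.loc[calls["included"] & sig.reindex(calls.index)]

    def min_margin(row: pd.Series) -> float:
        if row["branch"] == BRANCH_CONTROL:
            return row["control_margin"]
        if row["branch"] == BRANCH_ARSENITE:
            return row["arsenite_margin"]
        return min(row["control_margin"], row["arsenite_margin"])

    keyed = sorted(
        hit.index,
        key=lambda acc: (
            BRANCH_ORDER[hit.loc[acc, "branch"]],
            -min_margin(hit.loc[acc]),
            acc,
        ),
    )
    return keyed


def null_inclusion_probability() -> float:
    """Exact firing probability of the rule under iid group means: 11/18."""
    return 11.0 / 18.0
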