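"""Synthetic label-free proteomics experiments with planted ground truth.

Emulates the study design — 3 strains × control/arsenite = 7 groups × 3
replicates — with per-protein log-normal baseline intensities, planted
multiplicative effects, multiplicative within-group noise, and non-detect
dropout applied last (so non-detection behaves like a censoring process at
the instrument's detection limit).

Planted effect classes:

* ``arsr_dependent`` — fold applied in every group where ArsR protein is
  present (by default the complemented strain's two groups and the two
  arsenite-treated K-12 groups); these are the true positives the
  downstream pattern screen should recover.
* ``arsenite_responsive`` — fold applied in every arsenite-treated group,
  regardless of strain; a general stress response.
* ``inverse`` — fold applied only in the deletion mutant's groups
  (a GshA-like compensatory profile); must NOT be picked up by the screen.
* ``null`` — baseline only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from arspattern.data_io import (
    GROUP_ARSR_C,
    GROUP_ARSR_H,
    GROUP_AW_C,
    GROUP_AW_H,
    GROUP_K12_H,
    GROUP_K12_L,
    IntensityMatrix,
    StudyDesign,
    reference_design,
)

CLASS_NULL = "null"
CLASS_ARSR = "arsr_dependent"
CLASS_ARSENITE = "arsenite_responsive"
CLASS_INVERSE = "inverse"

# Groups in which ArsR protein is observed: the complement expresses it
# constitutively; K-12 induces it under arsenite. The trace single-replicate
# signal in the K-12 control is treated as absence.
DEFAULT_ARSR_PRESENT_GROUPS = (GROUP_ARSR_C, GROUP_ARSR_H, GROUP_K12_L, GROUP_K12_H)
ARSENITE_GROUPS = (GROUP_AW_H, GROUP_ARSR_H, GROUP_K12_L, GROUP_K12_H)
AW_GROUPS = (GROUP_AW_C, GROUP_AW_H)


@dataclass
class SyntheticSpec:
    """Parameters of one synthetic experiment.

    Baselines are log-normal: per-protein log10 mean drawn from
    Normal(baseline_log10_mean, baseline_log10_sd), matching the heavy
    right tail of shotgun-proteomics intensity distributions (raw
    intensities spanning roughly 1e5–1e9). ``noise_cv`` is the within-group
    coefficient of variation of the multiplicative replicate noise.
    Non-detection is a censoring process at the instrument's detection
    limit, so the default ``dropout_mode`` is ``censor``: a logistic on
    log10 intensity whose midpoint is calibrated so the overall zero
    fraction matches ``dropout_rate``, preferentially zeroing low-intensity
    cells. ``uniform`` instead zeroes every cell independently with
    probability ``dropout_rate`` (intensity-blind). Explicit
    ``dropout_slope``/``dropout_midpoint`` override the calibration.
    """

    n_proteins: int = 2000
    baseline_log10_mean: float = 7.0
    baseline_log10_sd: float = 1.0
    n_arsr_dependent: int = 30
    arsr_fold: float = 4.0
    n_arsenite_responsive: int = 100
    arsenite_fold: float = 3.0
    n_inverse: int = 10
    inverse_fold: float = 3.0
    noise_cv: float = 0.2
    dropout_rate: float = 0.05
    dropout_mode: str = "censor"
    dropout_slope: float | None = None
    dropout_midpoint: float | None = None
    seed: int = 0
    n_replicates: int = 3
    arsr_present_groups: tuple[str, ...] = DEFAULT_ARSR_PRESENT_GROUPS

    def __post_init__(self) -> None:
        planted = self.n_arsr_dependent + self.n_arsenite_responsive + self.n_inverse
        if planted > self.n_proteins:
            raise ValueError(
                f"planted classes ({planted}) exceed n_proteins ({self.n_proteins})"
            )
        for name in ("arsr_fold", "arsenite_fold", "inverse_fold"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not 0 <= self.dropout_rate < 1:
            raise ValueError("dropout_rate must lie in [0, 1)")
        if self.dropout_mode not in ("censor", "uniform"):
            raise ValueError("dropout_mode must be 'censor' or 'uniform'")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be ≥ 0")
        if self.n_proteins < 1 or self.n_replicates < 1:
            raise ValueError("n_proteins and n_replicates must be ≥ 1")


@dataclass
class SyntheticTruth:
    """Planted per-protein labels: class, true fold, affected groups."""

    table: pd.DataFrame  # columns: accession, truth_class, fold, affected_groups

    def class_counts(self) -> dict[str, int]:
        return self.table["truth_class"].value_counts().to_dict()

    def accessions_of(self, truth_class: str) -> list[str]:
        sel = self.table.loc[self.table["truth_class"] == truth_class, "accession"]
        return list(sel)


# Steepness of the default detection-limit logistic, per log10 decade.
# The transition (detection probability 0.08 → 0.92) spans ~±0.1 decade
# around the midpoint — narrow relative to typical biological folds, so
# non-detection behaves like near-deterministic censoring at the limit
# while proteins whose noise straddles it still show sporadic
# single-replicate dropouts.
DEFAULT_CENSOR_SLOPE = 25.0


def calibrate_censoring_midpoint(
    values: np.ndarray, slope: float, rate: float
) -> float:
    """Midpoint (log10 intensity) at which logistic censoring with the
    given slope zeroes the expected fraction ``rate`` of positive cells.

    The expected dropout fraction is monotone increasing in the midpoint,
    so a bisection over the observed log-intensity range suffices.
    """
    from scipy.special import expit

    logx = np.log10(values[values > 0])
    lo, hi = logx.min() - 10.0, logx.max() + 10.0
    for _ in range(100):
        mid = 0.5 * (lo + hi)
        frac = float(expit(-slope * (logx - mid)).mean())
        if frac < rate:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _lognormal_sigma(cv: float) -> float:
    # CV of a log-normal: cv^2 = exp(sigma^2) - 1 (natural-log scale).
    return float(np.sqrt(np.log1p(cv**2)))


def generate_experiment(
    spec: SyntheticSpec,
) -> tuple[IntensityMatrix, StudyDesign, SyntheticTruth]:
    """Simulate one experiment; deterministic for a given ``spec.seed``.

    Effects are multiplicative folds applied to group mean intensities
    before replicate noise and dropout, so with dropout 0 and noise_cv → 0
    the realized group-mean ratios equal the specified folds exactly.
    """
    design = reference_design(spec.n_replicates)
    rng = np.random.default_rng(spec.seed)
    n = spec.n_proteins
    accessions = [f"SYN{i:05d}" for i in range(n)]

    classes = np.array([CLASS_NULL] * n, dtype=object)
    folds = np.ones(n)
    i0 = 0
    for cls, count, fold in (
        (CLASS_ARSR, spec.n_arsr_dependent, spec.arsr_fold),
        (CLASS_ARSENITE, spec.n_arsenite_responsive, spec.arsenite_fold),
        (CLASS_INVERSE, spec.n_inverse, spec.inverse_fold),
    ):
        classes[i0 : i0 + count] = cls
        folds[i0 : i0 + count] = fold
        i0 += count

    affected = {
        CLASS_NULL: (),
        CLASS_ARSR: tuple(spec.arsr_present_groups),
        CLASS_ARSENITE: ARSENITE_GROUPS,
        CLASS_INVERSE: AW_GROUPS,
    }

    baseline = 10.0 ** rng.normal(spec.baseline_log10_mean, spec.baseline_log10_sd, size=n)

    sample_ids = design.sample_ids
    sample_group = dict(zip(design.table["sample_id"], design.table["group_label"]))
    group_mean = np.empty((n, len(sample_ids)))
    for j, sid in enumerate(sample_ids):
        g = sample_group[sid]
        mult = np.where(
            [g in affected[c] for c in classes],
            folds,
            1.0,
        )
        group_mean[:, j] = baseline * mult

    sigma = _lognormal_sigma(spec.noise_cv)
    if sigma > 0:
        # mean-one multiplicative log-normal noise
        noise = rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=group_mean.shape)
    else:
        noise = 1.0
    values = group_mean * noise

    matrix = IntensityMatrix(pd.DataFrame(values, index=accessions, columns=sample_ids))
    dropout_seed = int(rng.integers(0, 2**31 - 1))
    if spec.dropout_slope is not None or spec.dropout_midpoint is not None:
        matrix = apply_dropout(
            matrix, slope=spec.dropout_slope, midpoint=spec.dropout_midpoint, seed=dropout_seed
        )
    elif spec.dropout_rate > 0 and spec.dropout_mode == "censor":
        midpoint = calibrate_censoring_midpoint(
            matrix.values, DEFAULT_CENSOR_SLOPE, spec.dropout_rate
        )
        matrix = apply_dropout(
            matrix, slope=DEFAULT_CENSOR_SLOPE, midpoint=midpoint, seed=dropout_seed
        )
    else:
        matrix = apply_dropout(matrix, rate=spec.dropout_rate, seed=dropout_seed)

    truth = SyntheticTruth(
        pd.DataFrame(
            {
                "accession": accessions,
                "truth_class": classes,
                "fold": folds,
                "affected_groups": [";".join(affected[c]) for c in classes],
            }
        )
    )
    return matrix, design, truth


def apply_dropout(
    matrix: IntensityMatrix,
    rate: float = 0.0,
    slope: float | None = None,
    midpoint: float | None = None,
    seed: int = 0,
) -> IntensityMatrix:
    """Zero out cells to emulate non-detection.

    With ``slope``/``midpoint`` unset, every positive cell is zeroed
    independently with probability ``rate``. In logistic mode the per-cell
    dropout probability is ``sigmoid(-slope * (log10(x) - midpoint))``,
    so cells below the midpoint intensity are lost preferentially —
    mimicking an MS detection limit.
    """
    if not 0 <= rate < 1:
        raise ValueError("dropout rate must lie in [0, 1)")
    logistic = slope is not None or midpoint is not None
    if logistic and (slope is None or midpoint is None):
        raise ValueError("logistic dropout requires both slope and midpoint")

    values = matrix.data.to_numpy().copy()
    positive = values > 0
    if not logistic and rate == 0:
        return IntensityMatrix(matrix.data.copy(), dict(matrix.protein_names))

    rng = np.random.default_rng(seed)
    if logistic:
        with np.errstate(divide="ignore"):
            logx = np.where(positive, np.log10(np.where(positive, values, 1.0)), 0.0)
        from scipy.special import expit

        p = expit(-float(slope) * (logx - float(midpoint)))
    else:
        p = np.full(values.shape, rate)
    drop = positive & (rng.random(values.shape) < p)
    values[drop] = 0.0
    return IntensityMatrix(
        pd.DataFrame(values, index=matrix.data.index, columns=matrix.data.columns),
        dict(matrix.protein_names),
    )
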