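"""MetaboAnalyst-style preprocessing chain for intensity matrices.

Default step order: impute non-detects → sum-normalize samples → log10 →
autoscale features. Sum normalization divides each sample column by its
total (removing loading/depth differences), and autoscaling standardizes
each protein row to mean 0 / sample sd 1 so that every protein contributes
comparably to multivariate analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from arspattern.data_io import IntensityMatrix

IMPUTE_FIFTH_MIN = "fifth_of_feature_min"
IMPUTE_NONE = "none"

STEP_IMPUTE = "impute"
STEP_SUM = "sum"
STEP_LOG10 = "log10"
STEP_AUTOSCALE = "autoscale"
DEFAULT_STEPS = (STEP_IMPUTE, STEP_SUM, STEP_LOG10, STEP_AUTOSCALE)


@dataclass
class NormalizationConfig:
    impute_strategy: str = IMPUTE_FIFTH_MIN
    steps: tuple[str, ...] = DEFAULT_STEPS
    drop_constant_features: bool = True

    def __post_init__(self) -> None:
        if self.impute_strategy not in (IMPUTE_FIFTH_MIN, IMPUTE_NONE):
            raise ValueError(f"unknown impute strategy {self.impute_strategy!r}")
        unknown = set(self.steps) - set(DEFAULT_STEPS)
        if unknown:
            raise ValueError(f"unknown normalization steps: {sorted(unknown)}")


@dataclass
class NormalizedMatrix:
    """Result of the preprocessing chain.

    ``data`` has the same labels as the input minus dropped proteins;
    ``nondetect_mask`` marks cells that were originally 0 (i.e. imputed);
    ``dropped`` maps each removed accession to the reason; ``provenance``
    lists the applied steps in order.
    """

    data: pd.DataFrame
    nondetect_mask: pd.DataFrame
    provenance: list[str] = field(default_factory=list)
    dropped: dict[str, str] = field(default_factory=dict)

    @property
    def accessions(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    def dropped_report(self) -> pd.DataFrame:
        return pd.DataFrame(
            sorted(self.dropped.items()), columns=["accession", "reason"]
        )


def impute_nondetects(
    matrix: IntensityMatrix, strategy: str = IMPUTE_FIFTH_MIN
) -> tuple[IntensityMatrix, dict[str, str]]:
    """Replace non-detect zeros; returns (matrix, dropped accessions).

    ``fifth_of_feature_min`` substitutes each 0 with one fifth of that
    protein's minimum positive intensity across samples — a conservative
    "below detection limit" value. Proteins never detected anywhere have
    no positive minimum and are dropped (reported, not an error). With
    strategy ``none``, any protein containing a zero is dropped instead,
    since log10(0) is undefined downstream.
    """
    df = matrix.data.copy()
    dropped: dict[str, str] = {}
    if strategy == IMPUTE_NONE:
        has_zero = (df == 0).any(axis=1)
        for acc in df.index[has_zero]:
            dropped[acc] = "contains non-detects (imputation disabled)"
        df = df.loc[~has_zero]
    elif strategy == IMPUTE_FIFTH_MIN:
        arr = df.to_numpy()
        pos = np.where(arr > 0, arr, np.inf)
        row_min = pos.min(axis=1)
        all_zero = ~np.isfinite(row_min)
        for acc in df.index[all_zero]:
            dropped[acc] = "never detected in any sample"
        keep = ~all_zero
        arr = arr[keep]
        fill = (row_min[keep] / 5.0)[:, None]
        arr = np.where(arr == 0, fill, arr)
        df = pd.DataFrame(arr, index=df.index[keep], columns=df.columns)
    else:
        raise ValueError(f"unknown impute strategy {strategy!r}")
    return IntensityMatrix(df, dict(matrix.protein_names)), dropped


def sum_normalize(df: pd.DataFrame) -> pd.DataFrame:
    """Divide each sample column by its total so columns sum to 1."""
    totals = df.sum(axis=0)
    zero = totals[totals == 0]
    if not zero.empty:
        raise ValueError(f"sample column {zero.index[0]!r} sums to zero")
    return df / totals


def log10_transform(df: pd.DataFrame) -> pd.DataFrame:
    """Elementwise log10; any value ≤ 0 is a hard error."""
    arr = df.to_numpy()
    bad = arr <= 0
    if bad.any():
        r, c = np.argwhere(bad)[0]
        raise ValueError(
            f"log10 undefined for value {arr[r, c]} at ({df.index[r]}, {df.columns[c]})"
        )
    return pd.DataFrame(np.log10(arr), index=df.index, columns=df.columns)


def autoscale(
    df: pd.DataFrame, drop_constant: bool = True
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Standardize each protein row to mean 0, sample sd 1 (ddof=1).

    Constant rows have undefined scale; they are dropped and reported by
    default, or raise if ``drop_constant`` is False.
    """
    if df.shape[1] < 2:
        raise ValueError("autoscaling requires at least 2 samples")
    mean = df.mean(axis=1)
    sd = df.std(axis=1, ddof=1)
    # exactly-constant rows can yield a tiny nonzero sd from accumulated
    # roundoff; detect constancy on the values themselves
    constant = df.max(axis=1) == df.min(axis=1)
    dropped: dict[str, str] = {}
    if constant.any():
        if not drop_constant:
            raise ValueError(
                f"constant protein {df.index[constant.to_numpy()][0]!r} cannot be autoscaled"
            )
        for acc in df.index[constant]:
            dropped[acc] = "constant across samples (zero variance)"
    out = df.loc[~constant].sub(mean[~constant], axis=0).div(sd[~constant], axis=0)
    return out, dropped


def normalize(
    matrix: IntensityMatrix, config: NormalizationConfig | None = None
) -> NormalizedMatrix:
    """Run the configured preprocessing chain and record provenance."""
    if config is None:
        config = NormalizationConfig()
    mask = matrix.nondetect_mask()
    df = matrix.data.copy()
    provenance: list[str] = []
    dropped: dict[str, str] = {}
    for step in config.steps:
        if step == STEP_IMPUTE:
            m, d = impute_nondetects(IntensityMatrix(df), config.impute_strategy)
            df = m.data
            dropped.update(d)
        elif step == STEP_SUM:
            df = sum_normalize(df)
        elif step == STEP_LOG10:
            df = log10_transform(df)
        elif step == STEP_AUTOSCALE:
            df, d = autoscale(df, config.drop_constant_features)
            dropped.update(d)
        provenance.append(step)
    return NormalizedMatrix(
        data=df,
        nondetect_mask=mask.loc[df.index, df.columns],
        provenance=provenance,
        dropped=dropped,
    )
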