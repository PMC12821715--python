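"""Readers, writers, and the core data model.

The canonical on-disk form of a quantitative proteomics experiment here is a
wide table: one row per protein (UniProt accession), one column per sample,
cells holding raw label-free intensities. A value of exactly 0 (or a blank
cell) encodes "not detected" — the non-detect convention of MaxQuant /
Scaffold exports. Sample metadata (strain, arsenite dose, replicate) lives
in a separate design table; nothing is ever inferred from sample names.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

# Strain vocabulary of the three-strain comparison: the arsRBC deletion
# mutant (no ArsR), its arsR-complemented derivative (constitutive ArsR),
# and wild-type K-12.
STRAIN_AW3110 = "AW3110"
STRAIN_ARSR = "arsR_complement"
STRAIN_K12 = "K12"
STRAINS = (STRAIN_AW3110, STRAIN_ARSR, STRAIN_K12)

# Arsenite doses (µM) permitted per strain. AW3110 and the complement are
# near-isogenic and tolerate only 100 µM, which is their "high" stress;
# K-12 additionally receives 1 mM (= 1000 µM) as its "high" stress.
ALLOWED_DOSES = {
    STRAIN_AW3110: (0, 100),
    STRAIN_ARSR: (0, 100),
    STRAIN_K12: (0, 100, 1000),
}

STRESS_CONTROL = "control"
STRESS_LOW = "low"
STRESS_HIGH = "high"

SIGN_ACTIVATION = "activation"
SIGN_REPRESSION = "repression"
SIGN_DUAL = "dual"
EDGE_SIGNS = (SIGN_ACTIVATION, SIGN_REPRESSION, SIGN_DUAL)

LEVEL_GENE = "gene_level"
LEVEL_TF = "tf_level"
EDGE_LEVELS = (LEVEL_GENE, LEVEL_TF)


def stress_level(strain: str, dose_um: float) -> str:
    """Map (strain, arsenite dose in µM) to a stress level token.

    0 µM is always ``control``. For K-12, 100 µM is ``low`` and 1000 µM is
    ``high``; for AW3110 and the arsR complement, 100 µM is their ``high``.
    """
    if strain not in STRAINS:
        raise ValueError(f"unknown strain {strain!r}; expected one of {STRAINS}")
    dose = float(dose_um)
    if dose not in [float(d) for d in ALLOWED_DOSES[strain]]:
        raise ValueError(
            f"arsenite dose {dose_um} µM is not allowed for strain {strain} "
            f"(allowed: {ALLOWED_DOSES[strain]})"
        )
    if dose == 0:
        return STRESS_CONTROL
    if strain == STRAIN_K12:
        return STRESS_LOW if dose == 100 else STRESS_HIGH
    return STRESS_HIGH


def group_label(strain: str, stress: str) -> str:
    return f"{strain}:{stress}"


# The seven groups of the reference design, in the ArsR-presence gradient
# order used for reporting (lowest ArsR abundance first).
GROUP_AW_C = group_label(STRAIN_AW3110, STRESS_CONTROL)
GROUP_AW_H = group_label(STRAIN_AW3110, STRESS_HIGH)
GROUP_ARSR_C = group_label(STRAIN_ARSR, STRESS_CONTROL)
GROUP_ARSR_H = group_label(STRAIN_ARSR, STRESS_HIGH)
GROUP_K12_C = group_label(STRAIN_K12, STRESS_CONTROL)
GROUP_K12_L = group_label(STRAIN_K12, STRESS_LOW)
GROUP_K12_H = group_label(STRAIN_K12, STRESS_HIGH)

REFERENCE_GROUPS = (
    GROUP_AW_C,
    GROUP_AW_H,
    GROUP_ARSR_C,
    GROUP_ARSR_H,
    GROUP_K12_C,
    GROUP_K12_L,
    GROUP_K12_H,
)

# Observed ArsR abundance gradient across groups (increasing), used to
# order report tables.
ARSR_GRADIENT = (
    GROUP_AW_C,
    GROUP_AW_H,
    GROUP_K12_C,
    GROUP_K12_H,
    GROUP_K12_L,
    GROUP_ARSR_H,
    GROUP_ARSR_C,
)


@dataclass
class IntensityMatrix:
    """Protein × sample raw intensities; exactly 0 encodes non-detection.

    ``data`` is a DataFrame indexed by unique accession with unique sample
    columns; all values are finite and ≥ 0.
    """

    data: pd.DataFrame
    protein_names: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        idx = self.data.index
        if idx.has_duplicates:
            dup = idx[idx.duplicated()][0]
            raise ValueError(f"duplicate accession {dup}")
        cols = self.data.columns
        if cols.has_duplicates:
            dup = cols[cols.duplicated()][0]
            raise ValueError(f"duplicate sample id {dup}")
        values = self.data.to_numpy(dtype=float)
        if not np.all(np.isfinite(values)):
            raise ValueError("intensity matrix contains non-finite values")
        if (values < 0).any():
            r, c = np.argwhere(values < 0)[0]
            raise ValueError(
                f"negative intensity at ({idx[r]}, {cols[c]}): {values[r, c]}"
            )
        self.data = self.data.astype(float)

    @property
    def accessions(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    def nondetect_mask(self) -> pd.DataFrame:
        """Boolean frame, True where the protein was not detected."""
        return self.data == 0.0

    def subset_samples(self, sample_ids: Sequence[str]) -> "IntensityMatrix":
        missing = [s for s in sample_ids if s not in self.data.columns]
        if missing:
            raise KeyError(f"samples not in matrix: {missing}")
        return IntensityMatrix(self.data[list(sample_ids)].copy(), dict(self.protein_names))


@dataclass
class StudyDesign:
    """Per-sample strain / dose / replicate metadata defining the groups.

    ``table`` columns: sample_id, strain, arsenite_dose_uM, replicate, plus
    the derived stress_level and group_label.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"sample_id", "strain", "arsenite_dose_uM", "replicate"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"design table missing columns: {sorted(missing)}")
        t = self.table.copy()
        if t["sample_id"].duplicated().any():
            dup = t.loc[t["sample_id"].duplicated(), "sample_id"].iloc[0]
            raise ValueError(f"duplicate sample_id {dup}")
        reps = t["replicate"].astype(int)
        if (reps < 1).any():
            raise ValueError("replicate indices must be positive integers")
        t["replicate"] = reps
        # stress_level is a pure function of (strain, dose); this also
        # validates strain tokens and strain/dose combinations.
        t["stress_level"] = [
            stress_level(s, d) for s, d in zip(t["strain"], t["arsenite_dose_uM"])
        ]
        t["group_label"] = [
            group_label(s, lv) for s, lv in zip(t["strain"], t["stress_level"])
        ]
        self.table = t.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    @property
    def group_labels(self) -> list[str]:
        """Distinct group labels in first-appearance order."""
        return list(dict.fromkeys(self.table["group_label"]))

    def samples_in_group(self, group: str) -> list[str]:
        sel = self.table.loc[self.table["group_label"] == group, "sample_id"]
        return list(sel)

    def groups(self) -> dict[str, list[str]]:
        return {g: self.samples_in_group(g) for g in self.group_labels}

    def check_matches(self, matrix: IntensityMatrix) -> None:
        """Require every design sample to exist in the intensity matrix."""
        missing = set(self.sample_ids) - set(matrix.sample_ids)
        if missing:
            raise ValueError(f"design samples absent from intensity matrix: {sorted(missing)}")


@dataclass(frozen=True)
class RegulatoryEdge:
    """A signed regulatory relation from a transcription factor to a target.

    ``level`` distinguishes first-level regulation of a screened gene
    (``gene_level``) from second-level regulation of one of its TFs
    (``tf_level``).
    """

    target_gene: str
    regulator: str
    sign: str
    level: str = LEVEL_GENE

    def __post_init__(self) -> None:
        if self.sign not in EDGE_SIGNS:
            raise ValueError(f"unknown sign {self.sign!r}; expected one of {EDGE_SIGNS}")
        if self.level not in EDGE_LEVELS:
            raise ValueError(f"unknown level {self.level!r}; expected one of {EDGE_LEVELS}")


def _delimiter(dialect: str) -> str:
    if dialect == "csv":
        return ","
    if dialect == "tsv":
        return "\t"
    raise ValueError(f"unknown dialect {dialect!r}; expected 'csv' or 'tsv'")


def read_intensity_table(
    path: str | Path,
    dialect: str = "csv",
    accession_column: str | None = None,
    name_column: str | None = None,
) -> IntensityMatrix:
    """Read a wide intensity table (accessions × samples).

    The first column (or ``accession_column``) holds accessions; an optional
    ``name_column`` holds display names; every other column is a sample.
    Blank cells and literal 0 are both stored as 0 = not detected.
    """
    df = pd.read_csv(path, sep=_delimiter(dialect), dtype=str)
    if df.shape[1] < 2:
        raise ValueError("intensity table needs an accession column and ≥1 sample column")
    acc_col = accession_column if accession_column is not None else df.columns[0]
    if acc_col not in df.columns:
        raise ValueError(f"accession column {acc_col!r} not found")
    accessions = df[acc_col].astype(str)
    dup = accessions[accessions.duplicated()]
    if not dup.empty:
        raise ValueError(f"duplicate accession {dup.iloc[0]}")

    names: dict[str, str] = {}
    drop_cols = [acc_col]
    if name_column is not None:
        if name_column not in df.columns:
            raise ValueError(f"name column {name_column!r} not found")
        names = dict(zip(accessions, df[name_column].fillna("")))
        drop_cols.append(name_column)

    body = df.drop(columns=drop_cols)
    body.index = pd.Index(accessions, name="accession")
    # blank ≡ 0 ≡ non-detected
    body = body.replace(r"^\s*$", np.nan, regex=True)
    try:
        numeric = body.astype(float)
    except ValueError as exc:
        raise ValueError(f"non-numeric intensity cell: {exc}") from exc
    numeric = numeric.fillna(0.0)
    return IntensityMatrix(numeric, names)


def write_intensity_table(
    matrix: IntensityMatrix, path: str | Path, dialect: str = "csv"
) -> None:
    out = matrix.data.copy()
    out.index.name = "accession"
    out.to_csv(path, sep=_delimiter(dialect))


def read_design(path: str | Path, dialect: str = "csv") -> StudyDesign:
    """Read a sample design table (sample_id, strain, arsenite_dose_uM, replicate)."""
    df = pd.read_csv(path, sep=_delimiter(dialect))
    return StudyDesign(df)


def write_design(design: StudyDesign, path: str | Path, dialect: str = "csv") -> None:
    design.table.to_csv(path, sep=_delimiter(dialect), index=False)


def read_edge_table(path: str | Path, dialect: str = "csv") -> list[RegulatoryEdge]:
    """Read a signed TF→gene edge table; exact duplicate rows are dropped."""
    df = pd.read_csv(path, sep=_delimiter(dialect), dtype=str)
    required = {"target_gene", "regulator", "sign", "level"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"edge table missing columns: {sorted(missing)}")
    edges: list[RegulatoryEdge] = []
    seen: set[tuple[str, str, str, str]] = set()
    for row in df.itertuples(index=False):
        key = (str(row.target_gene), str(row.regulator), str(row.sign), str(row.level))
        if key in seen:
            continue
        seen.add(key)
        edges.append(RegulatoryEdge(*key))
    return edges


def write_edge_table(
    edges: Iterable[RegulatoryEdge], path: str | Path, dialect: str = "csv"
) -> None:
    df = pd.DataFrame(
        [(e.target_gene, e.regulator, e.sign, e.level) for e in edges],
        columns=["target_gene", "regulator", "sign", "level"],
    )
    df.to_csv(path, sep=_delimiter(dialect), index=False)


def reference_design(n_replicates: int = 3) -> StudyDesign:
    """The study's 7-group × n-replicate design (21 samples by default)."""
    rows = []
    specs = [
        (STRAIN_AW3110, 0),
        (STRAIN_AW3110, 100),
        (STRAIN_ARSR, 0),
        (STRAIN_ARSR, 100),
        (STRAIN_K12, 0),
        (STRAIN_K12, 100),
        (STRAIN_K12, 1000),
    ]
    for strain, dose in specs:
        lv = stress_level(strain, dose)
        for rep in range(1, n_replicates + 1):
            rows.append(
                {
                    "sample_id": f"{strain}_{lv}_r{rep}",
                    "strain": strain,
                    "arsenite_dose_uM": dose,
                    "replicate": rep,
                }
            )
    return StudyDesign(pd.DataFrame(rows))
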