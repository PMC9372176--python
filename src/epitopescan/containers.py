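"""In-memory containers shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .library import PeptideLibrary

GROUPS = ("healthy", "MN", "FSGS_idiopathic", "FSGS_genetic", "IgAGN")
OUTCOMES = ("complete_remission", "partial_remission", "persistence", "NA")

METADATA_COLUMNS = (
    "sample_id",
    "group",
    "anti_pla2r1",
    "proteinuria_T0",
    "proteinuria_T12",
    "proteinuria_T24",
    "outcome",
)


@dataclass
class IntensityMatrix:
    """Peptides x samples fluorescence matrix (arbitrary units, >= 0)."""

    values: np.ndarray
    peptide_ids: list[str]
    sample_ids: list[str]
    library: PeptideLibrary | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D peptides x samples matrix")
        if self.values.shape != (len(self.peptide_ids), len(self.sample_ids)):
            raise ValueError(
                f"shape {self.values.shape} does not match "
                f"{len(self.peptide_ids)} peptides x {len(self.sample_ids)} samples"
            )
        if np.isnan(self.values).any():
            raise ValueError("intensity matrix contains missing values")
        if (self.values < 0).any():
            i, j = np.argwhere(self.values < 0)[0]
            raise ValueError(
                f"negative intensity at peptide {self.peptide_ids[i]!r}, "
                f"sample {self.sample_ids[j]!r}"
            )
        if self.library is not None and self.library.peptide_ids != self.peptide_ids:
            raise ValueError("peptide index not aligned to the library")

    @property
    def n_peptides(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def column(self, sample_id: str) -> np.ndarray:
        return self.values[:, self.sample_ids.index(sample_id)]


@dataclass
class SampleMetadata:
    """Per-sample clinical annotations.

    ``group`` is one of healthy / MN / FSGS_idiopathic / FSGS_genetic / IgAGN.
    Proteinuria is in g/d at enrolment (T0) and at 12/24-month follow-up.
    Outcome classes follow the usual proteinuria bands: complete remission
    < 0.3 g/d, persistence > 3.5 g/d, partial remission in between.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in METADATA_COLUMNS if c not in self.df.columns]
        if missing:
            raise ValueError(f"metadata missing columns: {missing}")
        self.df = self.df.reset_index(drop=True)
        bad = set(self.df["group"]) - set(GROUPS)
        if bad:
            raise ValueError(f"unknown group labels: {sorted(bad)}")
        # outcome must agree with 12-month proteinuria when both are present
        for _, row in self.df.iterrows():
            out, p12 = row["outcome"], row["proteinuria_T12"]
            if pd.isna(p12) or out in (None, "NA") or pd.isna(out):
                continue
            if out == "complete_remission" and not p12 < 0.3:
                raise ValueError(
                    f"sample {row['sample_id']}: complete_remission requires "
                    f"proteinuria_T12 < 0.3 g/d, got {p12}"
                )
            if out == "persistence" and not p12 > 3.5:
                raise ValueError(
                    f"sample {row['sample_id']}: persistence requires "
                    f"proteinuria_T12 > 3.5 g/d, got {p12}"
                )

    @property
    def sample_ids(self) -> list[str]:
        return self.df["sample_id"].tolist()

    def ids_in_group(self, *groups: str) -> list[str]:
        return self.df.loc[self.df["group"].isin(groups), "sample_id"].tolist()

    @property
    def case_ids(self) -> list[str]:
        """Disease samples (any non-healthy group)."""
        return self.df.loc[self.df["group"] != "healthy", "sample_id"].tolist()

    @property
    def control_ids(self) -> list[str]:
        return self.ids_in_group("healthy")


@dataclass
class PlantedRun:
    """Ground truth for one synthetic epitope: a run of ``length``
    tiling-adjacent peptides starting at library row ``start_index``,
    multiplied by ``effect`` in the listed case samples."""

    protein_id: str
    start_index: int
    length: int
    sample_ids: list[str]
    effect: float

    def __post_init__(self) -> None:
        if self.length < 2:
            raise ValueError("a planted run spans at least 2 adjacent peptides")
        if not self.effect > 1:
            raise ValueError("effect size must exceed 1")

    @property
    def peptide_rows(self) -> np.ndarray:
        return np.arange(self.start_index, self.start_index + self.length)


@dataclass
class EpitopeTruth:
    """All planted epitopes of one simulated array."""

    runs: list[PlantedRun] = field(default_factory=list)

    def peptide_rows(self) -> np.ndarray:
        if not self.runs:
            return np.zeros(0, dtype=int)
        return np.unique(np.concatenate([r.peptide_rows for r in self.runs]))
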