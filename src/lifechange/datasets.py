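"""Survey dataset container: one row per participant per timepoint."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .codebook import ItemCodebook

ID_COL = "participant_id"
TIME_COL = "timepoint"


@dataclass
class SurveyDataset:
    """Long-format survey table.

    ``data`` has one row per (participant, timepoint) with item-response
    columns (ordinal, stored as float so missing values are representable)
    plus covariate columns (country, state, demographics, ...).

    ``timepoints`` preserves wave order (e.g. april < may < november), which
    the frame itself cannot express.
    """

    data: pd.DataFrame
    timepoints: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        for col in (ID_COL, TIME_COL):
            if col not in self.data.columns:
                raise ValueError(f"dataset is missing required column {col!r}")
        if not self.timepoints:
            self.timepoints = list(pd.unique(self.data[TIME_COL]))
        unknown = set(self.data[TIME_COL]) - set(self.timepoints)
        if unknown:
            raise ValueError(f"rows reference unknown timepoints: {sorted(unknown)}")

    @property
    def participants(self) -> pd.Index:
        return pd.Index(sorted(self.data[ID_COL].unique()), name=ID_COL)

    @property
    def n_participants(self) -> int:
        return self.data[ID_COL].nunique()

    def wave(self, timepoint: str) -> pd.DataFrame:
        """Rows of one wave, indexed by participant id."""
        if timepoint not in self.timepoints:
            raise KeyError(f"unknown timepoint {timepoint!r}")
        sub = self.data[self.data[TIME_COL] == timepoint]
        return sub.set_index(ID_COL).sort_index()

    def item_matrix(
        self, timepoint: str, items: list[str], complete_only: bool = False
    ) -> pd.DataFrame:
        """Participant x item matrix for one wave.

        With ``complete_only`` participants missing any of the requested
        items are dropped (model-wise deletion for the calling analysis).
        """
        mat = self.wave(timepoint)[items]
        if complete_only:
            mat = mat.dropna(axis=0, how="any")
        return mat

    def item_columns(self, codebook: ItemCodebook) -> list[str]:
        return [c for c in self.data.columns if c in codebook]

    def copy(self) -> "SurveyDataset":
        return SurveyDataset(self.data.copy(), list(self.timepoints))

    # ---------------------------------------------------------------- I/O

    def to_csv(self, path: str | Path) -> None:
        self.data.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path, timepoints: list[str] | None = None) -> "SurveyDataset":
        data = pd.read_csv(path)
        return cls(data, timepoints or [])
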