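"""qHTS activity scores and binary teacher labels.

Quantitative high-throughput screening (qHTS) assays summarise each
compound x assay pair by a normalized activity score in [0, 100]
(0 = inactive, 40-100 = active, 5-30 = inconclusive).  This module
parses score tables (SID rows x AID columns), normalizes raw plate
signals onto that scale, converts scores to binary active/inactive
teacher labels under the two screening criteria (threshold 40 or 1),
and loads the packaged registry of the 59 modelled assay targets
(molecular initiating events, MIEs).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "RawPlateMeasurement",
    "NormalizedScore",
    "LabelCriterion",
    "CRITERIA",
    "BinaryLabelTable",
    "TargetRegistry",
    "InvalidPlateControlsError",
    "CorruptRegistryError",
    "DuplicateIDError",
    "normalize_raw_activity",
    "read_score_table",
    "validate_score_table",
    "binarize_scores",
    "labels_for_target",
    "load_target_registry",
]

#: The two label criteria: active iff score >= threshold.
CRITERIA = (40, 1)

#: Number of assay targets in the packaged registry.
N_TARGETS = 59


class InvalidPlateControlsError(ValueError):
    """Positive-control and vehicle-control medians coincide."""


class CorruptRegistryError(ValueError):
    """Registry file has the wrong entry count or duplicate AIDs."""


class DuplicateIDError(ValueError):
    """A score table contains duplicate SIDs or AIDs."""


@dataclass(frozen=True)
class RawPlateMeasurement:
    """A single compound well with its plate controls.

    Parameters
    ----------
    v_compound : float
        Signal of the compound well, in arbitrary assay units.
    v_dmso : float
        Median signal of the DMSO (vehicle) control wells.
    v_pos : float
        Median signal of the positive-control wells.
    """

    v_compound: float
    v_dmso: float
    v_pos: float


@dataclass(frozen=True)
class NormalizedScore:
    """Normalized activity with the raw (unclamped) value preserved."""

    raw: float
    score: float
    clamped: bool


@dataclass(frozen=True)
class LabelCriterion:
    """Binarization rule: active iff score >= threshold (40 or 1)."""

    threshold: int

    def __post_init__(self) -> None:
        if self.threshold not in CRITERIA:
            raise ValueError(
                f"criterion threshold must be one of {CRITERIA}, got {self.threshold}"
            )


@dataclass
class BinaryLabelTable:
    """Active/inactive labels for a score table under one criterion.

    ``labels`` has the same shape as the score table: 1.0 = active,
    0.0 = inactive, NaN = no score (compound untested in that assay).
    """

    labels: pd.DataFrame
    criterion: LabelCriterion


def normalize_raw_activity(m: RawPlateMeasurement) -> NormalizedScore:
    """Normalize a raw plate signal onto the 0-100 activity scale.

    activity = (v_compound - v_dmso) / (v_pos - v_dmso) * 100.

    Values falling outside [0, 100] (compound beyond the controls) are
    clamped, with a warning; the unclamped value is kept in ``raw``.
    """
    denom = m.v_pos - m.v_dmso
    if denom == 0:
        raise InvalidPlateControlsError(
            "positive control equals vehicle control; score undefined"
        )
    raw = (m.v_compound - m.v_dmso) / denom * 100.0
    score = min(max(raw, 0.0), 100.0)
    clamped = score != raw
    if clamped:
        warnings.warn(
            f"normalized activity {raw:.3f} outside [0, 100]; clamped",
            stacklevel=2,
        )
    return NormalizedScore(raw=raw, score=score, clamped=clamped)


def validate_score_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check score-table invariants: unique IDs, scores in [0, 100] or NaN."""
    if table.index.has_duplicates:
        dups = table.index[table.index.duplicated()].unique().tolist()
        raise DuplicateIDError(f"duplicate SIDs in score table: {dups[:5]}")
    if table.columns.has_duplicates:
        dups = table.columns[table.columns.duplicated()].unique().tolist()
        raise DuplicateIDError(f"duplicate AIDs in score table: {dups[:5]}")
    values = table.to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        bad = (values < 0) | (values > 100)
    if np.any(bad):
        raise ValueError("score table contains values outside [0, 100]")
    return table


def read_score_table(path: str | Path) -> pd.DataFrame:
    """Read a SID x AID activity-score CSV.

    The header row holds AIDs, the first column SIDs; empty cells are
    missing scores. Duplicated SIDs are an error: the upstream source
    does not document a resolution rule, so conflicts must be resolved
    by the caller rather than silently merged.
    """
    table = pd.read_csv(path, index_col=0)
    table.index.name = "SID"
    return validate_score_table(table.astype(float))


def binarize_scores(
    table: pd.DataFrame, criterion: LabelCriterion | int
) -> BinaryLabelTable:
    """Convert activity scores to binary labels under one criterion.

    score >= threshold -> active (1.0); score < threshold -> inactive
    (0.0); missing stays missing (NaN).  Under the criterion of 40 the
    inconclusive band (5-30) is inactive; under the criterion of 1 it
    is active — exactly the threshold rule, no special casing.
    """
    if isinstance(criterion, int):
        criterion = LabelCriterion(criterion)
    validate_score_table(table)
    values = table.to_numpy(dtype=float)
    labels = np.where(np.isnan(values), np.nan, (values >= criterion.threshold))
    frame = pd.DataFrame(labels, index=table.index, columns=table.columns, dtype=float)
    return BinaryLabelTable(labels=frame, criterion=criterion)


def labels_for_target(table: BinaryLabelTable, aid: int | str) -> pd.Series:
    """Labels for one assay, with unscored compounds dropped.

    Compounds with no score for this AID are excluded from modelling of
    this target only; their scores in other assays are unaffected.
    """
    col = table.labels[_match_column(table.labels, aid)]
    return col.dropna().astype(int)


def _match_column(frame: pd.DataFrame, aid: int | str):
    if aid in frame.columns:
        return aid
    # CSV round-trips may stringify integer AIDs
    alt = str(aid)
    if alt in frame.columns:
        return alt
    raise KeyError(f"AID {aid!r} not in score table")


@dataclass
class TargetRegistry:
    """The 59 modelled assay targets: AID, MIE name, activity type, abbreviation."""

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"aid", "mie_name", "activity_type", "abbreviation"}
        missing = required - set(self.frame.columns)
        if missing:
            raise CorruptRegistryError(f"registry missing columns: {sorted(missing)}")
        if len(self.frame) != N_TARGETS:
            raise CorruptRegistryError(
                f"registry must have exactly {N_TARGETS} entries, got {len(self.frame)}"
            )
        if self.frame["aid"].duplicated().any():
            raise CorruptRegistryError("registry contains duplicate AIDs")

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def aids(self) -> list[int]:
        return [int(a) for a in self.frame["aid"]]

    def by_aid(self, aid: int) -> pd.Series:
        hit = self.frame[self.frame["aid"] == int(aid)]
        if hit.empty:
            raise KeyError(f"AID {aid} not in registry")
        return hit.iloc[0]

    def by_abbreviation(self, abbreviation: str) -> pd.Series:
        hit = self.frame[self.frame["abbreviation"] == abbreviation]
        if hit.empty:
            raise KeyError(f"abbreviation {abbreviation!r} not in registry")
        return hit.iloc[0]


def load_target_registry(path: str | Path | None = None) -> TargetRegistry:
    """Load the target registry (packaged CSV by default)."""
    if path is None:
        source = resources.files("mietox.data").joinpath("target_registry.csv")
        with resources.as_file(source) as p:
            frame = pd.read_csv(p)
    else:
        frame = pd.read_csv(path)
    return TargetRegistry(frame=frame)
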