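"""Battery data model, score orientation, contrast scores and tabular I/O.

A neurocognitive test battery is declared as a :class:`BatterySpec`: an
ordered set of variables, each tagged with the task it comes from, its
sensory modality, its score direction (is a larger number better or worse?)
and whether normative data exist for it.  Trial data are held in a
:class:`TrialDataset` — one row per participant per timepoint, one column
per variable — which is the currency every downstream stage consumes.

Two transformations live here because every analysis depends on them:

* ``orient_scores`` flips ``lower_better`` variables (reaction times,
  error counts) so that a larger value always means better performance.
* ``compute_contrasts`` appends difference scores that isolate a specific
  function (e.g. the reaction-time cost of inhibiting a prepotent
  response), defined as minuend − subtrahend on oriented scores.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Optional, Union

import numpy as np
import pandas as pd
from pydantic import BaseModel, field_validator, model_validator

TIMEPOINTS = ("baseline", "d91")
DEMOGRAPHIC_COLUMNS = ("id", "timepoint", "arm", "sex", "age", "iq")
ARMS = ("placebo", "active")
SEXES = ("M", "F")


class Modality(str, Enum):
    auditory = "auditory"
    visual = "visual"
    motor = "motor"


class Direction(str, Enum):
    higher_better = "higher_better"
    lower_better = "lower_better"


class VariableKind(str, Enum):
    raw = "raw"
    contrast = "contrast"
    domain = "domain"


class VariableDef(BaseModel):
    """One measured (or derived) variable of the battery."""

    name: str
    task: str
    modality: Modality
    direction: Direction
    has_norms: bool = False
    kind: VariableKind = VariableKind.raw

    @field_validator("name", "task")
    @classmethod
    def _identifier(cls, v: str) -> str:
        if not v or not v.replace("_", "a").replace("-", "a").isalnum():
            raise ValueError(f"not a valid identifier: {v!r}")
        return v


class ContrastDef(BaseModel):
    """A difference of two oriented raw scores: minuend − subtrahend."""

    name: str
    minuend: str
    subtrahend: str

    @model_validator(mode="after")
    def _distinct(self) -> "ContrastDef":
        if self.minuend == self.subtrahend:
            raise ValueError(f"contrast {self.name!r} subtracts a variable from itself")
        return self


class BatterySpec(BaseModel):
    """Ordered declaration of every variable in the battery plus contrasts."""

    variables: list[VariableDef]
    contrasts: list[ContrastDef] = []

    @model_validator(mode="after")
    def _validate(self) -> "BatterySpec":
        names = [v.name for v in self.variables]
        if len(names) != len(set(names)):
            raise ValueError("variable names must be unique within a battery")
        if len(self.variables) < 2:
            raise ValueError("a battery needs at least 2 variables")
        raw = {v.name for v in self.variables if v.kind == VariableKind.raw}
        for c in self.contrasts:
            missing = {c.minuend, c.subtrahend} - raw
            if missing:
                raise ValueError(
                    f"contrast {c.name!r} references unknown raw variables: {sorted(missing)}"
                )
            if c.name in names:
                raise ValueError(f"contrast name {c.name!r} collides with a variable")
        return self

    # -- convenience views -------------------------------------------------
    @property
    def raw_names(self) -> list[str]:
        return [v.name for v in self.variables if v.kind == VariableKind.raw]

    @property
    def contrast_names(self) -> list[str]:
        return [c.name for c in self.contrasts]

    @property
    def all_names(self) -> list[str]:
        return self.raw_names + self.contrast_names

    @property
    def norm_names(self) -> list[str]:
        return [v.name for v in self.variables if v.has_norms and v.kind == VariableKind.raw]

    def variable(self, name: str) -> VariableDef:
        for v in self.variables:
            if v.name == name:
                return v
        raise KeyError(name)

    def to_json(self, path: Union[str, Path]) -> None:
        Path(path).write_text(self.model_dump_json(indent=2))

    @classmethod
    def from_json(cls, path: Union[str, Path]) -> "BatterySpec":
        return cls.model_validate(json.loads(Path(path).read_text()))


@dataclass
class TrialDataset:
    """Per-participant, per-timepoint scores plus demographics.

    ``demographics`` is indexed by participant id with columns
    ``arm, sex, age, iq``; ``scores`` is indexed by (id, timepoint) with one
    column per variable.  Missing cells stay missing — no imputation
    anywhere in the package.
    """

    demographics: pd.DataFrame
    scores: pd.DataFrame
    oriented: bool = False
    has_contrasts: bool = False

    def __post_init__(self) -> None:
        if self.scores.index.duplicated().any():
            raise ValueError("duplicate (id, timepoint) rows")
        bad = set(self.scores.index.get_level_values("timepoint")) - set(TIMEPOINTS)
        if bad:
            raise ValueError(f"unknown timepoint labels: {sorted(bad)}")

    @property
    def n_participants(self) -> int:
        return len(self.demographics)

    @property
    def variables(self) -> list[str]:
        return list(self.scores.columns)

    def timepoint(self, label: str) -> pd.DataFrame:
        """Score table for one timepoint, indexed by participant id."""
        sub = self.scores.xs(label, level="timepoint")
        return sub.reindex(self.demographics.index)

    def copy(self) -> "TrialDataset":
        return replace(self, demographics=self.demographics.copy(), scores=self.scores.copy())

    def to_frame(self) -> pd.DataFrame:
        """Flat wide table: one row per (id, timepoint), demographics repeated."""
        flat = self.scores.reset_index()
        demo = self.demographics.reset_index().rename(columns={"index": "id"})
        out = flat.merge(demo, on="id", how="left")
        cols = list(DEMOGRAPHIC_COLUMNS) + [c for c in self.scores.columns]
        return out[cols]


def _validate_demographics(demo: pd.DataFrame) -> pd.DataFrame:
    if not demo["arm"].isin(ARMS).all():
        raise ValueError(f"arm must be one of {ARMS}")
    if not demo["sex"].isin(SEXES).all():
        raise ValueError(f"sex must be one of {SEXES}")
    return demo


def from_frame(
    frame: pd.DataFrame,
    spec: BatterySpec,
    oriented: bool = False,
    has_contrasts: bool = False,
) -> TrialDataset:
    """Build a validated :class:`TrialDataset` from a flat wide table."""
    missing = [c for c in DEMOGRAPHIC_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"missing required demographic columns: {missing}")
    if len(frame) == 0:
        raise ValueError("no participants in table")

    expected = spec.all_names if has_contrasts else spec.raw_names
    known = [c for c in frame.columns if c in expected]
    unknown = [
        c for c in frame.columns if c not in expected and c not in DEMOGRAPHIC_COLUMNS
    ]
    if unknown:
        warnings.warn(f"ignoring columns not in battery spec: {unknown}")
    absent = [c for c in expected if c not in frame.columns]
    if absent:
        raise ValueError(f"battery variables absent from table: {absent}")

    demo = frame[list(DEMOGRAPHIC_COLUMNS)].drop_duplicates()
    if demo["id"].duplicated().any():
        # demographics must be constant within participant across timepoints
        per_id = frame.groupby("id")[["arm", "sex", "age", "iq"]].nunique()
        varying = per_id[(per_id > 1).any(axis=1)].index.tolist()
        if varying:
            raise ValueError(f"arm/sex/age/iq vary within participant(s): {varying}")
    demo = (
        frame[["id", "arm", "sex", "age", "iq"]]
        .drop_duplicates("id")
        .set_index("id")
        .sort_index()
    )
    _validate_demographics(demo)

    scores = frame.set_index(["id", "timepoint"])[known].astype(float)
    if scores.index.duplicated().any():
        dupes = scores.index[scores.index.duplicated()].tolist()
        raise ValueError(f"duplicate (id, timepoint) rows: {dupes[:5]}")
    scores = scores.sort_index()
    return TrialDataset(demo, scores, oriented=oriented, has_contrasts=has_contrasts)


def load_trial(path: Union[str, Path], spec: BatterySpec) -> TrialDataset:
    """Read a trial CSV (wide by variable, long by timepoint) and validate it."""
    frame = pd.read_csv(path)
    return from_frame(frame, spec)


def write_trial(data: TrialDataset, path: Union[str, Path]) -> None:
    data.to_frame().to_csv(path, index=False)


def orient_scores(data: TrialDataset, spec: BatterySpec) -> TrialDataset:
    """Flip ``lower_better`` variables so larger always means better.

    Guarded: applying orientation to an already-oriented dataset raises,
    because the sign flip is an involution and silent re-application would
    corrupt every downstream score.
    """
    if data.oriented:
        raise ValueError("dataset already oriented; refusing to orient twice")
    out = data.copy()
    for v in spec.variables:
        if v.kind != VariableKind.raw or v.name not in out.scores.columns:
            continue
        if v.direction == Direction.lower_better:
            out.scores[v.name] = -out.scores[v.name]
    out.oriented = True
    return out


def compute_contrasts(data: TrialDataset, spec: BatterySpec) -> TrialDataset:
    """Append contrast columns (minuend − subtrahend of oriented scores).

    A contrast is missing wherever either operand is missing.
    """
    if not data.oriented:
        raise ValueError("orient scores before computing contrasts")
    out = data.copy()
    for c in spec.contrasts:
        out.scores[c.name] = out.scores[c.minuend] - out.scores[c.subtrahend]
    out.has_contrasts = True
    return out


def default_battery() -> BatterySpec:
    """The package's default battery, modelled on a paediatric ANT/Wechsler/Rey
    test set: baseline speed, go/no-go, auditory and visual attentional
    shifting, digit and spatial span, and verbal/visual list learning.
    """
    V = VariableDef
    variables = [
        V(name="bs_rt", task="BS", modality=Modality.motor, direction=Direction.lower_better, has_norms=True),
        V(name="bs_sd", task="BS", modality=Modality.motor, direction=Direction.lower_better, has_norms=True),
        V(name="gng_rt", task="GNG", modality=Modality.visual, direction=Direction.lower_better, has_norms=True),
        V(name="gng_false_alarms", task="GNG", modality=Modality.visual, direction=Direction.lower_better, has_norms=True),
        V(name="ssv1_rt", task="SSV", modality=Modality.visual, direction=Direction.lower_better, has_norms=True),
        V(name="ssv2_rt", task="SSV", modality=Modality.visual, direction=Direction.lower_better, has_norms=True),
        V(name="ssv1_errors", task="SSV", modality=Modality.visual, direction=Direction.lower_better, has_norms=False),
        V(name="ssv2_errors", task="SSV", modality=Modality.visual, direction=Direction.lower_better, has_norms=False),
        V(name="ssa1_rt", task="SSA", modality=Modality.auditory, direction=Direction.lower_better, has_norms=True),
        V(name="ssa2_rt", task="SSA", modality=Modality.auditory, direction=Direction.lower_better, has_norms=True),
        V(name="ssa1_errors", task="SSA", modality=Modality.auditory, direction=Direction.lower_better, has_norms=False),
        V(name="ssa2_errors", task="SSA", modality=Modality.auditory, direction=Direction.lower_better, has_norms=True),
        V(name="wisc_ds", task="WISC-DS", modality=Modality.auditory, direction=Direction.higher_better, has_norms=True),
        V(name="wnv_ss", task="WNV-SS", modality=Modality.visual, direction=Direction.higher_better, has_norms=True),
        V(name="ravlt_imprinting", task="RAVLT", modality=Modality.auditory, direction=Direction.higher_better, has_norms=True),
        V(name="ravlt_recall", task="RAVLT", modality=Modality.auditory, direction=Direction.higher_better, has_norms=True),
        V(name="rvdlt_imprinting", task="RVDLT", modality=Modality.visual, direction=Direction.higher_better, has_norms=True),
        V(name="rvdlt_recall", task="RVDLT", modality=Modality.visual, direction=Direction.higher_better, has_norms=True),
    ]
    contrasts = [
        # relative slowing under response-selection load vs plain motor speed
        ContrastDef(name="gng_biased_rt", minuend="gng_rt", subtrahend="bs_rt"),
        # set-shifting cost within each modality (part 2 − part 1, oriented)
        ContrastDef(name="ssv_shift_cost", minuend="ssv2_rt", subtrahend="ssv1_rt"),
        ContrastDef(name="ssa_shift_cost", minuend="ssa2_rt", subtrahend="ssa1_rt"),
    ]
    return BatterySpec(variables=variables, contrasts=contrasts)
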