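"""Disease severity hierarchy (DSH) trees, patient states, and risk scores.

A DSH tree is a complete binary tree over clinically ordered patient states.
The root encodes disease presence; each subsequent level refines severity
(requiring therapy, therapy line, dose escalation, control status), and every
right branch denotes intensification.  Scores follow the branch-doubling
rule: the root scores 1 with disease and 0 without; a right child doubles its
parent's score and a left child keeps it, so a tree with ``n`` levels tops
out at ``2**(n-1)``.

A patient's score at a time point is the score of the deepest node matching
their :class:`PatientState`, re-derived at every encounter to give a
time-varying score trajectory across the baseline window.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Mapping, Optional

from .ehr_data import (
    ConditionDefinition,
    ConfigurationError,
    PatientTimeline,
    WindowError,
    condition_indication,
)

logger = logging.getLogger(__name__)

THERAPY_LINE_ORDER = {"none": 0, "first": 1, "second": 2, "last": 3}


@dataclass
class DSHNode:
    level: int
    label: str
    score: Optional[float] = None
    left: Optional["DSHNode"] = None
    right: Optional["DSHNode"] = None

    def walk(self):
        yield self
        if self.left is not None:
            yield from self.left.walk()
        if self.right is not None:
            yield from self.right.walk()


@dataclass
class DSHTree:
    condition_name: str
    root: DSHNode
    n_levels: int
    # ordered semantics of the branch decision leading from level k to k+1;
    # right = the more severe alternative
    deciders: tuple[str, ...] = ()

    def max_score(self) -> float:
        return max(n.score for n in self.root.walk())

    def to_text(self) -> str:
        lines: list[str] = []

        def rec(node: DSHNode, prefix: str, tag: str) -> None:
            lines.append(f"{prefix}{tag}{node.label} [score {node.score:g}]")
            child_prefix = prefix + "    "
            if node.left is not None:
                rec(node.left, child_prefix, "L: ")
            if node.right is not None:
                rec(node.right, child_prefix, "R: ")

        rec(self.root, "", "")
        return "\n".join(lines)


@dataclass(frozen=True)
class PatientState:
    """Snapshot of one condition for one patient at one age."""

    condition_name: str
    at_age: float
    present: int
    treated: int
    therapy_line: str  # none | first | second | last
    dose_change: str  # increase | decrease | none
    controlled: Optional[int]  # 1 controlled, 0 uncontrolled, None unknown
    band: Optional[int] = None  # measurement band for band-graded conditions

    def __post_init__(self) -> None:
        if self.treated and not self.present:
            raise ValueError("treated implies present")
        if (self.therapy_line != "none") != bool(self.treated):
            raise ValueError("therapy_line must be 'none' exactly when untreated")


@dataclass
class ScoreTrajectory:
    condition_name: str
    samples: list[tuple[float, float]] = field(default_factory=list)

    @property
    def ages(self) -> list[float]:
        return [a for a, _ in self.samples]

    @property
    def scores(self) -> list[float]:
        return [s for _, s in self.samples]


# Branch-decision vocabulary.  Each decider maps a PatientState to True when
# the patient takes the right (intensifying) branch at that level.
def _d_treated(s: PatientState) -> bool:
    return bool(s.treated)


def _d_second_line(s: PatientState) -> bool:
    return THERAPY_LINE_ORDER[s.therapy_line] >= THERAPY_LINE_ORDER["second"]


def _d_last_line(s: PatientState) -> bool:
    return s.therapy_line == "last"


def _d_dose_increase(s: PatientState) -> bool:
    return s.dose_change == "increase"


def _d_uncontrolled(s: PatientState) -> bool:
    # unknown control status maps left (not assumed uncontrolled); flagged
    if s.controlled is None:
        logger.debug("control status unknown for %s at %.2f; mapping left",
                     s.condition_name, s.at_age)
        return False
    return s.controlled == 0


_DECIDER_FUNCS: dict[str, Callable[[PatientState], bool]] = {
    "treated": _d_treated,
    "second_line": _d_second_line,
    "last_line": _d_last_line,
    "dose_increase": _d_dose_increase,
    "uncontrolled": _d_uncontrolled,
}

# Default decision ladders by depth (after the presence root), truncations of
# presence -> treated -> line -> dose -> control.
_THERAPY_LADDERS: dict[int, tuple[str, ...]] = {
    2: ("treated",),
    3: ("treated", "second_line"),
    4: ("treated", "second_line", "uncontrolled"),
    5: ("treated", "second_line", "dose_increase", "uncontrolled"),
    6: ("treated", "second_line", "last_line", "dose_increase", "uncontrolled"),
}

_DECIDER_LABELS = {
    "treated": ("untreated", "requires therapy"),
    "second_line": ("first-line therapy", "second-line or beyond"),
    "last_line": ("below last-line", "last-line therapy"),
    "dose_increase": ("dose steady/decrease", "dose increase"),
    "uncontrolled": ("controlled", "uncontrolled"),
}


def _band_deciders(condition_def: ConditionDefinition, n_levels: int) -> tuple[str, ...]:
    # band conditions (e.g. obesity): right branches are successive measurement
    # bands, with the final level an increasing trend ("uncontrolled")
    names = [f"band:{k + 1}" for k in range(len(condition_def.band_thresholds))]
    ladder = tuple(names[: n_levels - 2]) + ("uncontrolled",)
    if len(ladder) < n_levels - 1:
        raise ConfigurationError(
            f"condition {condition_def.name!r}: not enough band thresholds for "
            f"{n_levels} levels"
        )
    return ladder


def build_tree(
    condition_def: ConditionDefinition,
    n_levels: int = 4,
    root_score: float = 1.0,
) -> DSHTree:
    """Build the complete severity tree for a condition and assign scores."""
    if not 2 <= n_levels <= 6:
        raise ConfigurationError(f"n_levels must be in 2..6, got {n_levels}")
    if condition_def.severity_mode == "bands":
        deciders = _band_deciders(condition_def, n_levels)
    else:
        deciders = _THERAPY_LADDERS[n_levels]

    def make(level: int, label: str) -> DSHNode:
        node = DSHNode(level=level, label=label)
        if level < n_levels:
            decider = deciders[level - 1]
            left_label, right_label = _DECIDER_LABELS.get(
                decider, (f"below {decider}", decider)
            )
            node.left = make(level + 1, left_label)
            node.right = make(level + 1, right_label)
        return node

    root = make(1, f"{condition_def.name} present")
    tree = DSHTree(condition_name=condition_def.name, root=root,
                   n_levels=n_levels, deciders=deciders)
    return assign_scores(tree, root_score)


def assign_scores(tree: DSHTree, root_score: float = 1.0) -> DSHTree:
    """Assign branch-doubling scores: left keeps, right doubles the parent."""
    if root_score not in (0, 1):
        raise ConfigurationError(f"root_score must be 0 or 1, got {root_score}")

    def rec(node: DSHNode, score: float) -> None:
        node.score = score
        if node.left is not None:
            rec(node.left, score)
        if node.right is not None:
            rec(node.right, 2 * score)

    rec(tree.root, float(root_score))
    return tree


def _band_level(values: list[float], thresholds: tuple[float, ...]) -> int:
    if not values:
        return 0
    latest = values[-1]
    return sum(latest >= t for t in thresholds)


def classify_state(
    timeline: PatientTimeline,
    condition_def: ConditionDefinition,
    at_age: float,
    btw: tuple[float, float],
    measurement_units: Mapping[str, str] | None = None,
) -> PatientState:
    """Classify one patient's state for one condition at a time point.

    Presence is sticky: once the condition is indicated at any baseline
    encounter at or before ``at_age`` it stays present (chronic-disease
    semantics).  Treatment derives from medication orders of the condition's
    drug classes, active from order age through the end of the baseline
    window; control from the most recent control measurement.
    """
    lo, hi = btw
    if not lo <= at_age < hi:
        raise WindowError(f"at_age {at_age} outside baseline window [{lo}, {hi})")

    indications = condition_indication(timeline, condition_def, (lo, at_age + 1e-9),
                                       measurement_units)
    present = int(any(flag for _, flag in indications))

    # control: most recent control measurement at or before at_age
    controlled: Optional[int] = None
    control_meas = condition_def.control_measurements
    latest: dict[str, tuple[float, float]] = {}
    for e in timeline.events:
        if e.kind in ("lab", "vital") and e.code in control_meas and lo <= e.event_age <= at_age:
            prev = latest.get(e.code)
            if prev is None or e.event_age >= prev[0]:
                latest[e.code] = (e.event_age, e.value)
    if condition_def.severity_mode == "bands":
        meas = condition_def.band_measurement
        vals = [
            (e.event_age, e.value)
            for e in timeline.events
            if e.kind in ("lab", "vital") and e.code == meas and lo <= e.event_age <= at_age
        ]
        band_values = [v for _, v in sorted(vals)]
        band = _band_level(band_values, condition_def.band_thresholds)
        if len(band_values) >= 2:
            controlled = int(band_values[-1] <= band_values[-2])
        treated = int(present and band >= 1)
        if present and band >= 2:
            line = "second" if band == 2 else "last"
        elif treated:
            line = "first"
        else:
            line = "none"
        dose = "none"
        if not present:
            return PatientState(condition_def.name, at_age, 0, 0, "none", "none",
                                controlled, band=0)
        return PatientState(condition_def.name, at_age, 1, treated, line, dose,
                            controlled, band=band)
    else:
        if latest:
            ok = all(
                any(c.in_range(latest[m][1]) for c in condition_def.control_criteria
                    if c.measurement == m)
                for m in latest
            )
            controlled = int(ok)
        # medications: active from order age to end of BTW
        active: set[str] = set()
        dose = "none"
        dose_age = -1.0
        for e in timeline.events:
            if e.kind != "medication" or not lo <= e.event_age <= at_age:
                continue
            if e.code in condition_def.drug_classes:
                active.add(e.code)
                if e.event_age >= dose_age:
                    dose_age = e.event_age
                    dose = e.dose_change or "none"
        treated = int(bool(active))
        if treated and not present:
            # therapy for the condition is itself clinical evidence of it
            present = 1
        if not treated:
            line = "none"
        else:
            line_rank = max(THERAPY_LINE_ORDER[condition_def.therapy_lines[c]] for c in active)
            if (condition_def.last_if_n_classes is not None
                    and len(active) >= condition_def.last_if_n_classes):
                line_rank = THERAPY_LINE_ORDER["last"]
            line = {v: k for k, v in THERAPY_LINE_ORDER.items()}[line_rank]

    if not present:
        controlled_out = controlled if controlled is not None else None
        return PatientState(condition_def.name, at_age, 0, 0, "none", "none", controlled_out)
    return PatientState(condition_def.name, at_age, 1, treated, line, dose, controlled)


def state_score(tree: DSHTree, state: PatientState, condition_def: ConditionDefinition | None = None) -> float:
    """Score of the deepest tree node matching the state; 0 when disease-free."""
    if state.condition_name != tree.condition_name:
        raise ValueError(
            f"state is for {state.condition_name!r}, tree for {tree.condition_name!r}"
        )
    if not state.present:
        return 0.0
    node = tree.root
    for decider in tree.deciders:
        if decider.startswith("band:"):
            k = int(decider.split(":")[1])
            go_right = (state.band or 0) >= k
        else:
            go_right = _DECIDER_FUNCS[decider](state)
        node = node.right if go_right else node.left
    return float(node.score)


def score_trajectory(
    timeline: PatientTimeline,
    tree: DSHTree,
    condition_def: ConditionDefinition,
    btw: tuple[float, float],
    measurement_units: Mapping[str, str] | None = None,
) -> ScoreTrajectory:
    """Time-varying DSH risk score: one sample per baseline encounter."""
    traj = ScoreTrajectory(condition_name=tree.condition_name)
    for age in timeline.encounter_ages(btw):
        st = classify_state(timeline, condition_def, age, btw, measurement_units)
        traj.samples.append((age, state_score(tree, st)))
    return traj
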