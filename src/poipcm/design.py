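"""Declarative model of the two-task tactile conditioning design.

The default experiment crosses two conditioning tasks (aversive pressure to
the right thumb, appetitive brush to the left forearm) with three conditioned
stimuli per task (two CS+ faces paired with touch, one CS- face never paired),
presented once per block across six CS-US paired blocks per task.  Only the
paired blocks contribute trials to representational similarity analysis; the
seven CS-only blocks per task are carried for the block count but generate no
trial events.

This module is the single source of truth for condition identity and trial
enumeration consumed by the RSA condenser and the POI constructors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "DesignError",
    "TaskSpec",
    "ConditionLabel",
    "TrialEvent",
    "ExperimentDesign",
    "build_design",
    "default_design",
    "condition_table",
    "CANONICAL_CONDITIONS",
]


class DesignError(ValueError):
    """Raised for invalid experiment-design declarations."""


@dataclass(frozen=True)
class TaskSpec:
    """One conditioning task: a US type with its CS and block counts."""

    task_id: str
    us_type: str
    n_cs_plus: int = 2
    n_cs_minus: int = 1
    n_paired_blocks: int = 6
    n_cs_only_blocks: int = 7

    def __post_init__(self) -> None:
        for name in ("n_cs_plus", "n_cs_minus", "n_paired_blocks", "n_cs_only_blocks"):
            if getattr(self, name) <= 0:
                raise DesignError(f"{name} must be strictly positive, got {getattr(self, name)}")

    @property
    def n_conditions(self) -> int:
        return self.n_cs_plus + self.n_cs_minus


@dataclass(frozen=True)
class ConditionLabel:
    """One face-touch pairing with its derived class attributes.

    ``valence_class`` groups conditions experienced as positive (PT) or
    negative (NT) relative to their task context; ``salience_class`` separates
    touch-stimulated (high) from unstimulated (low) trials;
    ``probability_class`` marks the rarer outcome (the unpaired CS-).
    """

    condition_id: int
    name: str
    task: str
    touch: str  # {"pressure", "brush", "none"}
    valence_class: str  # {"PT", "NT"}
    salience_class: str  # {"high", "low"}
    face_id: str
    probability_class: str  # {"frequent", "rare"}


@dataclass(frozen=True)
class TrialEvent:
    trial_id: int
    condition_id: int
    block_id: int
    task: str


@dataclass(frozen=True)
class ExperimentDesign:
    tasks: tuple[TaskSpec, ...]
    conditions: tuple[ConditionLabel, ...]
    trials: tuple[TrialEvent, ...]
    reps_per_condition: int = 6

    @property
    def n_conditions(self) -> int:
        return len(self.conditions)

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    @property
    def n_total_blocks(self) -> int:
        """Paired plus CS-only blocks summed over tasks (26 by default)."""
        return sum(t.n_paired_blocks + t.n_cs_only_blocks for t in self.tasks)

    def condition_of_trial(self) -> list[int]:
        return [t.condition_id for t in self.trials]

    def conditions_of_task(self, task_id: str) -> list[ConditionLabel]:
        return [c for c in self.conditions if c.task == task_id]


#: Canonical 6-condition order for the default design.
CANONICAL_CONDITIONS = ("P+1", "P+2", "P-", "B+1", "B+2", "B-")

_DEFAULT_TASKS = (
    TaskSpec(task_id="pressure", us_type="aversive-pressure"),
    TaskSpec(task_id="brush", us_type="appetitive-brush"),
)


def _default_conditions(tasks: tuple[TaskSpec, TaskSpec]) -> tuple[ConditionLabel, ...]:
    """Enumerate the canonical six conditions with their class attributes.

    Positive-trial (PT) class: brush CS+ plus the pressure-task CS- (safety);
    negative-trial (NT) class: pressure CS+ plus the brush-task CS- (omission).
    """
    pressure, brush = tasks
    rows = [
        # (name, task, touch, valence, salience, probability)
        ("P+1", pressure.task_id, "pressure", "NT", "high", "frequent"),
        ("P+2", pressure.task_id, "pressure", "NT", "high", "frequent"),
        ("P-", pressure.task_id, "none", "PT", "low", "rare"),
        ("B+1", brush.task_id, "brush", "PT", "high", "frequent"),
        ("B+2", brush.task_id, "brush", "PT", "high", "frequent"),
        ("B-", brush.task_id, "none", "NT", "low", "rare"),
    ]
    return tuple(
        ConditionLabel(
            condition_id=i,
            name=name,
            task=task,
            touch=touch,
            valence_class=val,
            salience_class=sal,
            face_id=f"face{i + 1}",
            probability_class=prob,
        )
        for i, (name, task, touch, val, sal, prob) in enumerate(rows)
    )


def _generic_conditions(tasks: tuple[TaskSpec, ...]) -> tuple[ConditionLabel, ...]:
    """Conditions for non-default designs: CS+ then CS- within each task."""
    out: list[ConditionLabel] = []
    cid = 0
    for task in tasks:
        touch = "pressure" if "pressure" in task.us_type else (
            "brush" if "brush" in task.us_type else "none"
        )
        for j in range(task.n_cs_plus):
            out.append(
                ConditionLabel(cid, f"{task.task_id}+{j + 1}", task.task_id, touch,
                               "NT" if touch == "pressure" else "PT",
                               "high", f"face{cid + 1}", "frequent")
            )
            cid += 1
        for j in range(task.n_cs_minus):
            out.append(
                ConditionLabel(cid, f"{task.task_id}-{j + 1}", task.task_id, "none",
                               "PT" if touch == "pressure" else "NT",
                               "low", f"face{cid + 1}", "rare")
            )
            cid += 1
    return tuple(out)


def build_design(tasks: tuple[TaskSpec, ...] | None = None) -> ExperimentDesign:
    """Build an :class:`ExperimentDesign` from task specifications.

    With the default two-task specification this enumerates 36 paired trial
    events (2 tasks x 6 paired blocks x 3 CS) over 26 total blocks, with the
    canonical condition order ``P+1, P+2, P-, B+1, B+2, B-``.

    Parameters
    ----------
    tasks : tuple of TaskSpec, optional
        Task declarations; ``None`` selects the default two-task design.

    Raises
    ------
    DesignError
        If any count is non-positive (raised by ``TaskSpec``).
    """
    if tasks is None:
        tasks = _DEFAULT_TASKS
    tasks = tuple(tasks)
    if not tasks:
        raise DesignError("at least one task required")
    is_default = (
        len(tasks) == 2
        and all(t.n_cs_plus == 2 and t.n_cs_minus == 1 for t in tasks)
        and {t.us_type for t in tasks} == {"aversive-pressure", "appetitive-brush"}
    )
    if is_default:
        ordered = tuple(sorted(tasks, key=lambda t: t.us_type != "aversive-pressure"))
        conditions = _default_conditions(ordered)  # type: ignore[arg-type]
    else:
        conditions = _generic_conditions(tasks)

    cond_by_task: dict[str, list[ConditionLabel]] = {}
    for c in conditions:
        cond_by_task.setdefault(c.task, []).append(c)

    trials: list[TrialEvent] = []
    tid = 0
    for task in tasks:
        for block in range(task.n_paired_blocks):
            for cond in cond_by_task[task.task_id]:
                trials.append(TrialEvent(tid, cond.condition_id, block, task.task_id))
                tid += 1

    reps = tasks[0].n_paired_blocks
    return ExperimentDesign(tasks=tasks, conditions=conditions,
                            trials=tuple(trials), reps_per_condition=reps)


def default_design() -> ExperimentDesign:
    """The default 6-condition, 36-trial, 26-block two-task design."""
    return build_design(None)


def condition_table(design: ExperimentDesign) -> list[ConditionLabel]:
    """Return the design's conditions in canonical order."""
    return sorted(design.conditions, key=lambda c: c.condition_id)
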