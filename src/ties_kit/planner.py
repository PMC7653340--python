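"""Ensemble task planning, config emission and output sanity checks.

Expands a ligand pair (or complex) into the concrete set of replica
simulations: for ensemble TI one task per (environment, λ window, replica)
— 13 windows × 5 replicas = 65 tasks per environment with the defaults —
and for the ensemble MMPBSA protocol (ESMACS) a flat ensemble of 25
replicas of 4 ns each.  Every task carries the full staged protocol
(minimize, heat 50→300 K over 60 ps, 2 ns restrained NPT equilibration
with a stepwise restraint release, 4 ns production) and a deterministic
per-task velocity seed derived from one master seed: replicas share
starting coordinates and differ only in their initial velocities.

The emitted per-task configuration stubs are keyword/value text files in a
versioned dialect owned by this project; byte-identical re-emission from
the same plan is a contract, engine compatibility is not.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import SchemaError, TiesKitError
from .hybrid import HybridTopology
from .schedule import LambdaSchedule, coupling_state, default_schedule

__all__ = [
    "ProtocolStage",
    "SimulationTask",
    "SimulationPlan",
    "default_stages",
    "plan_ties",
    "plan_esmacs",
    "emit_configs",
    "sanity_check",
    "SanityReport",
    "write_plan",
    "read_plan",
]

PLAN_SCHEMA = "ties-kit/simulation-plan"
PLAN_SCHEMA_VERSION = 1
CONFIG_DIALECT = "ties-kit/config-stub v1"
MANIFEST_NAME = "manifest.json"

#: protocol constants (ps, K, bar unless noted)
HEAT_PS = 60.0
HEAT_START_K = 50.0
TEMPERATURE_K = 300.0
PRESSURE_BAR = 1.0
EQUILIBRATION_PS = 2000.0
PRODUCTION_PS = 4000.0
LANGEVIN_DAMPING_PS = 5.0  # ps^-1
BARO_COMPRESSIBILITY = 4.57e-5  # bar^-1
BARO_RELAXATION_FS = 100.0
#: stepwise release of heavy-atom restraints during equilibration (kcal/mol/Å²)
RESTRAINT_SCHEDULE = (4.0, 2.0, 1.0, 0.0)
MINIMIZE_STEPS = 1000


@dataclass(frozen=True)
class ProtocolStage:
    """One stage of the per-replica simulation protocol."""

    name: str  # minimize | heat | equilibrate | produce
    duration_ps: float
    temperature_start_k: float = TEMPERATURE_K
    temperature_end_k: float = TEMPERATURE_K
    pressure_bar: float | None = None
    restraints_kcal_mol_a2: tuple[float, ...] = ()
    thermostat_damping_ps: float = LANGEVIN_DAMPING_PS
    barostat_compressibility: float = BARO_COMPRESSIBILITY
    barostat_relaxation_fs: float = BARO_RELAXATION_FS
    minimize_steps: int | None = None

    def __post_init__(self) -> None:
        if self.duration_ps <= 0:
            raise ValueError("stage duration must be positive")
        if self.temperature_start_k <= 0 or self.temperature_end_k <= 0:
            raise ValueError("temperatures must be positive")


def default_stages(
    production_ps: float = PRODUCTION_PS,
    equilibration_ps: float = EQUILIBRATION_PS,
    minimize_steps: int = MINIMIZE_STEPS,
) -> tuple[ProtocolStage, ...]:
    """The default four-stage protocol template."""
    return (
        ProtocolStage(
            name="minimize", duration_ps=minimize_steps * 0.002,
            minimize_steps=minimize_steps,
            restraints_kcal_mol_a2=(RESTRAINT_SCHEDULE[0],),
        ),
        ProtocolStage(
            name="heat", duration_ps=HEAT_PS,
            temperature_start_k=HEAT_START_K, temperature_end_k=TEMPERATURE_K,
            restraints_kcal_mol_a2=(RESTRAINT_SCHEDULE[0],),
        ),
        ProtocolStage(
            name="equilibrate", duration_ps=equilibration_ps,
            pressure_bar=PRESSURE_BAR,
            restraints_kcal_mol_a2=RESTRAINT_SCHEDULE,
        ),
        ProtocolStage(
            name="produce", duration_ps=production_ps, pressure_bar=PRESSURE_BAR,
        ),
    )


@dataclass(frozen=True)
class SimulationTask:
    """One replica simulation: where, at which λ, with which seed."""

    pair_label: str
    environment: str
    lambda_value: float | None
    replica_index: int  # 1-based
    stages: tuple[ProtocolStage, ...]
    seed: int

    def __post_init__(self) -> None:
        if self.replica_index < 1:
            raise ValueError("replica_index is 1-based")


@dataclass
class SimulationPlan:
    """The full ensemble task set for one ligand pair or complex."""

    method: str  # "ties" | "esmacs"
    pair_label: str
    tasks: list[SimulationTask]
    n_replicas: int
    schedule: LambdaSchedule | None = None
    environments: tuple[str, ...] = ()
    master_seed: int = 0

    def __post_init__(self) -> None:
        seeds = [t.seed for t in self.tasks]
        if len(set(seeds)) != len(seeds):
            raise ValueError("task seeds must be unique")
        if self.method == "ties":
            expect = len(self.environments) * len(self.schedule) * self.n_replicas
        elif self.method == "esmacs":
            expect = self.n_replicas
        else:
            raise ValueError(f"unknown method {self.method!r}")
        if len(self.tasks) != expect:
            raise ValueError(f"expected {expect} tasks, got {len(self.tasks)}")

    def __len__(self) -> int:
        return len(self.tasks)


def _task_seed(master_seed: int, index: int) -> int:
    """Deterministic, collision-free per-task seed below 2³¹."""
    ss = np.random.SeedSequence(entropy=int(master_seed), spawn_key=(index,))
    return int(ss.generate_state(1)[0] % (2**31))


def plan_ties(
    pair_label: str,
    schedule: LambdaSchedule | None = None,
    n_replicas: int = 5,
    environments: Sequence[str] = ("bound", "aqueous"),
    seed: int = 0,
    production_ps: float = PRODUCTION_PS,
) -> SimulationPlan:
    """Ensemble-TI task set: one task per (environment, λ, replica).

    With the default 13-window schedule and 5 replicas this is 65 tasks per
    environment for the ligand pair, 130 across both environments.
    """
    if n_replicas < 1:
        raise ValueError("n_replicas must be at least 1")
    if schedule is None:
        schedule = default_schedule()
    if len(schedule) == 0:
        raise ValueError("schedule must be non-empty")
    stages = default_stages(production_ps=production_ps)
    tasks: list[SimulationTask] = []
    idx = 0
    seen = set()
    for env in environments:
        if env in seen:
            raise ValueError(f"duplicate environment {env!r}")
        seen.add(env)
        for lam in schedule:
            for rep in range(1, n_replicas + 1):
                tasks.append(
                    SimulationTask(
                        pair_label=pair_label,
                        environment=env,
                        lambda_value=lam,
                        replica_index=rep,
                        stages=stages,
                        seed=_task_seed(seed, idx),
                    )
                )
                idx += 1
    return SimulationPlan(
        method="ties",
        pair_label=pair_label,
        tasks=tasks,
        n_replicas=n_replicas,
        schedule=schedule,
        environments=tuple(environments),
        master_seed=seed,
    )


def plan_esmacs(
    complex_label: str,
    n_replicas: int = 25,
    production_ps: float = PRODUCTION_PS,
    seed: int = 0,
) -> SimulationPlan:
    """Ensemble task set for the absolute (MMPBSA-style) protocol: a flat
    ensemble of replicas — 25 × 4 ns by default — with no λ dimension."""
    if n_replicas < 1:
        raise ValueError("n_replicas must be at least 1")
    stages = default_stages(production_ps=production_ps)
    tasks = [
        SimulationTask(
            pair_label=complex_label,
            environment="bound",
            lambda_value=None,
            replica_index=rep,
            stages=stages,
            seed=_task_seed(seed, rep - 1),
        )
        for rep in range(1, n_replicas + 1)
    ]
    return SimulationPlan(
        method="esmacs",
        pair_label=complex_label,
        tasks=tasks,
        n_replicas=n_replicas,
        environments=("bound",),
        master_seed=seed,
    )


# ---------------------------------------------------------------------------
# plan document I/O


def write_plan(plan: SimulationPlan, path: str | Path) -> None:
    doc = {
        "schema": PLAN_SCHEMA,
        "version": PLAN_SCHEMA_VERSION,
        "method": plan.method,
        "pair_label": plan.pair_label,
        "n_replicas": plan.n_replicas,
        "master_seed": plan.master_seed,
        "environments": list(plan.environments),
        "schedule": None
        if plan.schedule is None
        else {
            "values": list(plan.schedule.values),
            "elec_off_end": plan.schedule.elec_off_end,
            "elec_on_start": plan.schedule.elec_on_start,
        },
        "tasks": [
            {**asdict(t), "stages": [asdict(s) for s in t.stages]} for t in plan.tasks
        ],
    }
    Path(path).write_text(json.dumps(doc, indent=2) + "\n")


def read_plan(path: str | Path) -> SimulationPlan:
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise SchemaError(f"{path}: not valid JSON ({exc})") from exc
    if doc.get("schema") != PLAN_SCHEMA:
        raise SchemaError(f"{path}: schema is not {PLAN_SCHEMA!r}")
    sched = None
    if doc.get("schedule") is not None:
        s = doc["schedule"]
        sched = LambdaSchedule(
            values=tuple(s["values"]),
            elec_off_end=s["elec_off_end"],
            elec_on_start=s["elec_on_start"],
        )
    tasks = []
    for t in doc["tasks"]:
        stages = tuple(
            ProtocolStage(**{**s, "restraints_kcal_mol_a2": tuple(s["restraints_kcal_mol_a2"])})
            for s in t["stages"]
        )
        tasks.append(
            SimulationTask(
                pair_label=t["pair_label"],
                environment=t["environment"],
                lambda_value=t["lambda_value"],
                replica_index=t["replica_index"],
                stages=stages,
                seed=t["seed"],
            )
        )
    return SimulationPlan(
        method=doc["method"],
        pair_label=doc["pair_label"],
        tasks=tasks,
        n_replicas=doc["n_replicas"],
        schedule=sched,
        environments=tuple(doc["environments"]),
        master_seed=doc["master_seed"],
    )


# ---------------------------------------------------------------------------
# config emission and sanity checking


def _task_filename(task: SimulationTask) -> str:
    if task.lambda_value is None:
        return f"{task.pair_label}_{task.environment}_r{task.replica_index:02d}.conf"
    return (
        f"{task.pair_label}_{task.environment}_l{task.lambda_value:.3f}"
        f"_r{task.replica_index:02d}.conf"
    )


def _render_config(task: SimulationTask, plan: SimulationPlan, hybrid: HybridTopology | None) -> str:
    lines = [
        f"# {CONFIG_DIALECT}",
        f"pairLabel        {task.pair_label}",
        f"environment      {task.environment}",
        f"replica          {task.replica_index}",
        f"velocitySeed     {task.seed}",
    ]
    if task.lambda_value is not None and plan.schedule is not None:
        cs = coupling_state(task.lambda_value, plan.schedule)
        lines += [
            f"alchLambda       {task.lambda_value!r}",
            f"alchElecOnStart  {plan.schedule.elec_on_start!r}",
            f"alchElecOffEnd   {plan.schedule.elec_off_end!r}",
            f"vdwAppearing     {cs.vdw_appearing!r}",
            f"vdwDisappearing  {cs.vdw_disappearing!r}",
            f"elecAppearing    {cs.elec_appearing!r}",
            f"elecDisappearing {cs.elec_disappearing!r}",
        ]
    if hybrid is not None:
        lines += [
            f"hybridCoreAtoms         {len(hybrid.core)}",
            f"hybridDisappearingAtoms {len(hybrid.disappearing)}",
            f"hybridAppearingAtoms    {len(hybrid.appearing)}",
        ]
    for st in task.stages:
        lines.append(f"stage {st.name}")
        lines.append(f"  durationPs     {st.duration_ps!r}")
        if st.minimize_steps is not None:
            lines.append(f"  minimizeSteps  {st.minimize_steps}")
        lines.append(f"  tempStartK     {st.temperature_start_k!r}")
        lines.append(f"  tempEndK       {st.temperature_end_k!r}")
        if st.pressure_bar is not None:
            lines.append(f"  pressureBar    {st.pressure_bar!r}")
            lines.append(f"  baroCompress   {st.barostat_compressibility!r}")
            lines.append(f"  baroRelaxFs    {st.barostat_relaxation_fs!r}")
        lines.append(f"  langevinPs-1   {st.thermostat_damping_ps!r}")
        if st.restraints_kcal_mol_a2:
            sched = " ".join(repr(v) for v in st.restraints_kcal_mol_a2)
            lines.append(f"  restraints     {sched}")
    return "\n".join(lines) + "\n"


def emit_configs(
    plan: SimulationPlan,
    outdir: str | Path,
    hybrid: HybridTopology | None = None,
    force: bool = False,
) -> dict:
    """Write one configuration stub per task plus a checksummed manifest.

    Refuses to write into an existing non-empty directory unless ``force``;
    identical plan (and hybrid) input yields byte-identical output.
    """
    outdir = Path(outdir)
    if outdir.exists() and any(outdir.iterdir()) and not force:
        raise TiesKitError(
            f"{outdir} exists and is not empty; pass force=True to overwrite"
        )
    outdir.mkdir(parents=True, exist_ok=True)
    entries = []
    for task in plan.tasks:
        name = _task_filename(task)
        text = _render_config(task, plan, hybrid)
        (outdir / name).write_text(text)
        data = text.encode()
        entries.append(
            {"path": name, "bytes": len(data), "sha256": hashlib.sha256(data).hexdigest()}
        )
    manifest = {
        "schema": "ties-kit/manifest",
        "version": 1,
        "pair_label": plan.pair_label,
        "method": plan.method,
        "files": entries,
    }
    (outdir / MANIFEST_NAME).write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest


@dataclass
class SanityReport:
    """Outcome of the zero-length/missing-file check over an output tree."""

    checked: int
    defects: list[tuple[str, str]] = field(default_factory=list)  # (path, problem)

    @property
    def ok(self) -> bool:
        return not self.defects

    def summary(self) -> str:
        if self.ok:
            return f"sanity check: {self.checked} files present and non-empty"
        lines = [f"sanity check: {len(self.defects)} defect(s) in {self.checked} files"]
        lines += [f"  {p}: {why}" for p, why in self.defects]
        return "\n".join(lines)


def sanity_check(outdir: str | Path) -> SanityReport:
    """Verify that every manifest-listed file exists and has non-zero length."""
    outdir = Path(outdir)
    manifest_path = outdir / MANIFEST_NAME
    if not manifest_path.exists():
        raise SchemaError(f"{outdir}: no {MANIFEST_NAME} — nothing to check")
    manifest = json.loads(manifest_path.read_text())
    defects: list[tuple[str, str]] = []
    files = manifest.get("files", [])
    for entry in files:
        p = outdir / entry["path"]
        if not p.exists():
            defects.append((entry["path"], "missing"))
        elif p.stat().st_size == 0:
            defects.append((entry["path"], "zero length"))
    return SanityReport(checked=len(files), defects=defects)
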