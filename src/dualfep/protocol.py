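"""λ schedules, MD input decks and simulation-time accounting.

Each λ window samples the mixed potential ``U_i = (1−λ_i)·U_A + λ_i·U_B``.
The default protocol runs 10 replicate simulations differing only in their
initial random velocities; each replicate heats the sphere from 0.1 to
298 K over 31 ps while releasing a 25 kcal/mol/Å² solute restraint, then
equilibrates unrestrained for 100 ps, then samples 51 evenly spaced λ
windows for 10 ps each at a 1 fs time step — 6.41 ns per leg and 12.82 ns
per perturbation (bound plus reference leg).
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field

import numpy as np

from .constants import DEFAULT_SPHERE_RADIUS, DEFAULT_TEMPERATURE, SPHERE_EXCLUSION_RESTRAINT
from .dual_topology import DualTopologySpec

__all__ = [
    "LambdaSchedule",
    "EquilStage",
    "ProtocolPlan",
    "make_lambda_schedule",
    "total_sampling_time",
    "mixed_potential",
    "write_md_inputs",
]


@dataclass(frozen=True)
class LambdaSchedule:
    """Ordered λ values, possibly split into two branches.

    ``start`` is 0, 1 or 0.5.  With start 0 or 1 there is one branch running
    monotonically to the other endpoint.  With start 0.5 there are two
    branches, both beginning at the midpoint, one ending at 1 and one at 0;
    ``n`` then counts windows per branch (the midpoint is sampled in both).
    """

    branches: tuple[tuple[float, ...], ...]
    mode: str = "linear"
    start: float = 1.0

    def __post_init__(self):
        if not self.branches:
            raise ValueError("schedule needs at least one branch")
        for br in self.branches:
            if any(v < 0.0 or v > 1.0 for v in br):
                raise ValueError("λ values must lie in [0, 1]")
            diffs = [b - a for a, b in zip(br, br[1:])]
            if not (all(d > 0 for d in diffs) or all(d < 0 for d in diffs)):
                raise ValueError("branch must be strictly monotone")
        if self.start == 0.5:
            if len(self.branches) != 2:
                raise ValueError("midpoint start requires two branches")
            ends = sorted(br[-1] for br in self.branches)
            if any(br[0] != 0.5 for br in self.branches) or ends != [0.0, 1.0]:
                raise ValueError("midpoint branches must run 0.5→1 and 0.5→0")

    @property
    def values(self) -> tuple[float, ...]:
        """All λ values, branches concatenated."""
        return tuple(v for br in self.branches for v in br)

    @property
    def n_windows(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class EquilStage:
    """One equilibration stage: duration, bath temperature(s), solute restraint."""

    duration_ps: float
    temperature_start: float
    temperature_end: float
    solute_restraint: float  # kcal/mol/Å²

    def __post_init__(self):
        if self.duration_ps <= 0:
            raise ValueError("stage duration must be positive")


def default_equilibration() -> list[EquilStage]:
    """Heating ramp 0.1→298 K over 31 ps (five stages, restraint released
    25→0), then 100 ps unbiased and unrestrained at 298 K."""
    durations = [1.0, 2.0, 4.0, 8.0, 16.0]
    restraints = [25.0, 25.0, 10.0, 5.0, 1.0]
    temps = np.linspace(0.1, DEFAULT_TEMPERATURE, len(durations) + 1)
    stages = [
        EquilStage(d, float(temps[i]), float(temps[i + 1]), restraints[i])
        for i, d in enumerate(durations)
    ]
    stages.append(EquilStage(100.0, DEFAULT_TEMPERATURE, DEFAULT_TEMPERATURE, 0.0))
    return stages


@dataclass
class ProtocolPlan:
    """Replicates, equilibration stages and production settings."""

    replicates: int = 10
    equilibration: list[EquilStage] = field(default_factory=default_equilibration)
    production_ps: float = 10.0
    timestep_fs: float = 1.0
    temperature: float = DEFAULT_TEMPERATURE
    sphere_radius: float = DEFAULT_SPHERE_RADIUS
    sphere_restraint: float = SPHERE_EXCLUSION_RESTRAINT
    nonbonded_cutoff: float = 10.0   # Å; no cutoff for FEP atoms
    shake_solvent: bool = True

    def __post_init__(self):
        if self.replicates < 1:
            raise ValueError("need at least one replicate")
        if self.production_ps <= 0 or self.timestep_fs <= 0:
            raise ValueError("durations must be positive")

    @property
    def equilibration_ps(self) -> float:
        return float(sum(s.duration_ps for s in self.equilibration))


# ---------------------------------------------------------------------------
# Schedules
# ---------------------------------------------------------------------------

def _branch(start: float, end: float, n: int, mode: str, sharpness: float) -> tuple[float, ...]:
    t = np.linspace(0.0, 1.0, n)
    if mode == "sigmoidal":
        # tanh warp: largest steps mid-branch, densest at the endpoints;
        # endpoints are exact by construction.
        t = 0.5 * (1.0 + np.tanh(sharpness * (2.0 * t - 1.0)) / math.tanh(sharpness))
    vals = start + (end - start) * t
    vals[0], vals[-1] = start, end
    return tuple(float(v) for v in vals)


def make_lambda_schedule(n: int, mode: str = "linear", start: float = 1.0,
                         sharpness: float = 2.0) -> LambdaSchedule:
    """Build a λ schedule of *n* windows (per branch for midpoint start).

    ``linear`` gives evenly spaced values including both branch endpoints;
    ``sigmoidal`` warps them through a tanh so spacing is strictly smaller
    near the endpoints than mid-branch, useful when the end states overlap
    poorly with their neighbours.
    """
    if n < 2:
        raise ValueError("a schedule needs at least two λ values")
    if mode not in ("linear", "sigmoidal"):
        raise ValueError(f"unknown schedule mode {mode!r}")
    if start == 1.0:
        branches = (_branch(1.0, 0.0, n, mode, sharpness),)
    elif start == 0.0:
        branches = (_branch(0.0, 1.0, n, mode, sharpness),)
    elif start == 0.5:
        branches = (_branch(0.5, 1.0, n, mode, sharpness),
                    _branch(0.5, 0.0, n, mode, sharpness))
    else:
        raise ValueError("start must be 0, 0.5 or 1")
    return LambdaSchedule(branches=branches, mode=mode, start=start)


def total_sampling_time(plan: ProtocolPlan, schedule: LambdaSchedule) -> tuple[float, float]:
    """Simulation-time accounting: (ns per leg, ns per perturbation).

    Per leg: replicates × (equilibration + windows × production).  A
    perturbation closes a thermodynamic cycle with two legs (bound and
    reference), so the per-perturbation total is twice the per-leg time.
    """
    per_leg_ps = plan.replicates * (
        plan.equilibration_ps + schedule.n_windows * plan.production_ps)
    per_leg_ns = per_leg_ps / 1000.0
    return per_leg_ns, 2.0 * per_leg_ns


def mixed_potential(u_a, u_b, lam: float):
    """Linear λ mixing ``U = (1−λ)·U_A + λ·U_B`` (kcal/mol)."""
    if lam < 0.0 or lam > 1.0:
        raise ValueError(f"λ must lie in [0, 1], got {lam}")
    return (1.0 - lam) * np.asarray(u_a) + lam * np.asarray(u_b)


# ---------------------------------------------------------------------------
# Input decks
# ---------------------------------------------------------------------------

def _replicate_seed(master_seed: int, replicate: int) -> int:
    return (master_seed * 1_000_003 + 7919 * replicate + 1) % (2 ** 31)


def _window_name(lam: float) -> str:
    # Q convention: state weights in thousandths, e.g. md_1000_0000 for λ=0
    a = int(round((1.0 - lam) * 1000))
    return f"md_{a:04d}_{1000 - a:04d}"


def _md_input_text(plan: ProtocolPlan, *, steps: int, temperature: float,
                   seed: int | None, lam: float | None,
                   solute_restraint: float, topology: str, fep: str | None,
                   restart: str | None) -> str:
    lines = ["[MD]",
             f"steps        {steps}",
             f"stepsize     {plan.timestep_fs}",
             f"temperature  {temperature:.2f}",
             "bath_coupling 10"]
    if seed is not None:
        lines.append(f"random_seed  {seed}")
        lines.append("initial_temperature on")
    lines += ["[cut-offs]",
              f"solute_solute  {plan.nonbonded_cutoff}",
              f"solvent_solvent {plan.nonbonded_cutoff}",
              f"solute_solvent {plan.nonbonded_cutoff}",
              "q_atom 99",  # no cutoff for the FEP region
              "[sphere]",
              f"shell_radius  {plan.sphere_radius}",
              f"excluded_force {plan.sphere_restraint}"]
    if plan.shake_solvent:
        lines += ["[shake]", "solvent on"]
    if lam is not None:
        lines += ["[lambdas]", f"{1.0 - lam:.6f} {lam:.6f}"]
    if solute_restraint > 0:
        lines += ["[sequence_restraints]",
                  f"solute {solute_restraint:.2f}"]
    lines += ["[files]", f"topology   {topology}"]
    if fep is not None:
        lines.append(f"fep        {fep}")
    if restart is not None:
        lines.append(f"restart    {restart}")
    return "\n".join(lines) + "\n"


def write_md_inputs(plan: ProtocolPlan, schedule: LambdaSchedule,
                    spec: DualTopologySpec | None, outdir,
                    master_seed: int = 42, topology_file: str = "dual.top",
                    fep_file: str = "dual.fep",
                    cluster_template: str | None = None) -> list[str]:
    """Write the full input deck: equilibration + one file per (replicate, window).

    The deck is a pure function of (plan, schedule, spec, master seed): two
    invocations with the same arguments produce byte-identical files.  Each
    replicate gets a distinct deterministic velocity seed.  Midpoint-start
    schedules get one subdirectory per branch per replicate.  If
    *cluster_template* is given, a submit script is rendered from it with
    ``{jobname}`` and ``{n_replicates}`` placeholders.
    """
    written: list[str] = []
    os.makedirs(outdir, exist_ok=True)
    branch_names = (["up", "down"] if len(schedule.branches) == 2 else [""])
    for rep in range(1, plan.replicates + 1):
        seed = _replicate_seed(master_seed, rep)
        repdir = os.path.join(outdir, f"rep{rep:02d}")
        os.makedirs(repdir, exist_ok=True)
        prev = None
        for i, stage in enumerate(plan.equilibration, start=1):
            steps = int(round(stage.duration_ps * 1000.0 / plan.timestep_fs))
            text = _md_input_text(
                plan, steps=steps, temperature=stage.temperature_end,
                seed=seed if i == 1 else None,
                lam=schedule.branches[0][0],
                solute_restraint=stage.solute_restraint,
                topology=topology_file, fep=fep_file, restart=prev)
            path = os.path.join(repdir, f"eq{i}.inp")
            with open(path, "w") as fh:
                fh.write(text)
            written.append(path)
            prev = f"eq{i}.re"
        eq_restart = prev
        for branch, bname in zip(schedule.branches, branch_names):
            bdir = os.path.join(repdir, bname) if bname else repdir
            os.makedirs(bdir, exist_ok=True)
            prev = eq_restart
            steps = int(round(plan.production_ps * 1000.0 / plan.timestep_fs))
            for lam in branch:
                name = _window_name(lam)
                text = _md_input_text(
                    plan, steps=steps, temperature=plan.temperature,
                    seed=None, lam=lam, solute_restraint=0.0,
                    topology=topology_file, fep=fep_file, restart=prev)
                path = os.path.join(bdir, f"{name}.inp")
                with open(path, "w") as fh:
                    fh.write(text)
                written.append(path)
                prev = f"{name}.re"
    if cluster_template is not None:
        script = cluster_template.format(jobname="dualfep",
                                         n_replicates=plan.replicates)
        path = os.path.join(outdir, "submit.sh")
        with open(path, "w") as fh:
            fh.write(script)
        written.append(path)
    return written
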