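"""Free-energy estimation from per-window end-state energies.

Each λ window stores samples of the two end-state potentials U_A and U_B;
because the mixed potential is linear in λ, the perturbation energy between
windows i and j is ``ΔU = (λ_j − λ_i)·(U_B − U_A)`` evaluated on either
window's own samples.  Adjacent windows are combined with Zwanzig's
exponential formula, overlap sampling (OS), or Bennett's acceptance ratio
(BAR) — the statistically optimal two-state estimator and the default here.
Window contributions sum to the leg ΔG; replicate legs give mean ± SEM;
two legs close a thermodynamic cycle into a ΔΔG; a Born charging term
corrects perturbations that change the net charge inside the finite
dielectric cavity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .constants import COULOMB_332, DEFAULT_TEMPERATURE, kT

__all__ = [
    "WindowSamples",
    "BornParameters",
    "PerturbationResult",
    "BarConvergenceError",
    "neighbor_delta_u",
    "zwanzig",
    "overlap_sampling",
    "bar",
    "bar_residual",
    "sum_windows",
    "combine_branches",
    "born_correction",
    "combine_replicates",
    "cycle_ddg",
    "hysteresis",
    "leg_free_energy",
    "write_samples_csv",
    "read_samples_csv",
]


class BarConvergenceError(RuntimeError):
    """BAR self-consistency not reached; carries the last iterate."""

    def __init__(self, message: str, last_iterate: float):
        super().__init__(message)
        self.last_iterate = last_iterate


@dataclass
class WindowSamples:
    """Samples of both end-state potentials at one λ window.

    ``u_a``/``u_b`` are equal-length arrays in kcal/mol drawn from the mixed
    ensemble at ``lam``; ``temperature`` in Kelvin.
    """

    lam: float
    u_a: np.ndarray
    u_b: np.ndarray
    temperature: float = DEFAULT_TEMPERATURE

    def __post_init__(self):
        self.u_a = np.asarray(self.u_a, dtype=float)
        self.u_b = np.asarray(self.u_b, dtype=float)
        if self.u_a.size == 0 or self.u_a.shape != self.u_b.shape:
            raise ValueError("u_a and u_b must be non-empty and equal length")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")

    @property
    def n(self) -> int:
        return int(self.u_a.size)


@dataclass(frozen=True)
class BornParameters:
    """Inputs to the Born charging correction.

    ``net_charge`` Q_I (e) of the solute, ``radius`` r_Born (Å) of the
    cavity, ``dielectric`` ε of the surrounding medium.
    """

    net_charge: float
    radius: float
    dielectric: float = 80.0

    def __post_init__(self):
        if self.radius <= 0:
            raise ValueError("Born radius must be positive")
        if self.dielectric < 1:
            raise ValueError("dielectric constant must be >= 1")


@dataclass
class PerturbationResult:
    """Per-leg result: replicate ΔG values, their mean and SEM, corrections."""

    replicate_dg: list[float]
    estimator: str = "bar"
    leg: str = "bound"            # bound | water | vacuum
    born: float = 0.0             # applied correction, kcal/mol
    direction: str = "forward"

    mean: float = field(init=False)
    sem: float | None = field(init=False)

    def __post_init__(self):
        if not self.replicate_dg:
            raise ValueError("need at least one replicate ΔG")
        vals = np.asarray(self.replicate_dg, dtype=float) + self.born
        self.mean = float(vals.mean())
        self.sem = (float(vals.std(ddof=1) / math.sqrt(len(vals)))
                    if len(vals) >= 2 else None)


# ---------------------------------------------------------------------------
# Per-window estimators
# ---------------------------------------------------------------------------

def neighbor_delta_u(w_i: WindowSamples, w_j: WindowSamples
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Forward and backward perturbation energies between adjacent windows.

    Returns ``(ΔU_f, ΔU_r)`` where the forward array is evaluated on window
    i's samples and the backward array on window j's:
    ``ΔU_f = (λ_j − λ_i)(U_B − U_A)|_i`` and
    ``ΔU_r = (λ_i − λ_j)(U_B − U_A)|_j``.
    """
    if w_i.temperature != w_j.temperature:
        raise ValueError("windows must share a temperature")
    dlam = w_j.lam - w_i.lam
    if dlam == 0.0:
        raise ValueError("adjacent windows must have distinct λ")
    forward = dlam * (w_i.u_b - w_i.u_a)
    backward = -dlam * (w_j.u_b - w_j.u_a)
    return forward, backward


def zwanzig(delta_u, temperature: float = DEFAULT_TEMPERATURE) -> float:
    """Exponential (Zwanzig) free-energy estimate, max-shift stabilized.

    ΔG = −kT·ln⟨exp(−ΔU/kT)⟩ over the sampled configurations of the initial
    state.
    """
    du = np.asarray(delta_u, dtype=float)
    if du.size == 0:
        raise ValueError("empty ΔU array")
    beta = 1.0 / kT(temperature)
    return float(-(logsumexp(-beta * du) - math.log(du.size)) / beta)


def overlap_sampling(delta_u_f, delta_u_r,
                     temperature: float = DEFAULT_TEMPERATURE) -> float:
    """Overlap-sampling estimate from forward and reverse perturbations.

    ΔG = −kT·ln[ ⟨exp(−ΔU_f/2kT)⟩_f / ⟨exp(−ΔU_r/2kT)⟩_r ] — a simple
    symmetric bridge between the two adjacent ensembles.
    """
    f = np.asarray(delta_u_f, dtype=float)
    r = np.asarray(delta_u_r, dtype=float)
    if f.size == 0 or r.size == 0:
        raise ValueError("empty ΔU array")
    beta = 1.0 / kT(temperature)
    log_f = logsumexp(-0.5 * beta * f) - math.log(f.size)
    log_r = logsumexp(-0.5 * beta * r) - math.log(r.size)
    return float(-(log_f - log_r) / beta)


def _bar_update(dg: float, f: np.ndarray, r: np.ndarray, beta: float,
                log_ratio: float) -> float:
    """One Bennett self-consistent update using the exact identity
    exp(−β(ΔG−C)) = ⟨fermi(β(ΔU_f−C))⟩_f / ⟨fermi(β(ΔU_r+C))⟩_r with the
    variance-optimal C = ΔG + kT·ln(n_f/n_r)."""
    c = dg + log_ratio / beta
    # log⟨fermi⟩ via logsumexp of -log(1+e^x) = -logaddexp(0, x)
    log_num = logsumexp(-np.logaddexp(0.0, beta * (f - c))) - math.log(f.size)
    log_den = logsumexp(-np.logaddexp(0.0, beta * (r + c))) - math.log(r.size)
    return c - (log_num - log_den) / beta


def bar(delta_u_f, delta_u_r, temperature: float = DEFAULT_TEMPERATURE,
        tol: float = 1e-7, max_iter: int = 500,
        return_error: bool = False):
    """Bennett acceptance ratio free-energy estimate.

    Solves Bennett's implicit equation (Fermi-function averages, including
    the ln(n_f/n_r) term for unequal sample counts) by self-consistent
    iteration started from the overlap-sampling estimate; converged when
    successive iterates differ by less than *tol* kcal/mol.  With
    ``return_error=True`` also returns Bennett's asymptotic standard error
    of the estimate.
    """
    f = np.asarray(delta_u_f, dtype=float)
    r = np.asarray(delta_u_r, dtype=float)
    if f.size == 0 or r.size == 0:
        raise ValueError("empty ΔU array")
    beta = 1.0 / kT(temperature)
    log_ratio = math.log(f.size / r.size)
    dg = overlap_sampling(f, r, temperature)
    for _ in range(max_iter):
        new = _bar_update(dg, f, r, beta, log_ratio)
        if abs(new - dg) < tol:
            dg = new
            break
        dg = new
    else:
        raise BarConvergenceError(
            f"BAR did not converge in {max_iter} iterations (last ΔG={dg:.6f})", dg)
    if not return_error:
        return float(dg)
    return float(dg), _bar_error(dg, f, r, beta, log_ratio)


def _bar_error(dg: float, f: np.ndarray, r: np.ndarray, beta: float,
               log_ratio: float) -> float:
    """Bennett's asymptotic variance of the BAR estimate (kcal/mol)."""
    c = dg + log_ratio / beta
    ff = 1.0 / (1.0 + np.exp(np.clip(beta * (f - c), -700, 700)))
    fr = 1.0 / (1.0 + np.exp(np.clip(beta * (r + c), -700, 700)))
    var = 0.0
    for w in (ff, fr):
        m = w.mean()
        var += ((w ** 2).mean() / m ** 2 - 1.0) / w.size
    return float(math.sqrt(max(var, 0.0)) / beta)


def bar_residual(dg: float, delta_u_f, delta_u_r,
                 temperature: float = DEFAULT_TEMPERATURE) -> float:
    """Signed residual of Bennett's implicit equation at a trial ΔG.

    Zero at the self-consistent solution; exposed so the root can be checked
    (or bracketed) independently of the iteration.
    """
    f = np.asarray(delta_u_f, dtype=float)
    r = np.asarray(delta_u_r, dtype=float)
    beta = 1.0 / kT(temperature)
    log_ratio = math.log(f.size / r.size)
    return _bar_update(dg, f, r, beta, log_ratio) - dg


# ---------------------------------------------------------------------------
# Aggregation
# ---------------------------------------------------------------------------

def sum_windows(per_window_dg) -> float:
    """Leg ΔG: arithmetic sum of ordered per-window contributions."""
    return float(np.sum(np.asarray(list(per_window_dg), dtype=float)))


def combine_branches(dg_mid_to_one: float, dg_mid_to_zero: float) -> float:
    """Combine the two midpoint branches into ΔG(0→1).

    Starting from λ=0.5 and propagating in each direction gives
    ΔG(0.5→1) and ΔG(0.5→0); the full transformation is their difference:
    ΔG(0→1) = ΔG(0.5→1) − ΔG(0.5→0).
    """
    return float(dg_mid_to_one - dg_mid_to_zero)


def born_correction(params: BornParameters) -> float:
    """Born charging correction (kcal/mol) for a net-charge change.

    ΔG_Born = −332·Q_I²/(2·r_Born)·(1 − 1/ε): the reversible work of
    charging a sphere of radius r_Born carrying net charge Q_I inside a
    dielectric ε, missed by the finite droplet.  Applied only when the
    perturbation changes the net charge of the sphere.
    """
    q, r, eps = params.net_charge, params.radius, params.dielectric
    return float(-COULOMB_332 * q * q / (2.0 * r) * (1.0 - 1.0 / eps))


def combine_replicates(replicate_dg) -> tuple[float, float | None]:
    """Mean and SEM over replicate ΔG values (SEM undefined for n = 1)."""
    vals = np.asarray(list(replicate_dg), dtype=float)
    if vals.size == 0:
        raise ValueError("no replicate values")
    mean = float(vals.mean())
    sem = float(vals.std(ddof=1) / math.sqrt(vals.size)) if vals.size >= 2 else None
    return mean, sem


def cycle_ddg(leg_main: PerturbationResult, leg_reference: PerturbationResult
              ) -> tuple[float, float | None]:
    """Close the thermodynamic cycle: ΔΔG = ΔG_main − ΔG_reference.

    The reference leg is the ligand pair in water for binding free energies,
    or the vacuum leg paired with the water leg for hydration free energies.
    SEMs propagate in quadrature.  Estimator and direction must match
    between the legs.
    """
    if leg_main.estimator != leg_reference.estimator:
        raise ValueError("legs were analyzed with different estimators")
    if leg_main.direction != leg_reference.direction:
        raise ValueError("legs were run in different directions")
    ddg = leg_main.mean - leg_reference.mean
    if leg_main.sem is None or leg_reference.sem is None:
        return float(ddg), None
    return float(ddg), float(math.hypot(leg_main.sem, leg_reference.sem))


def hysteresis(dg_forward: float, dg_backward: float) -> float:
    """|forward − sign-corrected backward| ΔG of the same transformation.

    The backward (creation) run estimates −ΔG of the forward (annihilation)
    transformation, so the discrepancy is |ΔG_fwd − (−ΔG_bwd)|.
    """
    return float(abs(dg_forward + dg_backward))


# ---------------------------------------------------------------------------
# Whole-leg pipeline
# ---------------------------------------------------------------------------

def leg_free_energy(windows: list[WindowSamples], estimator: str = "bar"
                    ) -> tuple[float, list[float]]:
    """ΔG along one ordered branch of windows, summed over adjacent pairs.

    Returns (leg ΔG, per-window-pair contributions).  ``zwanzig`` uses the
    forward perturbation only; ``os`` and ``bar`` use both directions.
    """
    if len(windows) < 2:
        raise ValueError("need at least two windows")
    per_pair: list[float] = []
    for w_i, w_j in zip(windows, windows[1:]):
        fwd, bwd = neighbor_delta_u(w_i, w_j)
        t = w_i.temperature
        if estimator == "zwanzig":
            per_pair.append(zwanzig(fwd, t))
        elif estimator == "os":
            per_pair.append(overlap_sampling(fwd, bwd, t))
        elif estimator == "bar":
            per_pair.append(bar(fwd, bwd, t))
        else:
            raise ValueError(f"unknown estimator {estimator!r}")
    return sum_windows(per_pair), per_pair


# ---------------------------------------------------------------------------
# Energy-sample CSV dialect
# ---------------------------------------------------------------------------
#
# Columns: lam, sample, u_a, u_b, temperature — one row per sample; windows
# ordered by first appearance.  Engine-independent stand-in for binary
# energy files; a converter from a specific engine is an extension point.

def write_samples_csv(windows: list[WindowSamples], path) -> None:
    frames = []
    for w in windows:
        frames.append(pd.DataFrame({
            "lam": w.lam,
            "sample": np.arange(w.n),
            "u_a": w.u_a,
            "u_b": w.u_b,
            "temperature": w.temperature,
        }))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_samples_csv(path) -> list[WindowSamples]:
    df = pd.read_csv(path)
    required = {"lam", "u_a", "u_b"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: expected columns {sorted(required)}")
    windows = []
    for lam, grp in df.groupby("lam", sort=False):
        t = float(grp["temperature"].iloc[0]) if "temperature" in grp else DEFAULT_TEMPERATURE
        windows.append(WindowSamples(lam=float(lam),
                                     u_a=grp["u_a"].to_numpy(),
                                     u_b=grp["u_b"].to_numpy(),
                                     temperature=t))
    return windows
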