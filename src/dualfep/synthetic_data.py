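"""Synthetic fixtures with analytic ground truth.

Stands in for an MD engine: toy ligand pairs for topology machinery, toy
protein/water droplets for system preparation, and per-window energy
samples whose exact free-energy difference is known in closed form —
Gaussian work distributions (Crooks-consistent, so BAR/OS/Zwanzig all
estimate the same ΔG_true) and a 1-D harmonic-oscillator pair sampled
exactly at every λ window (ΔF = (kT/2)·ln(k_B/k_A)).

Every generator is a pure function of its parameters and seed.  Samples are
drawn independently per window: there is no autocorrelation, which isolates
estimator correctness from sampling dynamics.
"""

from __future__ import annotations

import math

import numpy as np

from .constants import DEFAULT_TEMPERATURE, kT
from .ligand_io import Atom, LigandTopology, ParameterSet
from .free_energy import WindowSamples
from .sphere_prep import (AtomRecord, Residue, SimulationSphere, Structure,
                          solvate_sphere)

__all__ = [
    "gen_toy_ligand_pair",
    "gen_toy_parameters",
    "gen_gaussian_work",
    "gen_harmonic_pair",
    "harmonic_delta_f",
    "gen_toy_system",
]

_ELEMENT_CYCLE = ("C", "N", "O", "C", "S")
_TYPE_FOR_ELEMENT = {"C": "c3", "N": "n3", "O": "oh", "S": "sh", "H": "hc"}

#: atoms emitted per residue name by gen_toy_system
_RESIDUE_ATOMS = {
    "ALA": ["N", "CA", "C", "O", "CB"],
    "SER": ["N", "CA", "C", "O", "CB", "OG"],
    "ASP": ["N", "CA", "C", "O", "CB", "CG", "OD1", "OD2"],
    "GLU": ["N", "CA", "C", "O", "CB", "CG", "CD", "OE1", "OE2"],
    "LYS": ["N", "CA", "C", "O", "CB", "CG", "CD", "CE", "NZ"],
    "ARG": ["N", "CA", "C", "O", "CB", "CG", "CD", "NE", "CZ", "NH1", "NH2"],
    "HIP": ["N", "CA", "C", "O", "CB", "CG", "ND1", "NE2"],
}
_RESIDUE_CYCLE = ("ALA", "ASP", "SER", "LYS", "ALA", "GLU", "ARG", "HIP")


def _chain_coords(n: int, rng: np.random.Generator, origin=(0.0, 0.0, 0.0),
                  step: float = 1.5) -> np.ndarray:
    """Mildly wiggly chain of n points, spaced ~step Å along x."""
    base = np.asarray(origin, dtype=float) + np.outer(np.arange(n), (step, 0.0, 0.0))
    base[:, 1] += 0.3 * np.sin(np.arange(n))
    base[:, 2] += 0.3 * np.cos(np.arange(n))
    return base


def gen_toy_ligand_pair(n_common: int, n_unique_a: int, n_unique_b: int,
                        seed: int = 0) -> tuple[LigandTopology, LigandTopology]:
    """Two superposed toy ligands sharing ``n_common`` near-identical atoms.

    The common core is duplicated between the pair with coordinate jitter
    below 0.05 Å (so the default equivalent-atom pairing cutoff of 0.25 Å
    matches exactly the common atoms); each ligand then grows its own
    substituent chain.  Charges are drawn small and adjusted on the last
    atom so each ligand carries integer net charge 0 (4-decimal values so
    text round-trips are exact).
    """
    if n_common < 1 or n_unique_a < 0 or n_unique_b < 0:
        raise ValueError("need n_common >= 1 and non-negative unique counts")
    rng = np.random.default_rng(seed)
    core = _chain_coords(n_common, rng)
    jitter_a = rng.uniform(-0.02, 0.02, size=core.shape)
    jitter_b = rng.uniform(-0.02, 0.02, size=core.shape)

    def build(tag: str, jitter: np.ndarray, n_unique: int) -> LigandTopology:
        coords = core + jitter
        if n_unique:
            # opposite growth directions: the substituents are the part of
            # the pair that differs, so they must not superpose
            direction = (0.0, 1.5, 0.0) if tag == "A" else (0.0, -1.5, 0.0)
            branch = _chain_coords(n_unique, rng, origin=coords[-1] + direction)
            coords = np.vstack([coords, branch])
        n = len(coords)
        charges = np.round(rng.uniform(-0.2, 0.2, size=n), 4)
        charges[-1] = np.round(-charges[:-1].sum(), 4)
        atoms = []
        for i in range(n):
            elem = _ELEMENT_CYCLE[i % len(_ELEMENT_CYCLE)]
            atoms.append(Atom(name=f"{elem}{i + 1}", element=elem,
                              type_code=_TYPE_FOR_ELEMENT[elem],
                              partial_charge=float(charges[i]),
                              xyz=tuple(float(v) for v in coords[i])))
        bonds = [(i, i + 1) for i in range(n_common - 1)]
        if n_unique:
            bonds.append((n_common - 1, n_common))
            bonds += [(n_common + i, n_common + i + 1) for i in range(n_unique - 1)]
        top = LigandTopology(residue_name=f"LG{tag}", atoms=atoms, bonds=bonds,
                             charge_groups=[list(range(n))])
        from .ligand_io import derive_angles, derive_torsions
        top.angles = derive_angles(bonds)
        top.torsions = derive_torsions(bonds)
        top.check()
        return top

    return build("A", jitter_a, n_unique_a), build("B", jitter_b, n_unique_b)


def gen_toy_parameters(*ligands: LigandTopology) -> ParameterSet:
    """A parameter set resolving every type the given ligands reference."""
    params = ParameterSet()
    masses = {"c3": 12.011, "n3": 14.007, "oh": 15.999, "sh": 32.06, "hc": 1.008}
    lj = {"c3": (0.1094, 1.9080), "n3": (0.1700, 1.8240),
          "oh": (0.2104, 1.7210), "sh": (0.2500, 2.0000), "hc": (0.0157, 1.4870)}
    for lig in ligands:
        for a in lig.atoms:
            if a.type_code in lj:
                params.vdw[a.type_code] = lj[a.type_code]
                params.masses[a.type_code] = masses[a.type_code]
        for i, j in lig.bonds:
            key = ParameterSet.canon((lig.atoms[i].type_code, lig.atoms[j].type_code))
            params.bond_params[key] = (300.0, 1.5)
        for i, j, k in lig.angles:
            key = ParameterSet.canon(tuple(lig.atoms[x].type_code for x in (i, j, k)))
            params.angle_params[key] = (50.0, 109.5)
        for t in lig.torsions:
            key = ParameterSet.canon(tuple(lig.atoms[x].type_code for x in t))
            params.torsion_params[key] = (0.5, 3.0, 0.0)
    return params


# ---------------------------------------------------------------------------
# Energy-sample generators with analytic ground truth
# ---------------------------------------------------------------------------

def gen_gaussian_work(dg_true: float, sigma: float, n: int,
                      temperature: float = DEFAULT_TEMPERATURE,
                      seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Crooks-consistent Gaussian work samples for a single window pair.

    Forward work ~ N(ΔG_true + σ²/2kT, σ²) and reverse work
    ~ N(−ΔG_true + σ²/2kT, σ²), the unique Gaussian pair satisfying the
    Crooks fluctuation theorem; BAR, OS and Zwanzig all estimate ΔG_true.
    σ = 0 degenerates to constant arrays where every estimator is exact.
    """
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    if n < 1:
        raise ValueError("need at least one sample")
    rng = np.random.default_rng(seed)
    shift = sigma ** 2 / (2.0 * kT(temperature))
    du_f = rng.normal(dg_true + shift, sigma, size=n)
    du_r = rng.normal(-dg_true + shift, sigma, size=n)
    return du_f, du_r


def harmonic_delta_f(k_a: float, k_b: float,
                     temperature: float = DEFAULT_TEMPERATURE) -> float:
    """Exact ΔF = (kT/2)·ln(k_B/k_A) between 1-D harmonic wells."""
    return 0.5 * kT(temperature) * math.log(k_b / k_a)


def gen_harmonic_pair(k_a: float, k_b: float, n_windows: int = 51,
                      n: int = 1000, temperature: float = DEFAULT_TEMPERATURE,
                      seed: int = 0, lambdas=None) -> list[WindowSamples]:
    """Exact window samples for perturbing between two 1-D harmonic wells.

    The λ-mixed potential ½[(1−λ)k_A + λk_B]x² is itself harmonic, so each
    window is sampled exactly from N(0, kT/k_λ); U_A and U_B are evaluated
    on the same configurations.  Pushing the result through the
    adjacent-window estimators recovers :func:`harmonic_delta_f`.
    """
    if k_a <= 0 or k_b <= 0:
        raise ValueError("force constants must be positive")
    rng = np.random.default_rng(seed)
    if lambdas is None:
        lambdas = np.linspace(0.0, 1.0, n_windows)
    windows = []
    for lam in lambdas:
        k_mix = (1.0 - lam) * k_a + lam * k_b
        x = rng.normal(0.0, math.sqrt(kT(temperature) / k_mix), size=n)
        windows.append(WindowSamples(lam=float(lam),
                                     u_a=0.5 * k_a * x ** 2,
                                     u_b=0.5 * k_b * x ** 2,
                                     temperature=temperature))
    return windows


# ---------------------------------------------------------------------------
# Toy structures
# ---------------------------------------------------------------------------

def gen_toy_system(n_residues: int, n_waters: int,
                   sphere: SimulationSphere | None = None,
                   seed: int = 0) -> Structure:
    """Synthetic protein-like chain plus water lattice.

    Residue names cycle through a palette that includes the ionizable types
    (ASP/GLU/LYS/ARG/HIP), each with its named charged-group atoms, so the
    neutralization logic can be exercised; per-residue atom counts follow a
    fixed table, making the total atom count a deterministic function of the
    inputs.  Waters are placed by the grid solvator and truncated to
    ``n_waters``.
    """
    if n_residues < 0 or n_waters < 0:
        raise ValueError("counts must be non-negative")
    sphere = sphere or SimulationSphere(center=(0.0, 0.0, 0.0), radius=12.0)
    rng = np.random.default_rng(seed)
    structure = Structure()
    centers = _chain_coords(max(n_residues, 1), rng,
                            origin=np.asarray(sphere.center) - (n_residues * 1.9 / 2, 0, 0),
                            step=3.8)
    for i in range(n_residues):
        name = _RESIDUE_CYCLE[i % len(_RESIDUE_CYCLE)]
        atom_names = _RESIDUE_ATOMS[name]
        local = _chain_coords(len(atom_names), rng, origin=centers[i], step=1.4)
        atoms = [AtomRecord(name=an, element=an[0], xyz=tuple(map(float, local[j])))
                 for j, an in enumerate(atom_names)]
        structure.residues.append(Residue(name=name, resid=i + 1, atoms=atoms))
    if n_waters:
        solvated = solvate_sphere(sphere, structure)
        waters = [r for r in solvated.residues if r.name == "HOH"][:n_waters]
        structure.residues.extend(waters)
    return structure
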