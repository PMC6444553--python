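"""Dual-topology alchemical specification.

Both end-state ligands are present simultaneously with their own
coordinates; in end state A every atom of ligand B is a dummy (zero charge,
zero Lennard-Jones) and vice versa.  Because the total potential is a linear
mix of the two states, the two molecules never interact with each other, and
bond topology may change freely between the pair — the property that makes
scaffold hopping tractable.  Pairs of equivalent (non-dummy) atoms are tied
together with flat-bottom half-harmonic distance restraints so the two
copies track the same pose; since each restrained pair always has one dummy
member at either end state, the restraint term cancels from the free energy
difference and needs no correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .ligand_io import IntegrityError, LigandTopology

__all__ = [
    "RestraintSpec",
    "DualAtom",
    "FepStage",
    "DualTopologySpec",
    "pair_equivalent_atoms",
    "restraint_energy",
    "build_dual_topology",
    "write_fep_file",
    "read_fep_file",
    "swap_states",
]

DUMMY_TYPE = "DUM"

#: softcore depth (kcal/mol) applied to the Lennard-Jones of dummy-state atoms
DEFAULT_SOFTCORE_DEPTH = 20.0

#: maximum atom count the FEP stage-file layout supports
MAX_FEP_ATOMS = 9999


@dataclass(frozen=True)
class RestraintSpec:
    """Flat-bottom half-harmonic distance restraint.

    Zero inside the window ``[lower, upper]`` Å, harmonic with force constant
    ``k`` (kcal/mol/Å²) beyond it.  The conventional factor: the energy is
    ``½·k·(d − upper)²`` past the upper edge (and mirrored below the lower
    edge), continuous and once-differentiable at the boundary.
    """

    force_constant: float = 2.0
    lower: float = 0.0
    upper: float = 0.2

    def __post_init__(self):
        if self.force_constant < 0:
            raise ValueError("force constant must be non-negative")
        if self.lower > self.upper:
            raise ValueError("restraint window lower bound exceeds upper bound")


@dataclass(frozen=True)
class DualAtom:
    """One atom of the merged system, renamed uniquely (Q1..Qn)."""

    name: str
    element: str
    xyz: tuple[float, float, float]
    source: str          # "A" or "B"
    source_name: str     # name in the originating ligand


@dataclass
class FepStage:
    """One FEP file's worth of perturbation: per-atom (initial, final) states."""

    name: str
    charges_initial: list[float]
    charges_final: list[float]
    types_initial: list[str]
    types_final: list[str]
    softcore_initial: list[float]
    softcore_final: list[float]


@dataclass
class DualTopologySpec:
    """Merged A+B system with state-dependent charges/types and restraints.

    ``state_a``/``state_b`` give the (type_code, partial_charge) of every
    atom in the two end states; B-ligand atoms are dummies in state A and
    mirrored for A-ligand atoms in state B.  ``restraint_pairs`` are global
    (A-atom, B-atom) index pairs.
    """

    atoms: list[DualAtom] = field(default_factory=list)
    state_a: list[tuple[str, float]] = field(default_factory=list)
    state_b: list[tuple[str, float]] = field(default_factory=list)
    softcore: list[tuple[float, float]] = field(default_factory=list)
    bonds: list[tuple[int, int]] = field(default_factory=list)
    restraint_pairs: list[tuple[int, int]] = field(default_factory=list)
    restraints: RestraintSpec = field(default_factory=RestraintSpec)
    stages: list[FepStage] = field(default_factory=list)
    residue_name_a: str = "LIGA"
    residue_name_b: str = "LIGB"

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def n_atoms_a(self) -> int:
        return sum(1 for a in self.atoms if a.source == "A")

    @property
    def n_atoms_b(self) -> int:
        return sum(1 for a in self.atoms if a.source == "B")

    @property
    def net_charge_a(self) -> float:
        return float(sum(q for (_, q) in self.state_a))

    @property
    def net_charge_b(self) -> float:
        return float(sum(q for (_, q) in self.state_b))

    @property
    def needs_born_correction(self) -> bool:
        """True when the perturbation changes the net charge of the sphere."""
        return abs(self.net_charge_a - self.net_charge_b) > 1e-3

    def check(self) -> None:
        n = self.n_atoms
        if not (len(self.state_a) == len(self.state_b) == len(self.softcore) == n):
            raise IntegrityError("state/softcore lists out of step with atoms")
        for i, atom in enumerate(self.atoms):
            if atom.source == "B" and self.state_a[i][0] != DUMMY_TYPE:
                raise IntegrityError(f"B atom {atom.name} not dummy in state A")
            if atom.source == "A" and self.state_b[i][0] != DUMMY_TYPE:
                raise IntegrityError(f"A atom {atom.name} not dummy in state B")
        n_a = self.n_atoms_a
        for i, j in self.bonds:
            if (i < n_a) != (j < n_a):
                raise IntegrityError(
                    f"bonded term ({i},{j}) crosses the A/B partition: "
                    "the two molecules must not interact")
        seen: set[int] = set()
        for i, j in self.restraint_pairs:
            if i in seen or j in seen:
                raise IntegrityError(f"atom in more than one restraint pair: ({i},{j})")
            seen.update((i, j))
            if not (self.atoms[i].source == "A" and self.atoms[j].source == "B"):
                raise IntegrityError(
                    f"restraint pair ({i},{j}) must connect an A atom to a B atom")


# ---------------------------------------------------------------------------
# Atom pairing
# ---------------------------------------------------------------------------

def pair_equivalent_atoms(lig_a: LigandTopology, lig_b: LigandTopology,
                          cutoff: float = 0.25,
                          require_element_match: bool = True,
                          ) -> list[tuple[int, int]]:
    """Greedy nearest-distance matching of equivalent atoms.

    Both ligands must be superposed in the same frame (docked or crystal
    poses).  Candidate pairs are sorted by ascending inter-atom distance
    (ties broken by index) and accepted iff the distance is within *cutoff*
    Å, elements match when the flag is set, and neither atom is already
    paired.  Returns (index_in_A, index_in_B) pairs; an empty result is
    legal (the perturbation is simply unrestrained) and warned about by the
    builder.
    """
    xa = np.asarray([a.xyz for a in lig_a.atoms], dtype=float)
    xb = np.asarray([b.xyz for b in lig_b.atoms], dtype=float)
    if len(xa) == 0 or len(xb) == 0:
        return []
    d = np.linalg.norm(xa[:, None, :] - xb[None, :, :], axis=2)
    candidates = sorted(
        ((d[i, j], i, j) for i in range(len(xa)) for j in range(len(xb))
         if d[i, j] <= cutoff
         and (not require_element_match
              or lig_a.atoms[i].element.upper() == lig_b.atoms[j].element.upper())),
        key=lambda t: (t[0], t[1], t[2]))
    used_a: set[int] = set()
    used_b: set[int] = set()
    pairs: list[tuple[int, int]] = []
    for _, i, j in candidates:
        if i in used_a or j in used_b:
            continue
        pairs.append((i, j))
        used_a.add(i)
        used_b.add(j)
    return pairs


def restraint_energy(distance: float, spec: RestraintSpec = RestraintSpec()) -> float:
    """Flat-bottom half-harmonic restraint energy (kcal/mol) at *distance* Å."""
    if distance < 0:
        raise ValueError("distance must be non-negative")
    if distance > spec.upper:
        return 0.5 * spec.force_constant * (distance - spec.upper) ** 2
    if distance < spec.lower:
        return 0.5 * spec.force_constant * (spec.lower - distance) ** 2
    return 0.0


# ---------------------------------------------------------------------------
# Building the merged spec
# ---------------------------------------------------------------------------

def build_dual_topology(lig_a: LigandTopology, lig_b: LigandTopology,
                        restraints: RestraintSpec | None = None,
                        stage_scheme: str = "single",
                        pair_cutoff: float = 0.25,
                        require_element_match: bool = True,
                        ) -> DualTopologySpec:
    """Merge two ligands into one dual-topology FEP specification.

    Atoms are concatenated A-then-B and renamed Q1..Qn for uniqueness (the
    source names are retained for bookkeeping).  Each ligand keeps its own
    bonded terms in both states — dummies stay internally intact — and no
    bonded term ever crosses the A/B partition.  ``stage_scheme`` is either
    ``"single"`` (one stage; charges and vdW interpolate together, softcore
    on the dummy-state Lennard-Jones of both ligands) or ``"three_stage"``
    (discharge A, swap vdW under softcore, charge B).
    """
    restraints = restraints or RestraintSpec()
    n_total = len(lig_a.atoms) + len(lig_b.atoms)
    if n_total > MAX_FEP_ATOMS:
        raise ValueError(
            f"combined atom count {n_total} exceeds FEP file limit {MAX_FEP_ATOMS}")
    if stage_scheme not in ("single", "three_stage"):
        raise ValueError(f"unknown stage scheme {stage_scheme!r}")

    spec = DualTopologySpec(restraints=restraints,
                            residue_name_a=lig_a.residue_name,
                            residue_name_b=lig_b.residue_name)
    for src, lig in (("A", lig_a), ("B", lig_b)):
        for atom in lig.atoms:
            idx = len(spec.atoms) + 1
            spec.atoms.append(DualAtom(name=f"Q{idx}", element=atom.element,
                                       xyz=atom.xyz, source=src,
                                       source_name=atom.name))
            real = (atom.type_code, atom.partial_charge)
            dummy = (DUMMY_TYPE, 0.0)
            if src == "A":
                spec.state_a.append(real)
                spec.state_b.append(dummy)
                spec.softcore.append((0.0, DEFAULT_SOFTCORE_DEPTH))
            else:
                spec.state_a.append(dummy)
                spec.state_b.append(real)
                spec.softcore.append((DEFAULT_SOFTCORE_DEPTH, 0.0))

    offset = len(lig_a.atoms)
    # each ligand keeps its own bonded terms in both states (dummies stay
    # internally intact); nothing bridges the two molecules
    spec.bonds = sorted(
        [tuple(sorted(b)) for b in lig_a.bonds]
        + [(i + offset, j + offset) for i, j in (tuple(sorted(b)) for b in lig_b.bonds)])
    raw_pairs = pair_equivalent_atoms(lig_a, lig_b, cutoff=pair_cutoff,
                                      require_element_match=require_element_match)
    if not raw_pairs:
        import warnings
        warnings.warn("no equivalent-atom pairs found within cutoff; "
                      "perturbation will run unrestrained", stacklevel=2)
    spec.restraint_pairs = sorted((i, offset + j) for i, j in raw_pairs)
    spec.stages = _make_stages(spec, stage_scheme)
    spec.check()
    return spec


def _make_stages(spec: DualTopologySpec, scheme: str) -> list[FepStage]:
    qa = [q for (_, q) in spec.state_a]
    qb = [q for (_, q) in spec.state_b]
    ta = [t for (t, _) in spec.state_a]
    tb = [t for (t, _) in spec.state_b]
    sa = [s for (s, _) in spec.softcore]
    sb = [s for (_, s) in spec.softcore]
    zeros = [0.0] * spec.n_atoms
    if scheme == "single":
        return [FepStage("full", qa, qb, ta, tb, sa, sb)]
    return [
        FepStage("discharge_A", qa, zeros, ta, ta, zeros, zeros),
        FepStage("vdw_swap", zeros, zeros, ta, tb, sa, sb),
        FepStage("charge_B", zeros, qb, tb, tb, zeros, zeros),
    ]


def swap_states(spec: DualTopologySpec) -> DualTopologySpec:
    """Relabel A<->B: reorder atoms B-block-first, swap end states.

    ``build_dual_topology(A, B)`` equals
    ``swap_states(build_dual_topology(B, A))`` up to the regenerated stage
    list — the builder's state-symmetry invariant.
    """
    n_a = spec.n_atoms_a
    order = list(range(n_a, spec.n_atoms)) + list(range(n_a))
    remap = {old: new for new, old in enumerate(order)}
    out = DualTopologySpec(restraints=spec.restraints,
                           residue_name_a=spec.residue_name_b,
                           residue_name_b=spec.residue_name_a)
    for new_idx, old in enumerate(order):
        a = spec.atoms[old]
        out.atoms.append(DualAtom(name=f"Q{new_idx + 1}", element=a.element,
                                  xyz=a.xyz,
                                  source="A" if a.source == "B" else "B",
                                  source_name=a.source_name))
        out.state_a.append(spec.state_b[old])
        out.state_b.append(spec.state_a[old])
        out.softcore.append((spec.softcore[old][1], spec.softcore[old][0]))
    out.bonds = sorted(tuple(sorted((remap[i], remap[j]))) for i, j in spec.bonds)
    out.restraint_pairs = sorted((remap[j], remap[i]) for i, j in spec.restraint_pairs)
    out.stages = _make_stages(out, "single" if len(spec.stages) == 1 else "three_stage")
    out.check()
    return out


# ---------------------------------------------------------------------------
# FEP stage-file I/O (Q dialect)
# ---------------------------------------------------------------------------

def write_fep_file(spec: DualTopologySpec, path) -> str:
    """Emit the dual-topology FEP specification as a Q-dialect stage file.

    All stages are written to the one file as repeated ``[stage]`` blocks;
    the global sections carry atom identities, end-state charge and type
    pairs, softcore depths and restraint pairs.  The file parses back to an
    equal spec via :func:`read_fep_file`.
    """
    spec.check()
    for i, j in spec.restraint_pairs:
        if not (0 <= i < spec.n_atoms and 0 <= j < spec.n_atoms):
            raise IntegrityError(f"restraint pair ({i},{j}) out of range")
    path = str(path)
    with open(path, "w") as fh:
        fh.write("[FEP]\n")
        fh.write(f"residues {spec.residue_name_a} {spec.residue_name_b}\n")
        fh.write(f"restraint_k {spec.restraints.force_constant}\n")
        fh.write(f"restraint_window {spec.restraints.lower} {spec.restraints.upper}\n")
        fh.write("[atoms]\n")
        for idx, a in enumerate(spec.atoms, start=1):
            x, y, z = a.xyz
            fh.write(f"{idx:5d} {a.name:<6s} {a.element:<2s} {a.source} "
                     f"{a.source_name:<6s} {x:10.4f} {y:10.4f} {z:10.4f}\n")
        fh.write("[change_charges]\n")
        for idx in range(spec.n_atoms):
            fh.write(f"{idx + 1:5d} {spec.state_a[idx][1]: .4f} {spec.state_b[idx][1]: .4f}\n")
        fh.write("[change_atoms]\n")
        for idx in range(spec.n_atoms):
            fh.write(f"{idx + 1:5d} {spec.state_a[idx][0]:<8s} {spec.state_b[idx][0]:<8s}\n")
        fh.write("[softcore]\n")
        for idx, (s1, s2) in enumerate(spec.softcore, start=1):
            fh.write(f"{idx:5d} {s1:8.2f} {s2:8.2f}\n")
        fh.write("[bonds]\n")
        for i, j in spec.bonds:
            fh.write(f"{i + 1:5d} {j + 1:5d}\n")
        fh.write("[distance_restraints]\n")
        for i, j in spec.restraint_pairs:
            fh.write(f"{i + 1:5d} {j + 1:5d} {spec.restraints.force_constant:6.2f} "
                     f"{spec.restraints.lower:6.2f} {spec.restraints.upper:6.2f}\n")
        for stage in spec.stages:
            fh.write(f"[stage {stage.name}]\n")
            for idx in range(spec.n_atoms):
                fh.write(f"{idx + 1:5d} {stage.charges_initial[idx]: .4f} "
                         f"{stage.charges_final[idx]: .4f} "
                         f"{stage.types_initial[idx]:<8s} {stage.types_final[idx]:<8s} "
                         f"{stage.softcore_initial[idx]:8.2f} {stage.softcore_final[idx]:8.2f}\n")
    return path


def read_fep_file(path) -> DualTopologySpec:
    """Parse a Q-dialect FEP stage file back into a :class:`DualTopologySpec`."""
    from .ligand_io import _iter_sections

    spec = DualTopologySpec()
    k, lower, upper = 2.0, 0.0, 0.2
    charges: list[tuple[float, float]] = []
    types: list[tuple[str, str]] = []
    for section, lines in _iter_sections(path):
        if section == "fep":
            for _, line in lines:
                parts = line.split()
                if parts[0] == "residues":
                    spec.residue_name_a, spec.residue_name_b = parts[1], parts[2]
                elif parts[0] == "restraint_k":
                    k = float(parts[1])
                elif parts[0] == "restraint_window":
                    lower, upper = float(parts[1]), float(parts[2])
        elif section == "atoms":
            for _, line in lines:
                p = line.split()
                spec.atoms.append(DualAtom(name=p[1], element=p[2], source=p[3],
                                           source_name=p[4],
                                           xyz=(float(p[5]), float(p[6]), float(p[7]))))
        elif section == "change_charges":
            charges = [(float(p[1]), float(p[2]))
                       for p in (line.split() for _, line in lines)]
        elif section == "change_atoms":
            types = [(p[1], p[2]) for p in (line.split() for _, line in lines)]
        elif section == "softcore":
            spec.softcore = [(float(p[1]), float(p[2]))
                             for p in (line.split() for _, line in lines)]
        elif section == "bonds":
            spec.bonds = [(int(p[0]) - 1, int(p[1]) - 1)
                          for p in (line.split() for _, line in lines)]
        elif section == "distance_restraints":
            for _, line in lines:
                p = line.split()
                i, j = int(p[0]) - 1, int(p[1]) - 1
                spec.restraint_pairs.append((i, j))
        elif section.startswith("stage"):
            name = section.split(None, 1)[1]
            ci, cf, ti, tf, si, sf = [], [], [], [], [], []
            for _, line in lines:
                p = line.split()
                ci.append(float(p[1]))
                cf.append(float(p[2]))
                ti.append(p[3])
                tf.append(p[4])
                si.append(float(p[5]))
                sf.append(float(p[6]))
            spec.stages.append(FepStage(name, ci, cf, ti, tf, si, sf))
    if len(charges) != len(spec.atoms) or len(types) != len(spec.atoms):
        raise IntegrityError(f"{path}: charge/type tables out of step with [atoms]")
    spec.restraints = RestraintSpec(force_constant=k, lower=lower, upper=upper)
    spec.state_a = [(types[i][0], charges[i][0]) for i in range(len(spec.atoms))]
    spec.state_b = [(types[i][1], charges[i][1]) for i in range(len(spec.atoms))]
    spec.check()
    return spec
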