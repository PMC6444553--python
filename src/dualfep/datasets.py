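"""Bundled benchmark tables.

Three published benchmark sets widely used to validate relative free-energy
methods, stored as printed (kcal/mol, two decimals):

* side-chain hydration — relative hydration free energies of 23 amino-acid
  side-chain analogs against methane, in three perturbation schemes
  (annihilation X→Me, growth Me→X, and the midpoint λ=0.5 scheme), with the
  per-row hysteresis between the two directions;
* CDK2 — absolute-scaled binding free energies of 16 kinase inhibitors in a
  radial design around a reference ligand, for several force fields;
* A2A — ΔΔG_bind of 8 adenosine-receptor antagonist analogs relative to a
  parent compound;
* Chk1 — ΔΔG_bind of 6 scaffold-hopping perturbations between kinase
  inhibitors with different core ring systems.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .stats_report import BenchmarkTable

__all__ = [
    "load_sidechain_hydration",
    "sidechain_table",
    "load_cdk2",
    "cdk2_table",
    "load_a2a",
    "a2a_table",
    "load_chk1",
    "chk1_table",
]


def _read(name: str) -> pd.DataFrame:
    with resources.files("dualfep.data").joinpath(name).open() as fh:
        return pd.read_csv(fh)


def load_sidechain_hydration() -> pd.DataFrame:
    """Raw side-chain hydration table (all schemes, SEMs, hysteresis)."""
    return _read("sidechain_hydration.csv")


def sidechain_table(scheme: str = "x_to_me", subset: str = "all") -> BenchmarkTable:
    """Benchmark view of one perturbation scheme.

    *scheme* is ``x_to_me``, ``me_to_x``, ``average`` or ``midpoint``;
    *subset* is ``all``, ``neutral`` or ``charged``.  The creation-direction
    column is sign-flipped so every scheme estimates the same annihilation
    ΔΔG.
    """
    df = load_sidechain_hydration()
    if subset == "neutral":
        df = df[df["charged"] == 0]
    elif subset == "charged":
        df = df[df["charged"] == 1]
    elif subset != "all":
        raise ValueError(f"unknown subset {subset!r}")
    calc = df[scheme]
    if scheme == "me_to_x":
        calc = -calc
    return BenchmarkTable(pd.DataFrame({
        "ligand": df["mimic"],
        "experimental": df["experimental"],
        "calculated": calc,
        "sem": df.get(f"{scheme}_sem"),
    }).reset_index(drop=True))


def load_cdk2() -> pd.DataFrame:
    return _read("cdk2_binding.csv")


def cdk2_table(column: str = "opls2005") -> BenchmarkTable:
    """CDK2 binding benchmark for one method column.

    Columns: ``opls2005``, ``amber``, ``charmm`` (this workflow) or
    ``fepplus_opls2005``/``fepplus_opls3``.  The reference ligand row keeps
    an empty calculated value and can be counted as a zero-deviation anchor
    by :func:`dualfep.stats_report.mae`.
    """
    df = load_cdk2()
    return BenchmarkTable(pd.DataFrame({
        "ligand": df["ligand"].astype(str),
        "experimental": df["experimental"],
        "calculated": df[column],
        "sem": df.get(f"{column}_sem"),
    }), reference_ligand="1h1q")


def load_a2a() -> pd.DataFrame:
    return _read("a2a_binding.csv")


def a2a_table(column: str = "ddg") -> BenchmarkTable:
    df = load_a2a()
    return BenchmarkTable(pd.DataFrame({
        "ligand": df["ligand"].astype(str),
        "experimental": df["experimental"],
        "calculated": df[column],
        "sem": df.get(f"{column}_sem"),
    }), reference_ligand="11")


def load_chk1() -> pd.DataFrame:
    return _read("chk1_scaffold_hopping.csv")


def chk1_table(column: str = "ddg") -> BenchmarkTable:
    df = load_chk1()
    return BenchmarkTable(pd.DataFrame({
        "ligand": df["ligand"],
        "experimental": df["experimental"],
        "calculated": df[column],
        "sem": df.get(f"{column}_sem"),
    }))
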