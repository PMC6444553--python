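"""Estimate ΔG from per-window energy samples with known ground truth.

Two fixtures: Crooks-consistent Gaussian work for a single window pair,
and a 51-window perturbation between two 1-D harmonic wells whose exact
answer is ΔF = (kT/2)·ln(k_B/k_A).
"""

from dualfep import bar, leg_free_energy, overlap_sampling, zwanzig
from dualfep.free_energy import combine_replicates
from dualfep.synthetic_data import (gen_gaussian_work, gen_harmonic_pair,
                                    harmonic_delta_f)

dg_true = 1.0
f, r = gen_gaussian_work(dg_true, sigma=1.0, n=5000, seed=1)
print(f"Gaussian work fixture (ΔG_true = {dg_true:+.4f} kcal/mol, n = 5000):")
print(f"  Zwanzig (forward): {zwanzig(f):+.4f}")
print(f"  overlap sampling:  {overlap_sampling(f, r):+.4f}")
print(f"  BAR:               {bar(f, r):+.4f}")

k_a, k_b = 1.0, 4.0
dgs = [leg_free_energy(gen_harmonic_pair(k_a, k_b, n_windows=51, n=10_000,
                                         seed=s))[0] for s in range(4)]
mean, sem = combine_replicates(dgs)
print(f"harmonic pair k_A={k_a}, k_B={k_b} (51 windows × 10⁴ samples, "
      "4 replicates):")
print(f"  pipeline ΔG = {mean:+.4f} ± {sem:.4f} kcal/mol")
print(f"  exact    ΔF = {harmonic_delta_f(k_a, k_b):+.4f} kcal/mol")
# The BAR estimate should sit within a few SEM of the closed form; the
# deviation shrinks as samples per window grow.
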