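"""Plan a perturbation: λ schedule, replicate deck, time accounting.

Uses the default protocol (10 replicates, 131 ps equilibration, 51 linear
windows × 10 ps) but writes a small 2-replicate, 5-window deck to keep the
example quick.
"""

from dualfep import (ProtocolPlan, build_dual_topology, make_lambda_schedule,
                     total_sampling_time, write_md_inputs)
from dualfep.synthetic_data import gen_toy_ligand_pair

default_plan = ProtocolPlan()
default_schedule = make_lambda_schedule(51, "linear", start=1.0)
per_leg, per_pert = total_sampling_time(default_plan, default_schedule)
print(f"default protocol: {default_plan.replicates} replicates × "
      f"({default_plan.equilibration_ps:.0f} ps equilibration + "
      f"{default_schedule.n_windows} × {default_plan.production_ps:.0f} ps)")
print(f"  = {per_leg:.2f} ns per leg, {per_pert:.2f} ns per perturbation")

spec = build_dual_topology(*gen_toy_ligand_pair(5, 2, 2, seed=1))
plan = ProtocolPlan(replicates=2)
schedule = make_lambda_schedule(5, "linear", start=0.5)
files = write_md_inputs(plan, schedule, spec, "deck_example", master_seed=42)
print(f"midpoint-start schedule branches: "
      f"{[br[:3] for br in schedule.branches]} ...")
print(f"wrote {len(files)} MD input files under deck_example/ "
      "(two branch directories per replicate)")
# Each replicate directory carries its own deterministic velocity seed, so
# regenerating the deck with the same master seed is byte-identical.
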