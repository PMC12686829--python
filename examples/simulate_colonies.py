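"""Simulate one HCT recipient's colony dataset with ground truth.

Ten single-HSPC colonies at hematopoietic age 20 y, five of them belonging
to a driver clone acquired 3.0 y after conception; writes the multi-sample
VCF, per-colony callable BEDs and the truth bundle.
"""

from hsctrace import SimulationParams, simulate_dataset
from hsctrace.simulate import write_truth

params = SimulationParams(
    n_colonies=10, hsc_age=20.0, driver_time=3.0, clone_size=5, seed=7
)
truth, obs = simulate_dataset(params)
obs.write("example_output/simulate")
write_truth(truth, "example_output/simulate")

mrca = truth.tree.find(truth.driver_branch)
print(f"colonies:          {sorted(truth.tree.tip_names())}")
print(f"driver clone:      {truth.clone_tips} (MRCA split at "
      f"{mrca.time:.2f} y since conception)")
print(f"true mutations:    {len(truth.mutations)}")
print(f"VCF records:       {obs.table.n_sites} "
      "(somatic + germline + low-VAF artifacts + low-quality sites)")
print("callable fraction: "
      + ", ".join(f"{s}={f:.2f}" for s, f in sorted(obs.callable_fraction.items())))
# The extra VCF records beyond the true somatic mutations are the material
# the downstream filters must remove; the truth bundle records which is which.
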