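"""Simulate a 10-AP, 20-Hz train for each genotype and compare phenotypes.

Runs the full release-site model (WT), the Doc2α knockout (k2+ = 0), the
syt7 knockout (f7 = 1) and the double knockout, then prints the headline
per-train metrics. Expect: identical first peaks, much weaker first-AP
asynchronous release without Doc2α, collapsed transient docking without
syt7, and depression ordered syt7-KO < WT < Doc2α-KO.
"""

import vesikin as vk

params = vk.default_parameters()
print(f"{'genotype':>9} {'peak1 (ves/s)':>14} {'AR after AP1':>13} "
      f"{'docking 5-15ms':>15} {'peak10/peak1':>13} {'AR total':>9}")
for genotype in vk.GENOTYPES:
    traj = vk.simulate(params, genotype=genotype)
    m = vk.per_stimulus_metrics(traj)
    row = m.table.iloc[0]
    print(f"{genotype:>9} {row.peak_rate:14.0f} {row.async_count:13.2f} "
          f"{row.dock_flux_5_15ms:15.1f} {m.depression_ratio:13.3f} "
          f"{m.ar_total:9.1f}")

print(
    "\npeak1: peak release rate after the first AP (equal across genotypes);\n"
    "AR after AP1: vesicles released 5-50 ms after the first AP;\n"
    "docking 5-15ms: vesicles docking in the transient-docking window after AP1\n"
    "(near zero without syt7); peak10/peak1: depression ratio; AR total:\n"
    "cumulative asynchronous release over the whole train (vesicles)."
)
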