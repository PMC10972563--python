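"""One-at-a-time sensitivity of the train metrics to the Doc2α fusion factor.

Rescales f2 (the per-ion boost Doc2α gives the fusion rate) from one-tenth
to tenfold around its canonical value of 16, re-simulating a shortened
5-AP train for each multiplier, and tabulates the headline metrics.
Asynchronous release grows monotonically with f2; the canonical value sits
where removing Doc2α entirely leaves the first peak unchanged while AR is
roughly halved.
"""

import dataclasses

import vesikin as vk
from vesikin.params import Protocol

params = dataclasses.replace(
    vk.default_parameters(), protocol=Protocol(n_aps=5, freq=20.0)
)
table = vk.parameter_sweep(params, ["f_2"], multipliers=[0.1, 0.3, 1.0, 3.0, 10.0])
wide = table.pivot(index="multiplier", columns="metric", values="value")
print(wide[["ar_total", "peak_rate_ap1", "depression_ratio"]].round(3).to_string())
print(
    "\nar_total: cumulative asynchronous release (vesicles) over the 5-AP"
    "\ntrain; peak_rate_ap1: first-AP peak release rate (vesicles/s);"
    "\ndepression_ratio: last/first peak-rate ratio."
)
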