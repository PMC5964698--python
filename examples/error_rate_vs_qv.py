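"""Check that the injected error rate tracks quality values.

The simulator's defining feature is that a base's error probability follows
its QV through the empirical model P_error(q) = 0.3942*10^(-q/10) + 0.0041
(rescaled to hit the configured average).  This script simulates reads,
bins every aligned column by its QV, and prints observed vs model rates.
"""

from npbss import CountSpec, ErrorConfig, error_rate_by_qv, load_qv_table, simulate
from npbss.synthetic import random_genome

refs = random_genome(500_000, seed=11)
cfg = ErrorConfig().calibrated_against(load_qv_table())
reads = list(
    simulate(
        refs,
        CountSpec(mode="explicit_n", n=400, mean_len=8500),
        error_config=cfg,
        seed=2,
    )
)
frame = error_rate_by_qv(reads, error_config=cfg, min_bases_per_bin=2000)
print(frame.to_string(index=False))
print(
    "\nEach row is one integer QV: observed_error_rate (fraction of "
    "non-match columns at that QV) should match model_error_rate (the "
    "calibrated empirical curve) within binomial noise, decreasing toward "
    "the 0.0041 floor as QV grows."
)
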