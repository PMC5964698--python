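"""Generate CCS-like reads by resampling donor (length, QV) profiles.

CCS reads are short and highly accurate; their joint length/quality
structure is easiest to reproduce by bootstrap: donor reads are drawn with
replacement from a CCS FASTQ and errors injected at the Phred-defined
probability 10^(-qv/10) of each donor QV.  Here the donor set is a
synthetic high-accuracy stand-in produced by the CLR engine itself.
"""

import numpy as np

from npbss import extract_profiles, length_quality_scatter, simulate_ccs, summarize_rates, write_fastq
from npbss.synthetic import pseudo_ccs_fastq, random_genome

pseudo_ccs_fastq("ccs_donors.fq", n_reads=200, seed=5)
refs = random_genome(200_000, seed=7)
rng = np.random.default_rng(1)
profiles = extract_profiles("ccs_donors.fq", rng, 300)
reads = list(simulate_ccs(refs, profiles, rng))
write_fastq(reads, "ccs_simulated.fq")

s = summarize_rates(reads)
scatter = length_quality_scatter(reads)
print(s.to_frame().to_string(index=False))
print(scatter.describe().loc[["mean", "std", "min", "max"]])
print(
    "\nTotal error should be well under 1% (donor QVs are 20-40), and the "
    "length/mean-QV scatter bootstraps the donor set's distribution."
)
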