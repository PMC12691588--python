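"""Estimate inversion frequency from junction-spanning whole-genome reads.

Reads covering a full inverted repeat with flanking bases on both sides are
diagnostic for the locus orientation; counting them estimates the fraction
of a mixed population carrying the inversion.
"""

from invertiscan import inversion_rate_from_junction_reads
from invertiscan.simulate import make_reference_loci, simulate_junction_reads

locus = make_reference_loci(seed=21, n_loci=1)[0]
reads = simulate_junction_reads(
    seed=22, locus=locus, fraction_inverted=0.195, n_reads=5_000, read_len=150,
)
res = inversion_rate_from_junction_reads(reads.reads, locus)
print(f"forward reads:  {res.n_forward}")
print(f"inverted reads: {res.n_inverted}")
print(f"discarded (both/neither): {res.n_both}/{res.n_neither}")
print(f"fraction inverted: {res.fraction_inverted:.4f} "
      f"(95% CI {res.ci_low:.4f}-{res.ci_high:.4f})")
print(f"planted fraction:  {reads.truth['planted_fraction_inverted']}")
# On error-free reads each read is assigned unambiguously, so the estimate
# equals the realized binomial draw of the planted 19.5% inversion rate.
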