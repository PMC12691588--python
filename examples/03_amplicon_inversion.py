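"""Estimate inversion frequency from an orientation-typing amplicon assay.

Two strains' amplicons (each in both orientation states) form the labeled
reference set; 20,000 mixed-population reads with substitution error are
collapsed to ASVs, classified at a 97% identity floor, and pooled into
per-strain inversion fractions with exact binomial confidence intervals.
"""

from invertiscan import AmpliconReferenceSet, inversion_rate_from_asv_table
from invertiscan.simulate import make_reference_loci, simulate_amplicon_reads

refs = AmpliconReferenceSet.from_loci({
    "strainA": make_reference_loci(seed=11, n_loci=1, anchor_len=100)[0],
    "strainB": make_reference_loci(seed=12, n_loci=1, anchor_len=100)[0],
})
amp = simulate_amplicon_reads(
    seed=13, refs=refs,
    fraction_inverted={"strainA": 0.05, "strainB": 0.20},
    n_reads=20_000, substitution_error=0.001,
)
result = inversion_rate_from_asv_table(amp.asvs, refs)
cols = ["strain_id", "n_forward", "n_inverted", "fraction_inverted", "ci_low", "ci_high"]
print(result.frequencies[cols].to_string(index=False))
print()
print(result.sample_summary.to_string(index=False))
# fraction_inverted estimates the planted per-strain rates (0.05 and 0.20);
# the audit row shows that classified + ambiguous + unclassified reads
# account for every input read.
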