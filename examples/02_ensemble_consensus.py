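"""k-of-n voting across somatic callers with variant-key normalization.

Three toy callers disagree on representation (one reports a padded indel);
normalization makes the votes land on the same key, and k=2 keeps only
variants seen by at least two callers.
"""

from oncocohort import (
    ChromTable,
    VcfSite,
    caller_result_from_sites,
    consensus_to_vcf,
    vote,
    write_vcf_sites,
)

chroms = ChromTable((("chr1", 1_000_000),))

# caller A: SNV at 100, padded deletion at 500 (CAG>CG == CA>C after trim)
a = [
    VcfSite(chrom="chr1", pos=100, ref="A", alt="T", filter="PASS"),
    VcfSite(chrom="chr1", pos=500, ref="CAG", alt="CG", filter="PASS"),
]
# caller B: same deletion in minimal form, plus a private call
b = [
    VcfSite(chrom="chr1", pos=500, ref="CA", alt="C", filter="PASS"),
    VcfSite(chrom="chr1", pos=900, ref="G", alt="C", filter="PASS"),
]
# caller C: the SNV again, plus a call its own FILTER rejected
c = [
    VcfSite(chrom="chr1", pos=100, ref="A", alt="T", filter="PASS"),
    VcfSite(chrom="chr1", pos=700, ref="T", alt="A", filter="LowQual"),
]

results = [
    caller_result_from_sites(name, sites)
    for name, sites in [("strelka", a), ("mutationseq", b), ("radia", c)]
]
for r in results:
    print(f"{r.caller_name}: {len(r.variants)} PASS call(s)")

consensus = vote(results, k=2, chrom_order=chroms)
print(f"\nk=2 consensus keeps {len(consensus)} variant(s):")
for v in consensus:
    print(f"  {v.key.chrom}:{v.key.pos} {v.key.ref}>{v.key.alt} "
          f"supported by {sorted(v.supporters)}")

print("\nannotated VCF:")
print(write_vcf_sites(consensus_to_vcf(consensus, chroms)), end="")
print("The padded and minimal deletion spellings voted as one key; the")
print("LowQual record and single-caller private calls were dropped.")
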