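"""Genotype a T2 population from two-PCR results and test segregation.

Loads the bundled 19-plant, three-locus screen (PCR A = T-DNA anchored,
PCR B = T-DNA flanking), calls each plant heterozygous (+/+), homozygous
(+/-), wildtype null (-/+) or indeterminate (-/-), and summarises each
locus against the 2:1:1 expectation for selfed progeny of a hemizygote.
"""

from importlib import resources

from tdnawalk.zygosity import (
    read_genotype_sheet,
    stacking_homozygosity_prob,
    summarize_segregation,
)

sheet = resources.files("tdnawalk") / "data" / "example_t2_zygosity.tsv"
by_locus = {}
for r in read_genotype_sheet(sheet):
    by_locus.setdefault(r.locus_id, []).append(r)

for locus, results in sorted(by_locus.items()):
    s = summarize_segregation(results)
    print(f"{locus}: het={s.counts['heterozygous']} hmz={s.counts['homozygous']} "
          f"null={s.counts['wildtype_null']}  "
          f"(carriers: {s.pct_of_carriers['heterozygous']}% het / "
          f"{s.pct_of_carriers['homozygous']}% hmz)  "
          f"chi2={s.chi_square:.2f} p={s.p_value:.3f}"
          f"{'  ** non-Mendelian' if s.non_mendelian else ''}")

print("\nexpected homozygosity among selfed T2 progeny:")
for k in (1, 2, 3):
    print(f"  {k} independent hemizygous locus/loci -> {stacking_homozygosity_prob(k)}%")
# A locus with zero homozygotes at non-trivial n (chi-square p < 0.05) is
# flagged: the signature of a homozygous-lethal insertion or a mis-primed
# flanking PCR.
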