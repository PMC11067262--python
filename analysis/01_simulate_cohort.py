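"""Generate the synthetic MHC cohort every later stage analyses.

Draws a reference pool of labelled haplotypes (2 genes x 4 alleles,
tagging strength 0.95), a cohort of 1,000 subjects by random union of
haplotypes, an amino-acid table, and phenotypes with planted HLA effects
(one binary, one quantitative, one null trait).
"""

from common import run_through

manifest = run_through("simulate")
ctx = manifest["_context"]
pool, typing, pheno = ctx["pool"], ctx["typing"], ctx["phenotypes"]

print(f"simulated {manifest['config']['n_subjects']} subjects, "
      f"{ctx['genotypes'].n_variants} SNPs across genes {pool.genes}")
for gene in pool.genes:
    alleles = pool.gene_alleles(gene)
    print(f"  {gene}: {len(alleles)} alleles, most common {alleles[0]}")
print(f"planted effects: {ctx['planted']}")
print(f"case fraction of 'disease': {pheno['disease'].mean():.3f}")
print(f"outputs: {sorted(manifest['stages']['simulate']['outputs'])}")
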