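"""Build the unified PheWAS variant catalogue.

SNVs/indels from the QCed region, HLA-allele dosages from the imputed
calls, amino-acid residue variants and multiallelic positions from the
translation table; then post-imputation QC (missing rate > 0.05 or
MAF < 0.01 for HLA-derived biallelic variants; missing rate only for
multiallelic positions) and LD-based gene assignment at r^2 >= 0.7.
"""

from common import run_through

manifest = run_through("encode")
cat = manifest["_context"]["catalogue"]
counts = cat.counts()

print("catalogue composition after post-imputation QC:")
for cls, n in counts.items():
    print(f"  {cls}: {n}")
print(f"  total test variants: {cat.total()}")
tagged = (cat.biallelic["gene"] != "-").sum()
print(f"variants carrying a gene tag (own or LD r^2 >= 0.7): {tagged}")
for pos in cat.multiallelic:
    print(f"  omnibus position {pos.id}: residues {pos.residues} "
          f"(df = {pos.n_residues - 1})")
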