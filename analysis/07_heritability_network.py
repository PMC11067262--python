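"""Region-wide heritability and the genetic-correlation network.

A GRM over all catalogue variants feeds univariate Haseman-Elston
regression per quantitative trait and bivariate HE for every pair;
pairs surviving Benjamini-Hochberg FDR at 0.05 become network edges.
"""

from common import run_through

manifest = run_through("heritability")
ests = manifest["_context"]["heritability"]

print("HLA-region-wide heritability (Haseman-Elston):")
for e in ests:
    print(f"  {e.trait}: h2 = {e.h2_percent} (SE {100 * e.se:.2f}%)")
n_edges = manifest["stages"]["heritability"]["n_edges"]
print(f"genetic-correlation network edges after FDR: {n_edges}")
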