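"""Scan every catalogue variant against every trait.

Binary traits use additive logistic regression (Firth fallback on
separation), quantitative traits use inverse-normal-transformed
covariate residuals in OLS, and each multiallelic amino-acid position
gets the omnibus likelihood-ratio test (chi-square, df = residues - 1).
Genome-wide significance is p < 5e-8.
"""

from common import run_through

manifest = run_through("phewas")
ctx = manifest["_context"]
assoc, omni = ctx["assoc"], ctx["omni"]

n_positions = (omni.groupby(["gene", "position"]).ngroups if len(omni) else 0)
print(f"tested {assoc['variant_id'].nunique()} biallelic variants x "
      f"{assoc['trait'].nunique()} traits "
      f"({len(assoc)} associations), plus {n_positions} omnibus positions")
print(f"genome-wide significant associations: {int(assoc['gws'].sum())}")
for trait, grp in assoc[assoc["gws"]].groupby("trait"):
    top = grp.sort_values("p").iloc[0]
    effect = (f"OR {top['or_']:.2f}" if top["trait_type"] == "binary"
              else f"beta {top['effect']:.3f}")
    print(f"  {trait}: top signal {top['variant_id']} "
          f"({effect}, p = {top['p']:.2e})")
if len(omni):
    best = omni.sort_values("p").iloc[0]
    print(f"strongest omnibus signal: {best['gene']} pos {best['position']} "
          f"for {best['trait']} (df {best['df']}, p = {best['p']:.2e})")
print(f"planted truth: {ctx['planted']}")
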