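"""Multilocus HLA haplotype frequencies from the imputed calls by EM.

Uses called subjects only; genes inserted progressively with pruning.
Compares the estimated distribution against the generating pool.
"""

from hla_phenoscope.haplotypes import top_haplotypes

from common import run_through

manifest = run_through("haplotypes")
ctx = manifest["_context"]
table = ctx["haplotype_table"]
pool = ctx["pool"]

print(f"EM over {table.n_subjects} fully-called subjects, "
      f"{len(table.frequencies)} haplotypes retained "
      f"({table.iterations} iterations, logL {table.log_likelihood:.1f})")
print("top five haplotypes:")
print(top_haplotypes(table, 5).to_string(index=False))

truth: dict = {}
for row in pool.hap_alleles:
    truth[tuple(row)] = truth.get(tuple(row), 0.0) + 1 / len(pool.hap_alleles)
top_truth = max(truth, key=truth.get)
print(f"generating-pool top haplotype: {'-'.join(top_truth)} "
      f"at {100 * truth[top_truth]:.2f}%")
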