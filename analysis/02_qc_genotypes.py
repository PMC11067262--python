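"""Pre-analysis QC: MHC extraction, then variant and sample filters.

Variant filters: call rate >= 0.98, MAF >= 0.05, HWE exact p >= 1e-6.
Sample filters: call rate, heterozygosity outliers (+-3 SD), IBD
PI_HAT > 0.1875 (skipped here: too few variants for a stable estimate).
"""

import pandas as pd

from common import OUT_DIR, run_through

manifest = run_through("qc")
vrep = pd.read_csv(f"{OUT_DIR}/variant_qc.tsv", sep="\t")
srep = pd.read_csv(f"{OUT_DIR}/sample_qc.tsv", sep="\t")

print(f"variants: {len(vrep)} in, "
      f"{(vrep['status'] == 'pass').sum()} pass "
      f"({(vrep['status'] == 'fail').sum()} fail: "
      f"{vrep.loc[vrep['status'] == 'fail', 'reason'].value_counts().to_dict()})")
print(f"samples: {len(srep)} in, {(srep['status'] == 'pass').sum()} pass")
print(f"MAF range of passing variants: "
      f"{vrep.loc[vrep['status'] == 'pass', 'maf'].min():.3f}"
      f"-{vrep.loc[vrep['status'] == 'pass', 'maf'].max():.3f}")
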