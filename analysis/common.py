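"""Shared configuration for the numbered analysis drivers.

Every driver reruns the deterministic pipeline through the stages it
needs (same seed, bit-identical upstream results) and reports its own
stage's findings, writing tables under results/analysis/.
"""

from hla_phenoscope.pipeline import STAGES, RunConfig, run

OUT_DIR = "results/analysis"
SEED = 17


def config(through: str) -> RunConfig:
    stages = STAGES[: STAGES.index(through) + 1]
    return RunConfig(out_dir=OUT_DIR, seed=SEED, stages=stages,
                     n_subjects=1000, n_classifiers=12,
                     alleles_per_gene=4, n_snps=40)


def run_through(stage: str) -> dict:
    return run(config(stage))
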