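"""Shared plumbing for the numbered analysis scripts.

Each script is runnable from the repository root and is independent: if the
simulated cohort tables are already under results/cohort/ they are read
back through the package's I/O layer, otherwise the cohort is regenerated
deterministically (seed 1, the published areas and burdens).
"""

from __future__ import annotations

from pathlib import Path

RESULTS = Path("results")
COHORT_DIR = RESULTS / "cohort"
DEFAULT_SEED = 1


def load_or_generate_cohort(seed: int = DEFAULT_SEED):
    from epiclone.core_io import (
        read_donor_table,
        read_mutation_table,
        read_sample_table,
    )
    from epiclone.synthetic_cohort import CohortConfig, generate_cohort

    mut_p = COHORT_DIR / "mutations.tsv"
    if mut_p.exists():
        donors = read_donor_table(COHORT_DIR / "donors.tsv")
        samples = read_sample_table(COHORT_DIR / "samples.tsv")
        records = read_mutation_table(mut_p)
        return donors, samples, records, None
    return generate_cohort(CohortConfig(seed=seed))


def ensure_outdir(sub: str = "") -> Path:
    p = RESULTS / sub if sub else RESULTS
    p.mkdir(parents=True, exist_ok=True)
    return p
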