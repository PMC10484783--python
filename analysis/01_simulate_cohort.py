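"""Simulate the grid-sampled cohort at the published areas and burdens.

Writes the three cohort tables plus ground-truth summaries under
results/cohort/. Five Singaporean donors (aging-dominant spectrum, sparse
clones) and six UK donors (UV-dominant spectrum, dense clones, TP53
hotspot spikes, more CNA) — 428 two-mm^2 samples in total.
"""

import argparse
import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).parent))
from common import DEFAULT_SEED, ensure_outdir

from epiclone.core_io import (
    germline_filter,
    write_donor_table,
    write_mutation_table,
    write_sample_table,
)
from epiclone.synthetic_cohort import CohortConfig, generate_cohort


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=DEFAULT_SEED)
    args = ap.parse_args()

    donors, samples, records, truth = generate_cohort(CohortConfig(seed=args.seed))
    kept, removed = germline_filter(records, samples)

    out = ensure_outdir("cohort")
    write_donor_table(donors, out / "donors.tsv")
    write_sample_table(samples, out / "samples.tsv")
    write_mutation_table(kept, out / "mutations.tsv")

    truth_rows = [
        {
            "clone_id": tc.clone_id,
            "donor_id": tc.donor_id,
            "piece_id": tc.piece_id,
            "gene": tc.gene or "",
            "consequence": tc.consequence,
            "area_mm2": tc.area_mm2,
            "n_samples": len(tc.sample_vafs),
            "parent_id": tc.parent_id or "",
            "is_driver": tc.is_driver,
            "is_hotspot": tc.is_hotspot,
        }
        for tc in truth.clones
    ]
    pd.DataFrame(truth_rows).to_csv(out / "true_clones.tsv", sep="\t", index=False)
    pd.DataFrame(
        [{"donor_id": k, "true_burden_per_mb": v} for k, v in truth.burden.items()]
    ).to_csv(out / "true_burden.tsv", sep="\t", index=False)

    n_sg = sum(s.donor_id.startswith("SG") for s in samples)
    print(f"cohort: {len(donors)} donors, {len(samples)} samples ({n_sg} SG)")
    print(f"mutation records: {len(kept)} kept, {len(removed)} removed as germline")
    print(f"true clones: {len(truth.clones)}; CNA samples: {len(truth.cna_samples)}")
    print(f"written to {out}/")


if __name__ == "__main__":
    main()
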