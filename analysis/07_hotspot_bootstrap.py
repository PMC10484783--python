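"""TP53 R248/R282 hotspot depletion: rule of three and scaled bootstrap.

Measures the per-sample mutation strata of the UK-like cohort (spiked at
the published hotspot rates), thins by the proportions measured against
the Singaporean cohort, and asks how many hotspot mutations the 191
Singaporean samples should have shown if their mutational landscape were
just a scaled-down UK one.
"""

import argparse
import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).parent))
from common import DEFAULT_SEED, ensure_outdir, load_or_generate_cohort

from epiclone.hotspot_bootstrap import (
    HotspotSpec,
    bootstrap_hotspot,
    measure_proportions,
    measure_strata,
    rule_of_three,
)


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=DEFAULT_SEED)
    ap.add_argument("--n-sims", type=int, default=1000)
    args = ap.parse_args()

    donors, samples, records, _ = load_or_generate_cohort()
    uk = measure_strata(
        [r for r in records if r.donor_id.startswith("UK")],
        [s for s in samples if s.donor_id.startswith("UK")],
    )
    sg_samples = [s for s in samples if s.donor_id.startswith("SG")]
    sg = measure_strata(
        [r for r in records if r.donor_id.startswith("SG")], sg_samples
    )
    p_all, p_ct, p_gene = measure_proportions(uk, sg)
    print(
        f"thinning proportions (SG/UK): all={p_all:.3f}, C>T|all={p_ct:.3f}, "
        f"TP53|C>T={p_gene:.3f}"
    )
    n_sg = len(sg_samples)
    spec = HotspotSpec(
        n_target_samples=n_sg,
        proportion_all=p_all,
        proportion_ct=p_ct,
        proportion_gene=p_gene,
        n_sims=args.n_sims,
        seed=args.seed,
    )
    res = bootstrap_hotspot(uk, spec)
    out = ensure_outdir()
    pd.DataFrame({"replicate_count": res.replicate_counts}).to_csv(
        out / "hotspot_bootstrap.tsv", sep="\t", index=False
    )
    print(f"rule of three bound for n={n_sg}: {rule_of_three(n_sg):.4f}")
    print(
        f"expected hotspot mutations in {n_sg} target samples: "
        f"{res.expected_count:.2f} (observed in the low-burden cohort: 0)"
    )
    print(
        f"replicates with zero hotspot events: {res.zero_fraction:.3f}; "
        f"replicates whose implied zero-event probability falls below the "
        f"bound: {res.p:.3f}"
    )


if __name__ == "__main__":
    main()
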