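"""Simplified dN/dS selection per gene and the between-country test.

Fits neutral per-channel rates from all SBS, flags genes with an excess of
non-synonymous mutations (BH q < 0.01), and tests which genes split their
non-synonymous counts between countries differently from the global ratio
(one-sided LRT, Holm-adjusted).
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).parent))
from common import ensure_outdir, load_or_generate_cohort

from epiclone.panel import default_panel
from epiclone.selection_dnds import (
    country_differential,
    global_nonsyn_ratio,
    panel_selection,
)


def main() -> None:
    donors, samples, records, _ = load_or_generate_cohort()
    panel = default_panel()

    results = panel_selection(records, panel)
    out = ensure_outdir()
    pd.DataFrame([vars(r) for r in results]).to_csv(
        out / "selection.tsv", sep="\t", index=False
    )
    selected = sorted((r.gene for r in results if r.q < 0.01))
    print(f"positively selected genes (q < 0.01): {', '.join(selected)}")

    by_country = {
        c: [r for r in records if r.donor_id.startswith(c)] for c in ("UK", "SG")
    }
    g = global_nonsyn_ratio(by_country)
    print(f"global UK/SG non-synonymous ratio = {g:.2f}")
    diff = country_differential(by_country, panel.gene_names, global_ratio=g)
    rows = [{"gene": k, **v} for k, v in diff.items()]
    pd.DataFrame(rows).to_csv(out / "country_differential.tsv", sep="\t", index=False)
    for gene, d in diff.items():
        if min(d["p_over_adj"], d["p_under_adj"]) < 0.001:
            side = "over" if d["p_over_adj"] < d["p_under_adj"] else "under"
            print(
                f"  {gene}: {side}-represented in UK "
                f"(p_adj = {min(d['p_over_adj'], d['p_under_adj']):.2g})"
            )


if __name__ == "__main__":
    main()
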