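"""Per-donor 96-channel catalogs, NNLS signature refitting and clustering.

Reports each donor's UV (SBS7a-d) exposure, the DBS CC>TT share and
transcriptional strand bias, and bootstrap support for the country split
in exposure space.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).parent))
from common import ensure_outdir, load_or_generate_cohort

from epiclone.burden_tissue import burden_uv_correlation, estimate_burden
from epiclone.panel import default_panel
from epiclone.signature_fit import (
    build_catalog,
    cluster_exposures,
    dbs_and_strand_summary,
    fit_exposures,
    packaged_reference_signatures,
    uv_fraction,
)
from epiclone.synthetic_cohort import DEFAULT_SIGNATURE_WEIGHTS


def main() -> None:
    donors, samples, records, _ = load_or_generate_cohort()
    reference = packaged_reference_signatures()

    catalogs, exposures = {}, {}
    for d in donors:
        recs = [r for r in records if r.donor_id == d.donor_id]
        cat = build_catalog(recs, d.donor_id)
        if not cat.usable:
            print(f"  {d.donor_id}: only {cat.n_mutations} SBS, excluded")
            continue
        catalogs[d.donor_id] = cat
        exposures[d.donor_id] = fit_exposures(cat, reference)

    out = ensure_outdir()
    rows = []
    for donor_id, exp in exposures.items():
        row = {"donor_id": donor_id, "n_sbs": exp.n_mutations,
               "uv_fraction": uv_fraction(exp)}
        row.update(exp.weights)
        rows.append(row)
    df = pd.DataFrame(rows).sort_values("donor_id")
    df.to_csv(out / "exposures.tsv", sep="\t", index=False)
    for country in ("UK", "SG"):
        sub = df[df.donor_id.str.startswith(country)]
        print(f"{country}: mean UV (SBS7a-d) exposure = {sub.uv_fraction.mean():.2f}")

    s = dbs_and_strand_summary(records)
    print(f"DBS: {s.n_dbs} total, CC>TT share = {s.cc_tt_fraction:.2f}")
    if s.strand_ratio is not None:
        print(f"C>T dipyrimidine strand ratio (tx/untx) = {s.strand_ratio:.1f}")

    res = cluster_exposures(catalogs, reference, n_boot=1000, seed=0)
    uk = frozenset(k for k in catalogs if k.startswith("UK"))
    sg = frozenset(k for k in catalogs if k.startswith("SG"))
    for side, name in ((uk, "UK"), (sg, "SG")):
        if side in res.support:
            print(f"bootstrap support for the {name} cluster: {res.support[side]:.3f}")

    # burden vs UV correlation
    panel = default_panel()
    est = {}
    for country in ("UK", "SG"):
        spectrum = reference.mixture_spectrum(DEFAULT_SIGNATURE_WEIGHTS[country])
        for e in estimate_burden(
            [r for r in records if r.donor_id.startswith(country)],
            [smp for smp in samples if smp.donor_id.startswith(country)],
            panel, spectrum,
        ):
            est[e.donor_id] = e.mutations_per_mb
    uv = dict(zip(df.donor_id, df.uv_fraction))
    corr = burden_uv_correlation(est, uv)
    print(
        f"burden vs UV exposure: Pearson r = {corr['pearson_r']:.2f}, "
        f"Spearman rho = {corr['spearman_rho']:.2f}"
    )


if __name__ == "__main__":
    main()
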