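"""Genome-wide burden from synonymous variants and percent-mutant-tissue bounds.

The targeted genes are cancer-associated, so their non-synonymous mutation
density is inflated by selection; synonymous variants are effectively
neutral passengers, and their density estimates the genome-wide rate. In
diploid tissue 2*VAF is the fraction of cells carrying a variant, so the
summed 2*VAF over synonymous calls in a sample estimates the expected
per-cell synonymous mutation count in the bait. Dividing by the synonymous
footprint L_syn = exonic footprint x f_syn gives mutations per cell per Mb;
f_syn is the spectrum-weighted fraction of possible coding changes that are
synonymous, which depends on the mutational spectrum (a UV-skewed spectrum
changes the synonymous opportunity). Samples with detected copy-number
aberrations are excluded, since 2*VAF no longer equals the cell fraction
there.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core_io import NONSYNONYMOUS, DonorMeta, MutationRecord, SampleInfo
from .panel import PanelDef

log = logging.getLogger(__name__)


@dataclass
class BurdenEstimate:
    donor_id: str
    mutations_per_mb: float | None
    n_syn_used: int
    samples_excluded_cna: int


@dataclass
class MutantTissueEstimate:
    donor_id: str
    gene: str  # gene name or "any"
    upper_pct: float
    lower_pct: float


def estimate_burden(
    records: list[MutationRecord],
    samples: list[SampleInfo],
    panel: PanelDef,
    spectrum: np.ndarray,
) -> list[BurdenEstimate]:
    """Per-donor genome-wide burden (mutations per cell per Mb).

    Per sample: sum(2*VAF) over synonymous SBS divided by the synonymous
    footprint; the donor estimate is the area-weighted mean over its
    CNA-free samples. A donor whose samples are all CNA-excluded gets a
    null estimate.
    """
    l_syn = panel.synonymous_footprint_mb(spectrum)
    syn_sum: dict[str, float] = {}
    syn_n: dict[str, int] = {}
    for r in records:
        if r.mut_class == "SBS" and r.consequence == "synonymous":
            syn_sum[r.sample_id] = syn_sum.get(r.sample_id, 0.0) + 2.0 * r.vaf
            syn_n[r.sample_id] = syn_n.get(r.sample_id, 0) + 1

    by_donor: dict[str, list[SampleInfo]] = {}
    for s in samples:
        by_donor.setdefault(s.donor_id, []).append(s)

    out = []
    for donor_id in sorted(by_donor):
        usable = [s for s in by_donor[donor_id] if not s.cna_excluded]
        n_excl = len(by_donor[donor_id]) - len(usable)
        if not usable:
            out.append(BurdenEstimate(donor_id, None, 0, n_excl))
            continue
        weights = np.array([s.area_mm2 for s in usable])
        per_sample = np.array(
            [syn_sum.get(s.sample_id, 0.0) / l_syn for s in usable]
        )
        est = float(per_sample @ weights / weights.sum())
        n_used = sum(syn_n.get(s.sample_id, 0) for s in usable)
        out.append(BurdenEstimate(donor_id, est if n_used else 0.0, n_used, n_excl))
    return out


def percent_mutant(
    records: list[MutationRecord],
    samples: list[SampleInfo],
    gene_filter: str = "any",
) -> list[MutantTissueEstimate]:
    """Bounds on the percentage of cells with >=1 non-synonymous mutation.

    Upper bound per sample: min(100, sum of per-mutation cell fractions),
    assuming mutations occupy different cells where possible. Lower bound:
    the largest single cell fraction, assuming co-occurrence in the same
    cells. Donor values are area-weighted means over CNA-free samples.
    ``gene_filter`` restricts to one gene, or "any" for all panel genes.
    """
    upper: dict[str, float] = {}
    lower: dict[str, float] = {}
    for r in records:
        if r.consequence not in NONSYNONYMOUS:
            continue
        if gene_filter != "any" and r.gene != gene_filter:
            continue
        cell_pct = min(100.0, 2.0 * r.vaf * 100.0)
        upper[r.sample_id] = upper.get(r.sample_id, 0.0) + cell_pct
        lower[r.sample_id] = max(lower.get(r.sample_id, 0.0), cell_pct)

    by_donor: dict[str, list[SampleInfo]] = {}
    for s in samples:
        by_donor.setdefault(s.donor_id, []).append(s)
    out = []
    for donor_id in sorted(by_donor):
        usable = [s for s in by_donor[donor_id] if not s.cna_excluded]
        if not usable:
            out.append(MutantTissueEstimate(donor_id, gene_filter, 0.0, 0.0))
            continue
        w = np.array([s.area_mm2 for s in usable])
        up = np.array([min(100.0, upper.get(s.sample_id, 0.0)) for s in usable])
        lo = np.array([lower.get(s.sample_id, 0.0) for s in usable])
        out.append(
            MutantTissueEstimate(
                donor_id=donor_id,
                gene=gene_filter,
                upper_pct=float(up @ w / w.sum()),
                lower_pct=float(lo @ w / w.sum()),
            )
        )
    return out


# ---------------------------------------------------------------------------
# routine country comparisons

@dataclass
class ComparisonResult:
    test: str
    p: float | None
    statistic: float | None
    group_means: dict[str, float]
    warning: str | None = None


def country_compare(
    values: dict[str, float],
    donors: list[DonorMeta],
    test: str = "t",
) -> ComparisonResult:
    """Compare a per-donor quantity between countries.

    ``test`` is "t" (two-sided Welch) or "wilcoxon" (two-sided rank-sum;
    the groups are unpaired so the rank-sum form of the Wilcoxon test is
    used). Degenerate groups (fewer than two donors, or zero variance in
    both) give a null p with a warning.
    """
    country = {d.donor_id: d.country for d in donors}
    groups: dict[str, list[float]] = {}
    for donor_id, v in values.items():
        if v is None:
            continue
        groups.setdefault(country[donor_id], []).append(v)
    if len(groups) != 2:
        raise ValueError(f"expected two countries, got {sorted(groups)}")
    (ga, va), (gb, vb) = sorted(groups.items())
    means = {ga: float(np.mean(va)), gb: float(np.mean(vb))}
    if len(va) < 2 or len(vb) < 2:
        warnings.warn("degenerate group (<2 donors); p undefined")
        return ComparisonResult(test, None, None, means, "degenerate group")
    if np.var(va) == 0 and np.var(vb) == 0 and np.mean(va) == np.mean(vb):
        return ComparisonResult(test, 1.0, 0.0, means, "identical groups")
    if test == "t":
        res = stats.ttest_ind(va, vb, equal_var=False)
    elif test == "wilcoxon":
        res = stats.mannwhitneyu(va, vb, alternative="two-sided")
    else:
        raise ValueError(f"unknown test {test!r}")
    return ComparisonResult(test, float(res.pvalue), float(res.statistic), means)


def per_gene_country_compare(
    per_gene_values: dict[str, dict[str, float]],
    donors: list[DonorMeta],
    test: str = "wilcoxon",
) -> dict[str, dict]:
    """Per-gene country comparison with Holm correction across genes."""
    genes = sorted(per_gene_values)
    raw = {}
    for g in genes:
        raw[g] = country_compare(per_gene_values[g], donors, test=test)
    testable = [g for g in genes if raw[g].p is not None]
    if testable:
        adj = multipletests([raw[g].p for g in testable], method="holm")[1]
        p_adj = dict(zip(testable, adj))
    else:
        p_adj = {}
    return {
        g: {"p": raw[g].p, "p_adj": p_adj.get(g), "group_means": raw[g].group_means}
        for g in genes
    }


def burden_uv_correlation(
    burden: dict[str, float],
    uv: dict[str, float],
) -> dict[str, float]:
    """Pearson and Spearman correlation of per-donor burden vs UV fraction."""
    ids = sorted(set(burden) & set(uv))
    x = np.array([burden[i] for i in ids])
    y = np.array([uv[i] for i in ids])
    if np.allclose(x, x[0]) or np.allclose(y, y[0]):
        warnings.warn("constant input; correlations undefined")
        return {"pearson_r": float("nan"), "spearman_rho": float("nan")}
    return {
        "pearson_r": float(stats.pearsonr(x, y).statistic),
        "spearman_rho": float(stats.spearmanr(x, y).statistic),
    }
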