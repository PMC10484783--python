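"""Allelic-imbalance detection from heterozygous-SNP read counts.

Targeted read depth varies too much across baits for depth-based copy
number, so only events producing allelic imbalance (LOH and gains) are
detectable. All samples of a donor are pooled as a panel to identify
heterozygous SNPs (pooled depth >= 1000x, pooled alt fraction within
[0.3, 0.7]); per sample and locus, each het SNP is assigned a phase sign so
deviations from 0.5 align (maximising the summed signed deviation, which
makes the statistic invariant to ref/alt labelling), and the pooled phased
counts are tested against 0.5 with a binomial test. Calls require BH
q < 0.01 and a mean phased deviation of at least 0.1; the deviation floor
suppresses tiny-clone noise that the fold-to-major-allele step would
otherwise convert into false calls.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)

MIN_POOLED_DEPTH = 1000
HET_WINDOW = (0.3, 0.7)
DEVIATION_FLOOR = 0.1
Q_THRESHOLD = 0.01

SNP_COLUMNS = ["donor_id", "sample_id", "snp_id", "locus", "ref_reads", "alt_reads"]


@dataclass
class ImbalanceCall:
    donor_id: str
    sample_id: str
    locus: str
    phased_fraction: float
    n_snps: int
    p: float
    q: float | None
    event: str  # "LOH", "gain", "imbalance_unclassified" or "none"


def read_snp_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in SNP_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    if (df[["ref_reads", "alt_reads"]] < 0).any().any():
        raise ValueError(f"{path}: negative read counts")
    return df


def find_het_snps(snp_counts: pd.DataFrame) -> set[tuple[str, str]]:
    """Heterozygous SNPs per donor, pooling reads over all the donor's samples.

    Returns the set of (donor_id, snp_id) with pooled depth >= 1000 and
    pooled alt fraction in [0.3, 0.7].
    """
    pooled = snp_counts.groupby(["donor_id", "snp_id"])[["ref_reads", "alt_reads"]].sum()
    depth = pooled["ref_reads"] + pooled["alt_reads"]
    frac = pooled["alt_reads"] / depth.where(depth > 0)
    ok = (depth >= MIN_POOLED_DEPTH) & frac.between(*HET_WINDOW)
    return set(pooled.index[ok])


def call_imbalance(
    snp_counts: pd.DataFrame,
    het_snps: set[tuple[str, str]] | None = None,
    q_threshold: float = Q_THRESHOLD,
    deviation_floor: float = DEVIATION_FLOOR,
) -> list[ImbalanceCall]:
    """Per sample x locus allelic-imbalance calls.

    Loci with fewer than two het SNPs in a sample are skipped (logged).
    Phasing is greedy per sample: each SNP's major-allele side is taken,
    which maximises the summed signed deviation from 0.5. Event sub-typing
    is heuristic: a single-copy gain cannot push the phased fraction much
    above 2/3 even at full clonality and observed gains are subclonal, so
    strong shifts (phased fraction >= 0.62) are classed LOH, milder
    significant shifts as gain; shifts right at the boundary where neither
    reading is compelling are labelled "imbalance_unclassified".
    """
    if het_snps is None:
        het_snps = find_het_snps(snp_counts)
    df = snp_counts[
        [
            (d, s) in het_snps
            for d, s in zip(snp_counts["donor_id"], snp_counts["snp_id"])
        ]
    ]
    calls: list[ImbalanceCall] = []
    skipped = 0
    for (donor, sample, locus), grp in df.groupby(
        ["donor_id", "sample_id", "locus"], sort=True
    ):
        if len(grp) < 2:
            skipped += 1
            continue
        major = grp[["ref_reads", "alt_reads"]].max(axis=1).sum()
        total = int(grp["ref_reads"].sum() + grp["alt_reads"].sum())
        if total == 0:
            skipped += 1
            continue
        phased = major / total
        res = stats.binomtest(int(major), total, 0.5, alternative="two-sided")
        calls.append(
            ImbalanceCall(
                donor_id=donor,
                sample_id=sample,
                locus=locus,
                phased_fraction=float(phased),
                n_snps=len(grp),
                p=float(res.pvalue),
                q=None,
                event="none",
            )
        )
    if skipped:
        log.info("skipped %d sample-locus pairs with <2 het SNPs", skipped)
    if not calls:
        return calls
    qs = multipletests([c.p for c in calls], method="fdr_bh")[1]
    for c, q in zip(calls, qs):
        c.q = float(q)
        deviation = c.phased_fraction - 0.5
        if c.q < q_threshold and deviation >= deviation_floor:
            if c.phased_fraction >= 0.62:
                c.event = "LOH"
            elif c.phased_fraction <= 0.60:
                c.event = "gain"
            else:
                c.event = "imbalance_unclassified"
    return calls


def excluded_samples(calls: list[ImbalanceCall]) -> set[str]:
    """Samples with any imbalance event, for exclusion from burden and
    percent-mutant estimation."""
    return {c.sample_id for c in calls if c.event != "none"}
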