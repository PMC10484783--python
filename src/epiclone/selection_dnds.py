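"""Simplified dN/dS selection inference and the between-country test.

Neutral per-channel mutation rates are fitted from all observed SBS over
the panel's per-channel opportunity (assuming the vast majority of
mutations are passengers). Expected synonymous and non-synonymous counts
per gene follow from the gene's codon models times the rates; selection is
quantified by omega = (obsN/expN)/(obsS/expS) with a Poisson likelihood
ratio test of omega = 1 and Benjamini-Hochberg correction across genes.
This is a deliberate simplification of full dNdScv (96 channels instead of
the 192-parameter strand-symmetric model with covariates), appropriate for
panel-sized data; q-values will not numerically match dNdScv's.

The between-country test asks whether a gene's non-synonymous mutation
count splits between cohorts differently from the global split: under the
null the gene's UK count is Binomial(n, g/(1+g)) where g is the global
UK:SG non-synonymous ratio, tested by one-sided likelihood ratio in each
direction with Holm correction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core_io import MutationRecord
from .panel import MIS, NON, SYN, PanelDef
from .contexts import channel_of

log = logging.getLogger(__name__)

#: consequence classes pooled as "non-synonymous" for selection inference
_NONSYN_SBS = {"missense", "nonsense", "essential_splice"}


@dataclass
class SelectionResult:
    gene: str
    obs_syn: int
    obs_mis: int
    obs_non: int  # nonsense + essential splice
    exp_syn: float
    exp_mis: float
    exp_non: float
    omega_mis: float
    omega_non: float
    omega: float  # pooled non-synonymous omega
    p: float
    q: float | None = None
    syn_pseudocount_used: bool = False


def fit_neutral_model(
    records: list[MutationRecord],
    panel: PanelDef,
) -> np.ndarray:
    """Maximum-likelihood per-channel rates from all panel SBS.

    Under a Poisson model with per-channel opportunity ``o_c`` and count
    ``n_c``, the MLE rate is ``n_c / o_c`` (mutations per available site
    change). Channels with zero opportunity get rate 0 and are effectively
    excluded. Rates scale linearly with total burden.
    """
    counts = np.zeros(96, dtype=float)
    for r in records:
        if r.mut_class == "SBS" and r.context is not None and r.gene in panel.gene_index:
            counts[channel_of(r.context)] += 1
    opp = panel.channel_opportunity().astype(float)
    rates = np.zeros(96)
    ok = opp > 0
    rates[ok] = counts[ok] / opp[ok]
    if np.any(~ok):
        log.info("%d channels without opportunity excluded", int((~ok).sum()))
    return rates


def _gene_observed(records: list[MutationRecord], gene: str) -> tuple[int, int, int]:
    s = m = n = 0
    for r in records:
        if r.gene != gene or r.mut_class != "SBS":
            continue
        if r.consequence == "synonymous":
            s += 1
        elif r.consequence == "missense":
            m += 1
        elif r.consequence in ("nonsense", "essential_splice"):
            n += 1
    return s, m, n


def _poisson_lrt(obs_n: float, exp_n: float, obs_s: float, exp_s: float) -> float:
    """LRT p-value for H0: common rate factor for N and S (omega = 1)."""
    if exp_n <= 0 or exp_s <= 0:
        return 1.0

    def ll(obs, mean):
        if mean <= 0:
            return 0.0 if obs == 0 else -np.inf
        return obs * np.log(mean) - mean

    # H1: separate scalings for N and S (saturated in the two totals)
    l1 = ll(obs_n, obs_n) + ll(obs_s, obs_s)
    # H0: shared scaling mu = (obs_n + obs_s) / (exp_n + exp_s)
    mu = (obs_n + obs_s) / (exp_n + exp_s)
    l0 = ll(obs_n, mu * exp_n) + ll(obs_s, mu * exp_s)
    lrt = max(0.0, 2.0 * (l1 - l0))
    return float(stats.chi2.sf(lrt, df=1))


def gene_dnds(
    records: list[MutationRecord],
    gene: str,
    rates: np.ndarray,
    panel: PanelDef,
) -> SelectionResult:
    """Observed/expected selection ratios for one gene.

    When the gene has zero observed synonymous mutations, 0.5 is added to
    the synonymous count (flagged) so omega stays finite.
    """
    if gene not in panel.gene_index:
        raise ValueError(f"gene {gene!r} not in panel")
    gi = panel.gene_index[gene]
    opp = panel.gene_opportunity[gi].astype(float)  # (96, 3)
    exp_syn = float(rates @ opp[:, SYN])
    exp_mis = float(rates @ opp[:, MIS])
    exp_non = float(rates @ opp[:, NON])
    obs_s, obs_m, obs_n = _gene_observed(records, gene)

    s_eff = float(obs_s)
    pseudo = False
    if obs_s == 0:
        s_eff = 0.5
        pseudo = True
    rate_s = s_eff / exp_syn if exp_syn > 0 else np.nan
    omega_mis = (obs_m / exp_mis) / rate_s if exp_mis > 0 and rate_s > 0 else np.nan
    omega_non = (obs_n / exp_non) / rate_s if exp_non > 0 and rate_s > 0 else np.nan
    exp_nonsyn = exp_mis + exp_non
    obs_nonsyn = obs_m + obs_n
    omega = (obs_nonsyn / exp_nonsyn) / rate_s if exp_nonsyn > 0 and rate_s > 0 else np.nan
    p = _poisson_lrt(obs_nonsyn, exp_nonsyn, s_eff, exp_syn)
    return SelectionResult(
        gene=gene,
        obs_syn=obs_s,
        obs_mis=obs_m,
        obs_non=obs_n,
        exp_syn=exp_syn,
        exp_mis=exp_mis,
        exp_non=exp_non,
        omega_mis=float(omega_mis),
        omega_non=float(omega_non),
        omega=float(omega),
        p=p,
        syn_pseudocount_used=pseudo,
    )


def panel_selection(
    records: list[MutationRecord],
    panel: PanelDef,
    rates: np.ndarray | None = None,
) -> list[SelectionResult]:
    """Per-gene selection across the whole panel with BH q-values."""
    if rates is None:
        rates = fit_neutral_model(records, panel)
    results = [gene_dnds(records, g, rates, panel) for g in panel.gene_names]
    qs = multipletests([r.p for r in results], method="fdr_bh")[1]
    for r, q in zip(results, qs):
        r.q = float(max(q, r.p))  # q >= p invariant
    return results


# ---------------------------------------------------------------------------
# between-country differential selection

def global_nonsyn_ratio(
    records_by_country: dict[str, list[MutationRecord]],
    numerator: str = "UK",
    denominator: str = "SG",
) -> float:
    """Cohort-wide ratio of non-synonymous mutation totals (e.g. UK/SG)."""
    totals = {}
    for c, recs in records_by_country.items():
        totals[c] = sum(1 for r in recs if r.consequence in _NONSYN_SBS)
    if totals.get(denominator, 0) == 0:
        raise ValueError(f"no non-synonymous mutations in {denominator}")
    return totals[numerator] / totals[denominator]


def country_differential(
    records_by_country: dict[str, list[MutationRecord]],
    genes: list[str],
    global_ratio: float | None = None,
    numerator: str = "UK",
    denominator: str = "SG",
) -> dict[str, dict]:
    """Per-gene one-sided LRTs for country-specific selection.

    Under H0 a gene's non-synonymous counts split between the cohorts at
    the global ratio g, i.e. the numerator-country count is Binomial(n,
    g/(1+g)). The one-sided LRT statistic is the signed deviance; Holm
    correction is applied across genes separately in each direction.
    Genes with zero counts in both cohorts get p = 1.
    """
    if global_ratio is None:
        global_ratio = global_nonsyn_ratio(records_by_country, numerator, denominator)
    p0 = global_ratio / (1.0 + global_ratio)

    def gene_counts(c: str, gene: str) -> int:
        return sum(
            1
            for r in records_by_country.get(c, [])
            if r.gene == gene and r.consequence in _NONSYN_SBS
        )

    out: dict[str, dict] = {}
    for gene in genes:
        k = gene_counts(numerator, gene)
        n = k + gene_counts(denominator, gene)
        if n == 0:
            out[gene] = {
                "n": 0, "k_num": 0, "p_over": 1.0, "p_under": 1.0,
                "direction": "none",
            }
            continue
        phat = k / n
        ll_alt = stats.binom.logpmf(k, n, phat) if 0 < phat < 1 else stats.binom.logpmf(k, n, max(min(phat, 1 - 1e-12), 1e-12))
        ll_null = stats.binom.logpmf(k, n, p0)
        lrt = max(0.0, 2.0 * (ll_alt - ll_null))
        p_two = float(stats.chi2.sf(lrt, df=1))
        if phat > p0:
            p_over, p_under = p_two / 2.0, 1.0 - p_two / 2.0
        elif phat < p0:
            p_over, p_under = 1.0 - p_two / 2.0, p_two / 2.0
        else:
            p_over = p_under = 0.5
        out[gene] = {
            "n": n,
            "k_num": k,
            "p_over": p_over,
            "p_under": p_under,
            "direction": "over" if phat > p0 else ("under" if phat < p0 else "none"),
        }
    for side in ("p_over", "p_under"):
        testable = [g for g in genes if out[g]["n"] > 0]
        if testable:
            adj = multipletests([out[g][side] for g in testable], method="holm")[1]
            for g, a in zip(testable, adj):
                out[g][side + "_adj"] = float(a)
        for g in genes:
            out[g].setdefault(side + "_adj", 1.0)
    return out
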