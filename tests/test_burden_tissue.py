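import numpy as np
import pytest
from scipy import stats

from epiclone.burden_tissue import (
    burden_uv_correlation,
    country_compare,
    estimate_burden,
    per_gene_country_compare,
    percent_mutant,
)
from epiclone.core_io import DonorMeta, SampleInfo
from epiclone.synthetic_cohort import PUBLISHED_DONORS

from .conftest import make_record


@pytest.fixture()
def one_sample():
    return [SampleInfo("D1", "D1_p0", "D1_p0_s00", 1.0, 0.5)]


def flat_spectrum():
    return np.full(96, 1 / 96)


class TestBurden:
    def test_no_synonymous_mutations_gives_zero(self, tiny_panel, one_sample):
        recs = [make_record(consequence="missense")]
        (est,) = estimate_burden(recs, one_sample, tiny_panel, flat_spectrum())
        assert est.mutations_per_mb == 0.0
        assert est.n_syn_used == 0

    def test_single_synonymous_vaf_arithmetic(self, tiny_panel, one_sample):
        recs = [make_record(consequence="synonymous", vaf=0.25, alt_reads=175)]
        (est,) = estimate_burden(recs, one_sample, tiny_panel, flat_spectrum())
        l_syn = tiny_panel.synonymous_footprint_mb(flat_spectrum())
        assert est.mutations_per_mb == pytest.approx(2 * 0.25 / l_syn)

    def test_invariant_to_nonsynonymous_records(self, tiny_panel, one_sample):
        syn = [make_record(consequence="synonymous", vaf=0.1, alt_reads=70)]
        extra = syn + [
            make_record(pos=200, consequence="missense", vaf=0.4, alt_reads=280),
            make_record(pos=300, consequence="nonsense", vaf=0.3, alt_reads=210),
        ]
        a = estimate_burden(syn, one_sample, tiny_panel, flat_spectrum())
        b = estimate_burden(extra, one_sample, tiny_panel, flat_spectrum())
        assert a[0].mutations_per_mb == b[0].mutations_per_mb

    def test_doubling_vafs_doubles_estimate(self, tiny_panel, one_sample):
        recs = [make_record(consequence="synonymous", vaf=0.1, alt_reads=70)]
        doubled = [make_record(consequence="synonymous", vaf=0.2, alt_reads=140)]
        a = estimate_burden(recs, one_sample, tiny_panel, flat_spectrum())
        b = estimate_burden(doubled, one_sample, tiny_panel, flat_spectrum())
        assert b[0].mutations_per_mb == pytest.approx(2 * a[0].mutations_per_mb)

    def test_cna_samples_excluded(self, tiny_panel):
        samples = [
            SampleInfo("D1", "D1_p0", "a", 1.0, 0.5),
            SampleInfo("D1", "D1_p0", "b", 3.0, 0.5, cna_excluded=True),
        ]
        recs = [
            make_record(sample_id="b", consequence="synonymous", vaf=0.3, alt_reads=210)
        ]
        (est,) = estimate_burden(recs, samples, tiny_panel, flat_spectrum())
        assert est.mutations_per_mb == 0.0
        assert est.samples_excluded_cna == 1

    def test_all_samples_cna_gives_null(self, tiny_panel):
        samples = [SampleInfo("D1", "D1_p0", "a", 1.0, 0.5, cna_excluded=True)]
        (est,) = estimate_burden([], samples, tiny_panel, flat_spectrum())
        assert est.mutations_per_mb is None

    def test_recovery_on_published_burdens(self, cohort11, panel, reference):
        """Cohorts simulated at the published per-donor burdens: estimates
        track the truth (slope ~1, mean error <15%) and reproduce the
        country means and their fourfold ratio."""
        donors, samples, records, truth = cohort11
        est = {}
        for country in ("UK", "SG"):
            spectrum = reference.mixture_spectrum(
                truth.config.signature_weights[country]
            )
            for e in estimate_burden(
                [r for r in records if r.donor_id.startswith(country)],
                [s for s in samples if s.donor_id.startswith(country)],
                panel,
                spectrum,
            ):
                est[e.donor_id] = e.mutations_per_mb
        true = {d.donor_id: d.burden_per_mb for d in PUBLISHED_DONORS}
        ids = sorted(true)
        x = np.array([true[i] for i in ids])
        y = np.array([est[i] for i in ids])
        slope = stats.linregress(x, y).slope
        assert 0.85 < slope < 1.15
        rel_err = np.abs(y - x) / x
        assert rel_err.mean() < 0.15
        uk = y[[i.startswith("UK") for i in ids]].mean()
        sg = y[[i.startswith("SG") for i in ids]].mean()
        assert uk == pytest.approx(6.3, rel=0.15)
        assert sg == pytest.approx(1.6, rel=0.15)
        assert uk / sg == pytest.approx(4.0, rel=0.25)


class TestPercentMutant:
    def test_upper_and_lower_bounds(self, one_sample):
        recs = [
            make_record(pos=100, vaf=0.10, alt_reads=70),
            make_record(pos=200, vaf=0.15, alt_reads=105),
        ]
        (est,) = percent_mutant(recs, one_sample)
        assert est.upper_pct == pytest.approx(50.0)
        assert est.lower_pct == pytest.approx(30.0)
        assert est.lower_pct <= est.upper_pct

    def test_upper_bound_caps_at_hundred(self, one_sample):
        recs = [make_record(vaf=0.6, alt_reads=420)]
        (est,) = percent_mutant(recs, one_sample)
        assert est.upper_pct == pytest.approx(100.0)

    def test_donor_mean_over_equal_area_samples(self):
        samples = [
            SampleInfo("D1", "D1_p0", "a", 1.0, 0.5),
            SampleInfo("D1", "D1_p0", "b", 3.0, 0.5),
        ]
        recs = [
            make_record(sample_id="a", vaf=0.2, alt_reads=140),
            make_record(sample_id="b", pos=200, vaf=0.3, alt_reads=210),
        ]
        (est,) = percent_mutant(recs, samples)
        assert est.upper_pct == pytest.approx(50.0)  # mean of 40 and 60

    def test_upper_monotone_lower_depends_on_max(self, one_sample):
        base = [make_record(pos=100, vaf=0.1, alt_reads=70)]
        more = base + [make_record(pos=200, vaf=0.05, alt_reads=35)]
        (a,) = percent_mutant(base, one_sample)
        (b,) = percent_mutant(more, one_sample)
        assert b.upper_pct >= a.upper_pct
        assert b.lower_pct == a.lower_pct  # smaller mutation does not move max

    def test_synonymous_records_ignored(self, one_sample):
        recs = [make_record(consequence="synonymous", vaf=0.4, alt_reads=280)]
        (est,) = percent_mutant(recs, one_sample)
        assert est.upper_pct == 0.0

    def test_gene_filter(self, one_sample):
        recs = [
            make_record(gene="TP53", vaf=0.1, alt_reads=70),
            make_record(pos=200, gene="NOTCH1", vaf=0.2, alt_reads=140),
        ]
        (est,) = percent_mutant(recs, one_sample, gene_filter="NOTCH1")
        assert est.upper_pct == pytest.approx(40.0)


class TestCountryComparisons:
    DONORS = [DonorMeta(f"UK{i}", "UK", 80.0) for i in range(3)] + [
        DonorMeta(f"SG{i}", "SG", 80.0) for i in range(3)
    ]

    def test_identical_groups_p_one(self):
        vals = {d.donor_id: 5.0 for d in self.DONORS}
        vals["UK1"] = vals["SG1"] = 6.0  # identical distributions
        res = country_compare(vals, self.DONORS, test="t")
        assert res.p == pytest.approx(1.0)

    def test_degenerate_group_warns(self):
        donors = self.DONORS[:1] + self.DONORS[3:]
        vals = {d.donor_id: float(i) for i, d in enumerate(donors)}
        with pytest.warns(UserWarning, match="degenerate"):
            res = country_compare(vals, donors)
        assert res.p is None

    def test_perfect_collinearity_gives_r_one(self):
        burden = {f"D{i}": float(i + 1) for i in range(5)}
        uv = {k: 0.1 * v for k, v in burden.items()}
        corr = burden_uv_correlation(burden, uv)
        assert corr["pearson_r"] == pytest.approx(1.0)
        assert corr["spearman_rho"] == pytest.approx(1.0)

    def test_fourfold_contrast_is_detected_with_power(self, panel, reference):
        """6 vs 5 donors with a fourfold burden contrast: the two-sided
        t-test on estimated burdens rejects at 0.05 in most replicates."""
        from epiclone.burden_tissue import estimate_burden
        from epiclone.synthetic_cohort import CohortConfig, generate_cohort

        hits = 0
        n_seeds = 5
        for seed in range(n_seeds):
            _, samples, records, truth = generate_cohort(CohortConfig(seed=100 + seed))
            vals = {}
            for country in ("UK", "SG"):
                spectrum = reference.mixture_spectrum(
                    truth.config.signature_weights[country]
                )
                for e in estimate_burden(
                    [r for r in records if r.donor_id.startswith(country)],
                    [s for s in samples if s.donor_id.startswith(country)],
                    panel,
                    spectrum,
                ):
                    vals[e.donor_id] = e.mutations_per_mb
            donors = [
                DonorMeta(d.donor_id, d.country, d.area_mm2) for d in PUBLISHED_DONORS
            ]
            res = country_compare(vals, donors, test="t")
            hits += res.p < 0.05
        assert hits >= 0.8 * n_seeds

    def test_per_gene_holm_adjustment_orders_p(self):
        rng = np.random.default_rng(0)
        per_gene = {}
        for g in ("A", "B", "C"):
            per_gene[g] = {
                d.donor_id: float(rng.normal(5 if d.country == "UK" else 1, 0.5))
                for d in self.DONORS
            }
        out = per_gene_country_compare(per_gene, self.DONORS, test="wilcoxon")
        for g in per_gene:
            assert out[g]["p_adj"] >= out[g]["p"]
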