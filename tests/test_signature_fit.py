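import itertools

import numpy as np
import pytest

from epiclone.contexts import CHANNELS
from epiclone.signature_fit import (
    Catalog96,
    Exposures,
    build_catalog,
    cluster_exposures,
    dbs_and_strand_summary,
    fit_exposures,
    load_signature_matrix,
    uv_fraction,
)

from .conftest import make_record


def catalog_from_counts(counts, scope="x"):
    return Catalog96(np.asarray(counts, dtype=np.int64), scope, min_mutations=0)


def sample_catalog(reference, weights, n, seed, scope="x"):
    rng = np.random.default_rng(seed)
    p = reference.mixture_spectrum(weights)
    return catalog_from_counts(rng.multinomial(n, p), scope)


class TestCatalog:
    def test_single_record_fills_its_channel(self):
        cat = build_catalog([make_record(context="T[C>T]G")], "d")
        assert cat.n_mutations == 1
        assert cat.counts[CHANNELS.index("T[C>T]G")] == 1

    def test_records_without_context_are_excluded_but_counted(self):
        recs = [make_record(), make_record(pos=200, context=None)]
        cat = build_catalog(recs, "d")
        assert cat.n_mutations == 1
        assert cat.n_excluded_no_context == 1

    def test_usability_threshold(self):
        recs = [make_record(pos=i + 1) for i in range(99)]
        assert not build_catalog(recs, "d").usable
        recs.append(make_record(pos=1000))
        assert build_catalog(recs, "d").usable

    def test_ct_fraction_reflected_in_catalog(self, reference):
        """A catalog built at a 66% C>T fraction reports that fraction."""
        rng = np.random.default_rng(0)
        ct = [i for i, ch in enumerate(CHANNELS) if ch[2:5] == "C>T"]
        other = [i for i in range(96) if i not in ct]
        counts = np.zeros(96, dtype=int)
        for i in rng.choice(ct, 6600):
            counts[i] += 1
        for i in rng.choice(other, 3400):
            counts[i] += 1
        cat = catalog_from_counts(counts)
        got = cat.counts[ct].sum() / cat.n_mutations
        assert got == pytest.approx(0.66, abs=1e-9)


class TestNnlsRefit:
    def test_pure_column_recovers_weight_one(self, reference):
        col = reference.labels.index("SBS7a")
        cat = catalog_from_counts((reference.matrix[:, col] * 1e6).round())
        exp = fit_exposures(cat, reference)
        assert exp.weights["SBS7a"] > 0.99

    def test_exact_mixture_matches_grid_search_oracle(self, reference):
        """An exact 50/50 two-signature catalog: NNLS agrees with a coarse
        grid search over the two-signature simplex."""
        a = reference.labels.index("SBS1")
        b = reference.labels.index("SBS7a")
        y = 0.5 * reference.matrix[:, a] + 0.5 * reference.matrix[:, b]
        cat = catalog_from_counts((y * 1e6).round())
        exp = fit_exposures(cat, reference)
        # oracle: evaluate the residual on a grid of two-signature mixtures
        best, best_res = None, np.inf
        for wa in np.linspace(0, 1, 101):
            mix = wa * reference.matrix[:, a] + (1 - wa) * reference.matrix[:, b]
            res = np.linalg.norm(cat.normalised() - mix)
            if res < best_res:
                best, best_res = wa, res
        assert best == pytest.approx(0.5, abs=0.01)
        assert exp.weights["SBS1"] == pytest.approx(0.5, abs=1e-4)
        assert exp.weights["SBS7a"] == pytest.approx(0.5, abs=1e-4)

    def test_residual_zero_inside_cone(self, reference):
        rng = np.random.default_rng(4)
        w = rng.dirichlet(np.ones(reference.n_signatures))
        y = reference.matrix @ w
        cat = catalog_from_counts((y * 1e7).round())
        exp = fit_exposures(cat, reference)
        assert exp.residual < 1e-6

    def test_uv_weight_recovered_from_uk_mixture(self, reference):
        """3,000 draws from a 66%-UV mixture: the fitted SBS7a-d total is
        within 3 points of the generating weight."""
        weights = {"SBS1": 0.12, "SBS5": 0.22, "SBS7a": 0.30, "SBS7b": 0.18,
                   "SBS7c": 0.10, "SBS7d": 0.06}
        cat = sample_catalog(reference, weights, 3000, seed=11)
        exp = fit_exposures(cat, reference)
        assert uv_fraction(exp) == pytest.approx(0.64, abs=0.03)

    def test_recovery_error_shrinks_with_catalog_size(self, reference):
        weights = {"SBS1": 0.3, "SBS5": 0.3, "SBS7a": 0.4}
        true_uv = 0.4
        errs = []
        for n in (100, 1000, 10000):
            es = []
            for seed in range(10):
                cat = sample_catalog(reference, weights, n, seed=seed)
                es.append(abs(uv_fraction(fit_exposures(cat, reference)) - true_uv))
            errs.append(np.mean(es))
        assert errs[2] < errs[0]

    def test_empty_catalog_rejected(self, reference):
        with pytest.raises(ValueError, match="empty"):
            fit_exposures(catalog_from_counts(np.zeros(96)), reference)


class TestUvFraction:
    @pytest.mark.parametrize(
        "weights,expected",
        [
            ({"SBS1": 1.0}, 0.0),
            ({"SBS7a": 0.3, "SBS7b": 0.36, "SBS5": 0.34}, 0.66),
        ],
    )
    def test_known_mixtures(self, weights, expected):
        exp = Exposures("x", weights, 100, 0.0)
        assert uv_fraction(exp) == pytest.approx(expected)

    def test_matches_label_filtered_sum(self):
        rng = np.random.default_rng(2)
        labels = ["SBS1", "SBS5", "SBS7a", "SBS7b", "SBS7c", "SBS7d"]
        w = rng.dirichlet(np.ones(len(labels)))
        exp = Exposures("x", dict(zip(labels, w)), 100, 0.0)
        brute = sum(v for k, v in exp.weights.items() if k.startswith("SBS7"))
        assert uv_fraction(exp) == pytest.approx(brute)
        assert 0.0 <= uv_fraction(exp) <= 1.0


class TestDbsStrand:
    def test_cc_tt_fraction(self):
        recs = [
            make_record(
                pos=100 + i, mut_class="DBS", ref="CC", alt="TT", context=None,
                consequence="noncoding",
            )
            for i in range(17)
        ] + [
            make_record(
                pos=500 + i, mut_class="DBS", ref="CT", alt="AA", context=None,
                consequence="noncoding",
            )
            for i in range(3)
        ]
        s = dbs_and_strand_summary(recs)
        assert s.n_dbs == 20
        assert s.cc_tt_fraction == pytest.approx(0.85)

    def test_equal_strand_counts_give_ratio_one(self):
        recs = [
            make_record(pos=100 + i, strand_class="transcribed") for i in range(5)
        ] + [
            make_record(pos=200 + i, strand_class="untranscribed") for i in range(5)
        ]
        s = dbs_and_strand_summary(recs)
        assert s.strand_ratio == pytest.approx(1.0)

    def test_zero_untranscribed_gives_null_ratio(self):
        recs = [make_record(strand_class="transcribed")]
        with pytest.warns(UserWarning, match="strand ratio"):
            s = dbs_and_strand_summary(recs)
        assert s.strand_ratio is None

    def test_non_dipyrimidine_ct_excluded_from_ratio(self):
        recs = [
            make_record(context="A[C>T]G", ref="C", strand_class="transcribed"),
        ]
        s = dbs_and_strand_summary(recs)
        assert s.n_transcribed == 0


class TestClustering:
    def test_country_split_reproduced_in_bootstrap(self, reference):
        """UV-high vs UV-low donor groups: the two-group split recurs in
        nearly every bootstrap replicate."""
        uv_high = {"SBS1": 0.10, "SBS5": 0.24, "SBS7a": 0.40, "SBS7b": 0.26}
        uv_low = {"SBS1": 0.40, "SBS5": 0.44, "SBS7a": 0.10, "SBS7b": 0.06}
        catalogs = {}
        for i in range(3):
            catalogs[f"hi{i}"] = sample_catalog(reference, uv_high, 2000, seed=i, scope=f"hi{i}")
            catalogs[f"lo{i}"] = sample_catalog(reference, uv_low, 2000, seed=10 + i, scope=f"lo{i}")
        res = cluster_exposures(catalogs, reference, n_boot=200, seed=0)
        hi = frozenset({"hi0", "hi1", "hi2"})
        lo = frozenset({"lo0", "lo1", "lo2"})
        support = {c: s for c, s in res.support.items()}
        assert support.get(hi, 0) >= 0.95 or support.get(lo, 0) >= 0.95

    def test_identical_exposures_single_zero_height_cluster(self, reference):
        counts = (reference.matrix[:, 0] * 1000).round()
        catalogs = {f"s{i}": catalog_from_counts(counts, f"s{i}") for i in range(3)}
        res = cluster_exposures(catalogs, reference, n_boot=100, seed=0)
        assert np.allclose(res.linkage[:, 2], 0.0)

    def test_scope_order_invariance(self, reference):
        weights = [
            {"SBS1": 1.0},
            {"SBS5": 1.0},
            {"SBS7a": 1.0},
            {"SBS7a": 0.5, "SBS1": 0.5},
        ]
        catalogs = {
            f"s{i}": sample_catalog(reference, w, 1500, seed=i, scope=f"s{i}")
            for i, w in enumerate(weights)
        }
        res1 = cluster_exposures(catalogs, reference, n_boot=100, seed=5)
        shuffled = dict(reversed(list(catalogs.items())))
        res2 = cluster_exposures(shuffled, reference, n_boot=100, seed=5)
        assert set(res1.clusters) == set(res2.clusters)

    def test_too_few_scopes_rejected(self, reference):
        catalogs = {
            "a": catalog_from_counts((reference.matrix[:, 0] * 500).round()),
            "b": catalog_from_counts((reference.matrix[:, 1] * 500).round()),
        }
        with pytest.raises(ValueError, match="3 scopes"):
            cluster_exposures(catalogs, reference, n_boot=100)
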