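import numpy as np
import pytest

from epiclone.clone_map import (
    clone_size_distribution,
    infer_nesting,
    merge_mutations,
)
from epiclone.core_io import DonorMeta, SampleInfo
from epiclone.synthetic_cohort import CohortConfig, DonorSpec, generate_cohort

from .conftest import make_record


def grid_samples(n, donor="D1", piece="D1_p0", spacing=2.0):
    """n samples in a row, centres ``spacing`` mm apart."""
    return [
        SampleInfo(
            donor_id=donor,
            piece_id=piece,
            sample_id=f"{piece}_s{i:02d}",
            x_mm=i * spacing + 1.0,
            y_mm=0.5,
        )
        for i in range(n)
    ]


class TestMerging:
    def test_nearby_identical_variants_merge(self):
        samples = grid_samples(3, spacing=4.0)
        recs = [
            make_record(sample_id=samples[0].sample_id, vaf=0.1, alt_reads=70),
            make_record(sample_id=samples[1].sample_id, vaf=0.2, alt_reads=140),
        ]
        (clone,) = merge_mutations(recs, samples)
        assert clone.n_samples == 2
        assert clone.summed_vaf == pytest.approx(0.3)

    def test_beyond_threshold_stays_split(self):
        samples = grid_samples(2, spacing=12.0)
        recs = [
            make_record(sample_id=samples[0].sample_id),
            make_record(sample_id=samples[1].sample_id),
        ]
        clones = merge_mutations(recs, samples)
        assert len(clones) == 2

    def test_different_pieces_never_merge(self):
        s0 = grid_samples(1, piece="D1_p0")[0]
        s1 = grid_samples(1, piece="D1_p1")[0]  # same coordinates, other piece
        recs = [
            make_record(sample_id=s0.sample_id, piece_id="D1_p0"),
            make_record(sample_id=s1.sample_id, piece_id="D1_p1"),
        ]
        assert len(merge_mutations(recs, [s0, s1])) == 2

    def test_chain_merges_past_threshold_by_transitive_closure(self):
        # 8 samples 2 mm apart: ends are 14 mm apart but the chain merges
        samples = grid_samples(8, spacing=2.0)
        recs = [make_record(sample_id=s.sample_id) for s in samples]
        (clone,) = merge_mutations(recs, samples)
        assert clone.n_samples == 8

    def test_order_invariance_and_vaf_conservation(self):
        rng = np.random.default_rng(0)
        samples = grid_samples(12, spacing=3.0)
        recs = []
        for pos in (100, 200, 300):
            for s in rng.choice(samples, size=5, replace=False):
                a = int(rng.integers(5, 200))
                recs.append(
                    make_record(sample_id=s.sample_id, pos=pos, alt_reads=a, depth=700)
                )
        base = merge_mutations(recs, samples)
        for _ in range(3):
            perm = list(rng.permutation(len(recs)))
            shuffled = [recs[i] for i in perm]
            again = merge_mutations(shuffled, samples)
            assert [c.member_vafs for c in again] == [c.member_vafs for c in base]
        assert sum(c.summed_vaf for c in base) == pytest.approx(
            sum(r.vaf for r in recs)
        )

    def test_clone_count_monotone_in_distance_threshold(self):
        rng = np.random.default_rng(1)
        samples = grid_samples(15, spacing=3.5)
        recs = [
            make_record(sample_id=s.sample_id, pos=100)
            for s in rng.choice(samples, size=9, replace=False)
        ]
        counts = [
            len(merge_mutations(recs, samples, max_distance_mm=d))
            for d in (20.0, 10.0, 5.0, 2.0)
        ]
        assert counts == sorted(counts)

    def test_duplicate_listings_collapse_with_summed_reads(self):
        samples = grid_samples(1)
        recs = [
            make_record(alt_reads=10, depth=100),
            make_record(alt_reads=20, depth=100),
        ]
        (clone,) = merge_mutations(recs, samples)
        assert clone.summed_vaf == pytest.approx(30 / 200)

    def test_unknown_sample_rejected(self):
        with pytest.raises(ValueError, match="unknown sample"):
            merge_mutations([make_record(sample_id="nope")], grid_samples(1))


class TestCloneSizes:
    def test_single_clone_summary(self):
        samples = grid_samples(1)
        donors = [DonorMeta("D1", "UK", 2.0)]
        clones = merge_mutations(
            [make_record(alt_reads=210, depth=700)], samples
        )
        summaries, _ = clone_size_distribution(clones, donors)
        assert summaries["UK"].mean == pytest.approx(0.3)

    def test_identical_groups_welch_p_near_one(self):
        donors = [DonorMeta("D1", "UK", 8.0), DonorMeta("D2", "SG", 8.0)]
        samples, recs = [], []
        for donor in ("D1", "D2"):
            piece = f"{donor}_p0"
            for j, a in enumerate((70, 140, 70, 140)):
                sid = f"{piece}_s{j:02d}"
                samples.append(SampleInfo(donor, piece, sid, 4.0 * j, 0.5))
                recs.append(
                    make_record(
                        donor_id=donor,
                        piece_id=piece,
                        sample_id=sid,
                        pos=100 + j,
                        alt_reads=a,
                    )
                )
        clones = merge_mutations(recs, samples)
        _, test = clone_size_distribution(clones, donors)
        assert test["p"] == pytest.approx(1.0)

    def test_dense_cohort_has_smaller_clones(self):
        """Dense (UK-like, 4x burden) vs sparse cohorts: the dense group's
        mean clone size is smaller, the restriction seen in competition."""
        means = {"dense": [], "sparse": []}
        for seed in range(3):
            cfg = CohortConfig(
                donors=(
                    DonorSpec("U1", "UK", 48.0, 6.4),
                    DonorSpec("S1", "SG", 48.0, 1.6),
                ),
                seed=seed,
            )
            donors, samples, records, _ = generate_cohort(cfg)
            clones = merge_mutations(records, samples)
            summaries, _ = clone_size_distribution(clones, donors)
            means["dense"].append(summaries["UK"].mean)
            means["sparse"].append(summaries["SG"].mean)
        assert np.mean(means["dense"]) < np.mean(means["sparse"])


class TestNesting:
    def test_contained_smaller_clone_gets_parent(self):
        samples = grid_samples(4)
        recs = [
            make_record(sample_id=samples[0].sample_id, pos=100, alt_reads=200),
            make_record(sample_id=samples[1].sample_id, pos=100, alt_reads=200),
            make_record(sample_id=samples[0].sample_id, pos=200, alt_reads=100),
        ]
        clones = infer_nesting(merge_mutations(recs, samples))
        by_pos = {c.variant_key[1]: c for c in clones}
        assert by_pos[200].parent_clone_id == by_pos[100].clone_id
        assert by_pos[100].parent_clone_id is None

    def test_disjoint_clones_are_parentless(self):
        samples = grid_samples(2, spacing=4.0)
        recs = [
            make_record(sample_id=samples[0].sample_id, pos=100),
            make_record(sample_id=samples[1].sample_id, pos=200),
        ]
        clones = infer_nesting(merge_mutations(recs, samples))
        assert all(c.parent_clone_id is None for c in clones)

    def test_ground_truth_nesting_recovery(self):
        """In a sparse, deeply sequenced cohort with large clones, >=90% of
        generator-recorded nestings are recovered (via the ancestor chain)."""
        recovered = total = 0
        for seed in range(6):
            cfg = CohortConfig(
                donors=(DonorSpec("D1", "UK", 80.0, 2.5),),
                clone_area_scale_mm2={"UK": 2.0},
                drivers={"UK": {}},
                hotspot_rates_per_cm2={"UK": {}},
                cna_rate={"UK": 0.0},
                dbs_fraction={"UK": 0.0},
                indel_fraction={"UK": 0.0},
                nest_prob=0.6,
                extra_mutations_per_clone=0.0,
                depth=700,
                seed=seed,
            )
            _, samples, records, truth = generate_cohort(cfg)
            clones = infer_nesting(merge_mutations(records, samples))
            by_key = {}
            for c in clones:
                by_key.setdefault((c.piece_id,) + c.variant_key, []).append(c)
            ids = {c.clone_id: c for c in clones}
            truth_by_id = {tc.clone_id: tc for tc in truth.clones}
            for tc in truth.clones:
                if tc.parent_id is None:
                    continue
                parent_tc = truth_by_id[tc.parent_id]
                ck = (tc.piece_id,) + tc.variant_key
                pk = (parent_tc.piece_id,) + parent_tc.variant_key
                if len(by_key.get(ck, [])) != 1 or len(by_key.get(pk, [])) != 1:
                    continue
                child, parent = by_key[ck][0], by_key[pk][0]
                total += 1
                anc = child.parent_clone_id
                for _ in range(30):
                    if anc is None:
                        break
                    if anc == parent.clone_id:
                        recovered += 1
                        break
                    anc = ids[anc].parent_clone_id
        assert total >= 40
        assert recovered / total >= 0.9
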