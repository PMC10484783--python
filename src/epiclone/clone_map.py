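"""Merge identical mutations across nearby grid samples into clones.

A clone that spreads across the tissue is called independently in each
grid sample it touches. Identical variants (same donor, piece, chromosome,
position, ref and alt) are merged into one clone when their samples lie
within a distance threshold of each other, by single-linkage transitive
closure — so a long run of adjacent samples merges into one clone even
though its extremes are farther apart than the threshold. Variants in
different epidermis pieces are never merged, because the physical distance
between pieces is unknown. Clone size is the summed VAF over member
samples.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import DonorMeta, MutationRecord, SampleInfo

log = logging.getLogger(__name__)

MERGE_DISTANCE_MM = 10.0
NESTING_VAF_TOLERANCE = 0.25


@dataclass
class Clone:
    clone_id: str
    donor_id: str
    piece_id: str
    variant_key: tuple[str, int, str, str]
    member_vafs: dict[str, float]  # sample_id -> VAF
    gene: str | None = None
    consequence: str = "noncoding"
    parent_clone_id: str | None = None

    @property
    def summed_vaf(self) -> float:
        return float(sum(self.member_vafs.values()))

    @property
    def n_samples(self) -> int:
        return len(self.member_vafs)

    @property
    def sample_ids(self) -> frozenset[str]:
        return frozenset(self.member_vafs)


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[max(ra, rb)] = min(ra, rb)


def merge_mutations(
    records: list[MutationRecord],
    samples: list[SampleInfo],
    max_distance_mm: float = MERGE_DISTANCE_MM,
) -> list[Clone]:
    """Single-linkage merge of identical variants within ``max_distance_mm``.

    Records should already be germline-filtered. Duplicate listings of one
    variant in one sample collapse with summed alt reads (logged). The
    result is deterministic and independent of record order: clones are
    keyed by sorted member samples.
    """
    coord = {s.sample_id: (s.x_mm, s.y_mm) for s in samples}
    for r in records:
        if r.sample_id not in coord:
            raise ValueError(f"record references unknown sample {r.sample_id!r}")

    groups: dict[tuple, dict[str, MutationRecord]] = {}
    n_dup = 0
    for r in records:
        key = (r.donor_id, r.piece_id) + r.variant_key
        by_sample = groups.setdefault(key, {})
        if r.sample_id in by_sample:
            prev = by_sample[r.sample_id]
            alt = prev.alt_reads + r.alt_reads
            depth = prev.depth + r.depth
            from dataclasses import replace

            by_sample[r.sample_id] = replace(
                prev, alt_reads=alt, depth=depth, vaf=alt / depth if depth else 0.0
            )
            n_dup += 1
        else:
            by_sample[r.sample_id] = r
    if n_dup:
        log.info("collapsed %d duplicate variant listings", n_dup)

    clones: list[Clone] = []
    for key in sorted(groups):
        by_sample = groups[key]
        sids = sorted(by_sample)
        n = len(sids)
        uf = _UnionFind(n)
        for i in range(n):
            xi, yi = coord[sids[i]]
            for j in range(i + 1, n):
                xj, yj = coord[sids[j]]
                if math.hypot(xi - xj, yi - yj) <= max_distance_mm:
                    uf.union(i, j)
        comps: dict[int, list[str]] = {}
        for i in range(n):
            comps.setdefault(uf.find(i), []).append(sids[i])
        for root in sorted(comps):
            members = comps[root]
            rec0 = by_sample[members[0]]
            clones.append(
                Clone(
                    clone_id="",  # assigned below, after deterministic ordering
                    donor_id=rec0.donor_id,
                    piece_id=rec0.piece_id,
                    variant_key=rec0.variant_key,
                    member_vafs={m: by_sample[m].vaf for m in members},
                    gene=rec0.gene,
                    consequence=rec0.consequence,
                )
            )
    clones.sort(key=lambda c: (c.donor_id, c.piece_id, c.variant_key, min(c.member_vafs)))
    for i, c in enumerate(clones):
        c.clone_id = f"cl{i:06d}"
    return clones


@dataclass
class CloneSizeSummary:
    group: str
    n_clones: int
    mean: float | None
    quantiles: dict[float, float]
    sizes: np.ndarray


def clone_size_distribution(
    clones: list[Clone],
    donors: list[DonorMeta],
    group_by: str = "country",
) -> tuple[dict[str, CloneSizeSummary], dict]:
    """Per-group clone-size (summed VAF) summaries plus a two-sided Welch
    t-test on group means (only computed for exactly two nonempty groups)."""
    meta = {d.donor_id: d for d in donors}
    grouped: dict[str, list[float]] = {}
    for c in clones:
        if group_by == "country":
            g = meta[c.donor_id].country
        elif group_by == "donor":
            g = c.donor_id
        else:
            raise ValueError(f"unknown group_by {group_by!r}")
        grouped.setdefault(g, []).append(c.summed_vaf)
    summaries = {}
    for g, sizes in sorted(grouped.items()):
        arr = np.array(sizes)
        summaries[g] = CloneSizeSummary(
            group=g,
            n_clones=arr.size,
            mean=float(arr.mean()) if arr.size else None,
            quantiles={
                q: float(np.quantile(arr, q)) if arr.size else float("nan")
                for q in (0.25, 0.5, 0.75)
            },
            sizes=arr,
        )
    test: dict = {"test": "welch_t", "p": None, "statistic": None}
    nonempty = [s for s in summaries.values() if s.n_clones > 1]
    if len(nonempty) == 2:
        res = stats.ttest_ind(nonempty[0].sizes, nonempty[1].sizes, equal_var=False)
        test["p"] = float(res.pvalue)
        test["statistic"] = float(res.statistic)
    return summaries, test


def infer_nesting(
    clones: list[Clone],
    tolerance: float = NESTING_VAF_TOLERANCE,
) -> list[Clone]:
    """Infer subclone nesting within each donor piece.

    Clone B nests under A iff B's member samples are a subset of A's and in
    every shared sample VAF_B <= VAF_A * (1 + tolerance); the tolerance
    absorbs read-sampling noise. Among multiple containing candidates the
    smallest (by summed VAF) is the parent; ties between equal-looking
    clones are broken by making the smaller summed VAF the child.
    Unresolvable clones keep parent None. Parent links are set in place and
    the list is returned for convenience.
    """
    by_piece: dict[tuple[str, str], list[Clone]] = {}
    for c in clones:
        c.parent_clone_id = None
        by_piece.setdefault((c.donor_id, c.piece_id), []).append(c)
    for piece_clones in by_piece.values():
        for b in piece_clones:
            best: Clone | None = None
            for a in piece_clones:
                if a is b:
                    continue
                if not b.sample_ids <= a.sample_ids:
                    continue
                ok = all(
                    b.member_vafs[s] <= a.member_vafs[s] * (1 + tolerance)
                    for s in b.member_vafs
                )
                if not ok:
                    continue
                if a.summed_vaf == b.summed_vaf and a.clone_id > b.clone_id:
                    continue  # tie: deterministic direction
                if b.summed_vaf > a.summed_vaf:
                    continue  # child must be the smaller clone
                if best is None or a.summed_vaf < best.summed_vaf:
                    best = a
            if best is not None:
                b.parent_clone_id = best.clone_id
    return clones


def clones_to_frame(clones: list[Clone]) -> pd.DataFrame:
    rows = []
    for c in clones:
        rows.append(
            {
                "clone_id": c.clone_id,
                "donor_id": c.donor_id,
                "piece_id": c.piece_id,
                "chrom": c.variant_key[0],
                "pos": c.variant_key[1],
                "ref": c.variant_key[2],
                "alt": c.variant_key[3],
                "gene": c.gene or "",
                "consequence": c.consequence,
                "n_samples": c.n_samples,
                "summed_vaf": c.summed_vaf,
                "members": ";".join(sorted(c.member_vafs)),
                "parent_clone_id": c.parent_clone_id or "",
            }
        )
    return pd.DataFrame(rows)
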