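"""Synthetic grid-sampled epidermis cohorts with recorded ground truth.

The real cohort is controlled-access; this generator emits cohorts with the
same statistical structure so every analysis stage is testable end to end:

* Each donor's epidermis is cut into contiguous pieces, each a grid of
  2 x 1 mm samples (2 mm^2), matching the published per-donor sampled areas.
* Somatic clones are discs placed on a per-piece torus (so no clone mass is
  lost at piece edges); disc area follows an exponential law whose scale
  differs by country, encoding the observed clone-size contrast. Driver
  clones get both excess non-synonymous mutations and a scaled-up area.
* A clone's true allele fraction in a sample is 0.5 x overlap / sample
  area (diploid heterozygous), then perturbed by binomial read sampling at
  the configured depth. Records with zero alt reads are not emitted
  (undetectable calls).
* Mutation contexts are drawn from a country-specific mixture of the
  packaged reference signatures (UV-dominant in the UK, aging-dominant in
  Singapore); sites are drawn uniformly within the drawn context channel
  from the gene panel, which fixes the synonymous fraction to the panel's
  spectrum-weighted synonymous opportunity.
* Occasional samples carry a copy-number aberration (allele fractions of
  mutations in the affected gene are doubled, and the sample is flagged);
  TP53 R248W/R282W hotspot mutations are spiked at configured per-cm^2
  rates.

The per-donor mutation event rate is calibrated so that the expected
per-cell mutation count in the exonic bait footprint equals
``burden_per_mb * exonic_footprint_mb``, which the synonymous-site burden
estimator then recovers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from shapely.affinity import translate
from shapely.geometry import Point, box

from .contexts import CHANNELS, PYRIMIDINES
from .core_io import DonorMeta, MutationRecord, SampleInfo
from .panel import CONSEQUENCE_OF_CLASS, SYN, PanelDef, default_panel
from .signature_fit import SignatureMatrix, packaged_reference_signatures

# polygonised discs: 64-gon, radius inflated so polygon area = disc area
_NGON_QUADSEGS = 16
_NGON_RADIUS_FACTOR = math.sqrt(
    2 * math.pi / (4 * _NGON_QUADSEGS * math.sin(2 * math.pi / (4 * _NGON_QUADSEGS)))
)

SAMPLE_W_MM = 2.0  # sample footprint 2 x 1 mm
SAMPLE_H_MM = 1.0
SAMPLE_AREA_MM2 = SAMPLE_W_MM * SAMPLE_H_MM


@dataclass(frozen=True)
class DonorSpec:
    donor_id: str
    country: str
    area_mm2: float
    burden_per_mb: float
    age_band: str = ""
    sex: str = ""


#: published cohort: five Singaporean and six UK donors with their sampled
#: areas (mm^2) and genome-wide burden estimates (mutations per Mb)
PUBLISHED_DONORS: tuple[DonorSpec, ...] = (
    DonorSpec("SG1", "SG", 68.0, 3.75, "68-71", "F"),
    DonorSpec("SG2", "SG", 78.0, 0.62, "28-31", "F"),
    DonorSpec("SG3", "SG", 76.0, 0.74, "72-75", "M"),
    DonorSpec("SG4", "SG", 80.0, 1.31, "76-79", "M"),
    DonorSpec("SG5", "SG", 80.0, 1.34, "56-59", "M"),
    DonorSpec("UK1", "UK", 88.0, 4.24, "60-63", "M"),
    DonorSpec("UK2", "UK", 90.0, 4.13, "76-79", "F"),
    DonorSpec("UK3", "UK", 78.0, 11.9, "64-67", "F"),
    DonorSpec("UK4", "UK", 78.0, 4.87, "76-79", "M"),
    DonorSpec("UK5", "UK", 72.0, 5.50, "72-75", "M"),
    DonorSpec("UK6", "UK", 68.0, 7.35, "48-51", "F"),
)

#: UV-dominant (UK, SBS7a-d total 0.66) vs aging-dominant (SG, SBS1+5 = 0.64)
DEFAULT_SIGNATURE_WEIGHTS: dict[str, dict[str, float]] = {
    "UK": {"SBS1": 0.12, "SBS5": 0.22, "SBS7a": 0.30, "SBS7b": 0.18,
           "SBS7c": 0.10, "SBS7d": 0.08},
    "SG": {"SBS1": 0.25, "SBS5": 0.39, "SBS7a": 0.15, "SBS7b": 0.10,
           "SBS7c": 0.07, "SBS7d": 0.04},
}

#: exponential clone-area scale (mm^2); mean summed VAF = scale / (2 *
#: sample area), giving the observed country means 0.029 (UK) / 0.037 (SG)
DEFAULT_CLONE_AREA_SCALE: dict[str, float] = {"UK": 0.116, "SG": 0.148}

#: per-gene selection strength: multiplies both the non-synonymous event
#: rate and the clone-area scale of clones in that gene
DEFAULT_DRIVERS: dict[str, dict[str, float]] = {
    "UK": {"NOTCH1": 2.5, "FAT1": 2.5, "TP53": 4.0, "NOTCH2": 1.8,
           "NOTCH3": 1.6, "ARID2": 1.6, "AJUBA": 1.5},
    "SG": {"NOTCH1": 4.0, "FAT1": 2.5, "TP53": 1.8, "NOTCH2": 3.0,
           "NOTCH3": 1.6, "ARID2": 1.2, "AJUBA": 1.5},
}

#: TP53 hotspot spike rates, mutations per cm^2 of sampled tissue
DEFAULT_HOTSPOTS: dict[str, dict[str, float]] = {
    "UK": {"R248W": 3.2, "R282W": 2.5},
    "SG": {},
}

_HOTSPOT_CHANGES = {
    "R248W": ("TP53", 248, "C", "T"),
    "R282W": ("TP53", 282, "C", "T"),
}

DEFAULT_CNA_RATE: dict[str, float] = {"UK": 0.13, "SG": 0.01}
DEFAULT_DBS_FRACTION: dict[str, float] = {"UK": 0.060, "SG": 0.035}
DEFAULT_INDEL_FRACTION: dict[str, float] = {"UK": 0.040, "SG": 0.100}


@dataclass
class HotspotSpec:
    """Codon-level hotspot spike: protein change -> rate per cm^2."""

    gene: str = "TP53"
    rates_per_cm2: dict[str, float] = field(default_factory=dict)


@dataclass
class CohortConfig:
    donors: tuple[DonorSpec, ...] = PUBLISHED_DONORS
    panel: PanelDef | None = None
    reference: SignatureMatrix | None = None
    signature_weights: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_SIGNATURE_WEIGHTS.items()}
    )
    clone_area_scale_mm2: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLONE_AREA_SCALE)
    )
    drivers: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_DRIVERS.items()}
    )
    hotspot_rates_per_cm2: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_HOTSPOTS.items()}
    )
    cna_rate: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_CNA_RATE))
    dbs_fraction: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_DBS_FRACTION)
    )
    indel_fraction: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_INDEL_FRACTION)
    )
    strand_ratio_uv: float = 52.7
    depth: int = 700
    piece_cols: int = 4
    piece_rows: int = 4
    nest_prob: float = 0.15
    extra_mutations_per_clone: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        for c, w in self.signature_weights.items():
            vals = np.array(list(w.values()))
            if np.any(vals < 0) or abs(vals.sum() - 1.0) > 1e-6:
                raise ValueError(f"signature weights for {c} must be a distribution")
        for d in self.donors:
            if d.burden_per_mb < 0:
                raise ValueError(f"{d.donor_id}: burden must be >= 0")
            if d.area_mm2 < SAMPLE_AREA_MM2:
                raise ValueError(
                    f"{d.donor_id}: area {d.area_mm2} smaller than one sample"
                )


@dataclass
class TrueClone:
    clone_id: str
    donor_id: str
    piece_id: str
    variant_key: tuple
    gene: str | None
    consequence: str
    area_mm2: float
    center: tuple[float, float]
    sample_vafs: dict[str, float]
    parent_id: str | None = None
    co_clone_of: str | None = None  # same physical clone (co-occurring mutation)
    is_driver: bool = False
    is_hotspot: bool = False


@dataclass
class GroundTruth:
    burden: dict[str, float]
    exposures: dict[str, dict[str, float]]
    clones: list[TrueClone]
    cna_samples: list[tuple[str, str]]  # (sample_id, gene)
    synonymous_footprint_mb: dict[str, float]
    config: CohortConfig


# ---------------------------------------------------------------------------

class _Piece:
    """Grid geometry of one epidermis piece on a local torus."""

    def __init__(self, piece_id: str, donor_id: str, cols: int, rows: int,
                 y_offset: float, depth: int):
        self.piece_id = piece_id
        self.width = cols * SAMPLE_W_MM
        self.height = rows * SAMPLE_H_MM
        self.cols = cols
        self.rows = rows
        self.samples: list[SampleInfo] = []
        self.cells: dict[tuple[int, int], SampleInfo] = {}
        for j in range(rows):
            for i in range(cols):
                s = SampleInfo(
                    donor_id=donor_id,
                    piece_id=piece_id,
                    sample_id=f"{piece_id}_s{j * cols + i:02d}",
                    x_mm=i * SAMPLE_W_MM + SAMPLE_W_MM / 2,
                    y_mm=y_offset + j * SAMPLE_H_MM + SAMPLE_H_MM / 2,
                    area_mm2=SAMPLE_AREA_MM2,
                    mean_depth=depth,
                )
                self.samples.append(s)
                self.cells[(i, j)] = s

    def clone_overlaps(self, cx: float, cy: float, area: float) -> dict[str, float]:
        """Exact per-sample overlap (mm^2) of a disc on the piece torus."""
        r = math.sqrt(area / math.pi) * _NGON_RADIUS_FACTOR
        cx %= self.width
        cy %= self.height
        disc = Point(cx, cy).buffer(r, quad_segs=_NGON_QUADSEGS)
        shifts_x = [0.0]
        if cx - r < 0:
            shifts_x.append(self.width)
        if cx + r > self.width:
            shifts_x.append(-self.width)
        shifts_y = [0.0]
        if cy - r < 0:
            shifts_y.append(self.height)
        if cy + r > self.height:
            shifts_y.append(-self.height)
        out: dict[str, float] = {}
        for dx in shifts_x:
            for dy in shifts_y:
                d = translate(disc, dx, dy) if (dx or dy) else disc
                x0, y0, x1, y1 = d.bounds
                i0 = max(0, int(math.floor(x0 / SAMPLE_W_MM)))
                i1 = min(self.cols - 1, int(math.floor(x1 / SAMPLE_W_MM)))
                j0 = max(0, int(math.floor(y0 / SAMPLE_H_MM)))
                j1 = min(self.rows - 1, int(math.floor(y1 / SAMPLE_H_MM)))
                for i in range(i0, i1 + 1):
                    for j in range(j0, j1 + 1):
                        cell = box(i * SAMPLE_W_MM, j * SAMPLE_H_MM,
                                   (i + 1) * SAMPLE_W_MM, (j + 1) * SAMPLE_H_MM)
                        a = d.intersection(cell).area
                        if a > 0:
                            sid = self.cells[(i, j)].sample_id
                            out[sid] = out.get(sid, 0.0) + a
        return out

    @property
    def max_clone_area(self) -> float:
        rmax = 0.475 * min(self.width, self.height)
        return math.pi * rmax * rmax


def _assign_strand(context: str | None, ratio: float, rng: np.random.Generator) -> str:
    from .contexts import is_dipyrimidine_ct

    if context is None:
        return "unknown"
    if is_dipyrimidine_ct(context):
        p = ratio / (1.0 + ratio)
        return "transcribed" if rng.random() < p else "untranscribed"
    return "transcribed" if rng.random() < 0.5 else "untranscribed"


# ---------------------------------------------------------------------------

def generate_cohort(
    config: CohortConfig | None = None,
) -> tuple[list[DonorMeta], list[SampleInfo], list[MutationRecord], GroundTruth]:
    """Generate a full cohort; deterministic under ``config.seed``."""
    config = config or CohortConfig()
    panel = config.panel or default_panel()
    reference = config.reference or packaged_reference_signatures()
    rng = np.random.default_rng(config.seed)

    donors: list[DonorMeta] = []
    samples: list[SampleInfo] = []
    records: list[MutationRecord] = []
    truth_clones: list[TrueClone] = []
    cna_samples: list[tuple[str, str]] = []
    exposures: dict[str, dict[str, float]] = {}
    burden: dict[str, float] = {}
    l_syn: dict[str, float] = {}

    spectra = {
        c: reference.mixture_spectrum(w) for c, w in config.signature_weights.items()
    }
    for c, spec in spectra.items():
        l_syn[c] = panel.synonymous_footprint_mb(spec)

    clone_counter = 0
    for donor in config.donors:
        country = donor.country
        spectrum = spectra[country]
        donors.append(
            DonorMeta(
                donor_id=donor.donor_id,
                country=country,
                total_area_mm2=donor.area_mm2,
                age_band=donor.age_band,
                sex=donor.sex,
            )
        )
        burden[donor.donor_id] = donor.burden_per_mb
        exposures[donor.donor_id] = dict(config.signature_weights[country])

        # cut the donor area into pieces of piece_cols x piece_rows samples
        n_samples = int(round(donor.area_mm2 / SAMPLE_AREA_MM2))
        per_piece = config.piece_cols * config.piece_rows
        pieces: list[_Piece] = []
        p_idx = 0
        remaining = n_samples
        while remaining > 0:
            k = min(per_piece, remaining)
            cols = config.piece_cols
            rows = max(1, k // cols)
            if cols * rows > remaining and remaining < per_piece:
                cols = min(cols, remaining)
                rows = max(1, remaining // cols)
            piece = _Piece(
                piece_id=f"{donor.donor_id}_p{p_idx}",
                donor_id=donor.donor_id,
                cols=cols,
                rows=rows,
                y_offset=p_idx * 1000.0,
                depth=config.depth,
            )
            pieces.append(piece)
            remaining -= cols * rows
            p_idx += 1

        # CNA flags per sample
        cna_gene_by_sample: dict[str, str] = {}
        for piece in pieces:
            flags = rng.random(len(piece.samples)) < config.cna_rate.get(country, 0.0)
            new_samples = []
            for s, flag in zip(piece.samples, flags):
                if flag:
                    g = (
                        "NOTCH1"
                        if rng.random() < 0.78
                        else str(rng.choice(["TP53", "NOTCH4", "FGFR2", "RB1"]))
                    )
                    if g in panel.gene_index:
                        cna_gene_by_sample[s.sample_id] = g
                        cna_samples.append((s.sample_id, g))
                        s = replace(s, cna_excluded=True)
                new_samples.append(s)
            piece.samples = new_samples
            piece.cells = {
                k: s for k, s in zip(piece.cells.keys(), new_samples)
            }
            samples.extend(new_samples)

        driver_table = config.drivers.get(country, {})
        scale = config.clone_area_scale_mm2[country]
        mean_muts_per_clone = 1.0 + config.extra_mutations_per_clone

        for piece in pieces:
            piece_area = len(piece.samples) * SAMPLE_AREA_MM2
            clones_here: list[TrueClone] = []
            geometry: dict[str, tuple[float, float, float]] = {}  # id -> cx, cy, r

            def emit_clone(
                site: int,
                alt_slot: int,
                area: float,
                *,
                is_driver: bool = False,
                is_hotspot: bool = False,
                extra_sites: list[tuple[int, int]] | None = None,
            ) -> None:
                nonlocal clone_counter
                area = min(area, piece.max_clone_area)
                r = math.sqrt(area / math.pi)
                parent_id = None
                # occasionally nest inside an existing larger clone
                candidates = [
                    c for c in clones_here
                    if geometry[c.clone_id][2] > 1.25 * r and not c.is_hotspot
                ]
                if candidates and rng.random() < config.nest_prob:
                    parent = candidates[rng.integers(len(candidates))]
                    pcx, pcy, pr = geometry[parent.clone_id]
                    theta = rng.random() * 2 * math.pi
                    rad = rng.random() * 0.8 * (pr - r)
                    cx = pcx + rad * math.cos(theta)
                    cy = pcy + rad * math.sin(theta)
                    parent_id = parent.clone_id
                else:
                    cx = rng.random() * piece.width
                    cy = rng.random() * piece.height
                overlaps = piece.clone_overlaps(cx, cy, area)
                site_list = [(site, alt_slot)] + (extra_sites or [])
                first_id = None
                for s_i, (st, sl) in enumerate(site_list):
                    d = panel.describe_site(st, sl)
                    clone_counter += 1
                    cid = f"tc{clone_counter:06d}"
                    if first_id is None:
                        first_id = cid
                    sample_vafs = {}
                    for sid, ov in overlaps.items():
                        vaf_true = 0.5 * ov / SAMPLE_AREA_MM2
                        sample_vafs[sid] = min(0.5, vaf_true)
                    tc = TrueClone(
                        clone_id=cid,
                        donor_id=donor.donor_id,
                        piece_id=piece.piece_id,
                        variant_key=(d["chrom"], d["pos"], d["ref"], d["alt"]),
                        gene=d["gene"],
                        consequence=d["consequence"],
                        area_mm2=area,
                        center=(cx, cy),
                        sample_vafs=sample_vafs,
                        parent_id=parent_id,
                        co_clone_of=None if s_i == 0 else first_id,
                        is_driver=is_driver,
                        is_hotspot=is_hotspot,
                    )
                    clones_here.append(tc)
                    geometry[cid] = (cx, cy, r)
                    truth_clones.append(tc)
                    context = CHANNELS[d["channel"]]
                    strand = _assign_strand(context, config.strand_ratio_uv, rng)
                    for sid, vaf_true in sample_vafs.items():
                        af = vaf_true
                        if cna_gene_by_sample.get(sid) == d["gene"]:
                            af = min(1.0, 2.0 * af)
                        alt = int(rng.binomial(config.depth, af))
                        if alt == 0:
                            continue
                        records.append(
                            MutationRecord(
                                donor_id=donor.donor_id,
                                piece_id=piece.piece_id,
                                sample_id=sid,
                                chrom=d["chrom"],
                                pos=d["pos"],
                                ref=d["ref"],
                                alt=d["alt"],
                                mut_class="SBS",
                                consequence=d["consequence"],
                                vaf=alt / config.depth,
                                alt_reads=alt,
                                depth=config.depth,
                                gene=d["gene"],
                                protein_change=(
                                    d["protein_change"]
                                    if d["consequence"] != "synonymous"
                                    else None
                                ),
                                context=context,
                                strand_class=strand,
                            )
                        )

            # neutral (passenger) clones
            expected_events = (
                donor.burden_per_mb
                * panel.exonic_footprint_mb
                * piece_area
                / (scale * mean_muts_per_clone)
            )
            n_events = int(rng.poisson(expected_events))
            if n_events > 0:
                chans = rng.choice(96, size=n_events, p=spectrum)
                sites, slots = panel.sample_sites(chans, rng)
                for ev in range(n_events):
                    n_extra = int(rng.poisson(config.extra_mutations_per_clone))
                    extra: list[tuple[int, int]] = []
                    if n_extra:
                        ec = rng.choice(96, size=n_extra, p=spectrum)
                        es, esl = panel.sample_sites(ec, rng)
                        extra = list(zip(es.tolist(), esl.tolist()))
                    emit_clone(
                        int(sites[ev]),
                        int(slots[ev]),
                        float(rng.exponential(scale)),
                        extra_sites=extra,
                    )

            # driver clones: excess non-synonymous events per driver gene
            for gene, strength in driver_table.items():
                if gene not in panel.gene_index or strength <= 1.0:
                    continue
                gi = panel.gene_index[gene]
                opp_tot = panel.channel_opportunity().astype(float)
                p_gene_nonsyn = float(
                    spectrum
                    @ (
                        panel.gene_opportunity[gi, :, 1:].sum(axis=1)
                        / np.maximum(opp_tot, 1)
                    )
                )
                lam = (strength - 1.0) * expected_events * mean_muts_per_clone * p_gene_nonsyn
                n_driver = int(rng.poisson(lam))
                placed = 0
                guard = 0
                while placed < n_driver and guard < 200:
                    guard += 1
                    m = max(32, 4 * (n_driver - placed))
                    chans = rng.choice(96, size=m, p=spectrum)
                    sites, slots = panel.sample_sites(chans, rng)
                    ok = (panel.site_gene(sites) == gi) & (
                        panel.cls[sites, slots] != SYN
                    )
                    for st, sl in zip(sites[ok], slots[ok]):
                        if placed >= n_driver:
                            break
                        emit_clone(
                            int(st),
                            int(sl),
                            float(rng.exponential(scale * strength)),
                            is_driver=True,
                        )
                        placed += 1

            # DBS and indel events (class-level realism only)
            for klass, frac in (
                ("DBS", config.dbs_fraction.get(country, 0.0)),
                ("INDEL", config.indel_fraction.get(country, 0.0)),
            ):
                n_k = int(rng.poisson(frac * expected_events * mean_muts_per_clone))
                for _ in range(n_k):
                    area = min(float(rng.exponential(scale)), piece.max_clone_area)
                    cx = rng.random() * piece.width
                    cy = rng.random() * piece.height
                    overlaps = piece.clone_overlaps(cx, cy, area)
                    gi = int(rng.integers(len(panel.genes)))
                    g = panel.genes[gi]
                    local = int(rng.integers(g.seq.size))
                    pos = g.start + local
                    if klass == "DBS":
                        cc_tt = rng.random() < 0.85
                        ref_s, alt_s = ("CC", "TT") if cc_tt else ("CT", "AA")
                        mut_class = "DBS"
                        consequence = "missense" if rng.random() < 0.7 else "synonymous"
                    else:
                        ins = rng.random() < 94 / (94 + 388)
                        mut_class = "INS" if ins else "DEL"
                        ref_s, alt_s = ("A", "AT") if ins else ("AT", "A")
                        consequence = (
                            "indel_frameshift" if rng.random() < 0.8 else "indel_inframe"
                        )
                    clone_counter += 1
                    cid = f"tc{clone_counter:06d}"
                    sample_vafs = {
                        sid: min(0.5, 0.5 * ov / SAMPLE_AREA_MM2)
                        for sid, ov in overlaps.items()
                    }
                    truth_clones.append(
                        TrueClone(
                            clone_id=cid,
                            donor_id=donor.donor_id,
                            piece_id=piece.piece_id,
                            variant_key=(g.chrom, pos, ref_s, alt_s),
                            gene=g.name,
                            consequence=consequence,
                            area_mm2=area,
                            center=(cx, cy),
                            sample_vafs=sample_vafs,
                        )
                    )
                    for sid, vaf_true in sample_vafs.items():
                        alt = int(rng.binomial(config.depth, vaf_true))
                        if alt == 0:
                            continue
                        records.append(
                            MutationRecord(
                                donor_id=donor.donor_id,
                                piece_id=piece.piece_id,
                                sample_id=sid,
                                chrom=g.chrom,
                                pos=pos,
                                ref=ref_s,
                                alt=alt_s,
                                mut_class=mut_class,
                                consequence=consequence,
                                vaf=alt / config.depth,
                                alt_reads=alt,
                                depth=config.depth,
                                gene=g.name,
                                context=None,
                                strand_class="unknown",
                            )
                        )

            # TP53 hotspot spikes
            hotspots = config.hotspot_rates_per_cm2.get(country, {})
            for change, rate in hotspots.items():
                if rate <= 0:
                    continue
                gene, codon, ref_b, alt_b = _HOTSPOT_CHANGES[change]
                lam = rate * (piece_area / 100.0)  # mm^2 -> cm^2
                tp53_strength = driver_table.get(gene, 2.0)
                for _ in range(int(rng.poisson(lam))):
                    st, sl = panel.hotspot_site(gene, codon, ref_b, alt_b)
                    emit_clone(
                        st,
                        sl,
                        float(rng.exponential(scale * tp53_strength)),
                        is_driver=True,
                        is_hotspot=True,
                    )

    truth = GroundTruth(
        burden=burden,
        exposures=exposures,
        clones=truth_clones,
        cna_samples=cna_samples,
        synonymous_footprint_mb=l_syn,
        config=config,
    )
    return donors, samples, records, truth


# ---------------------------------------------------------------------------

def spike_hotspots(
    records: list[MutationRecord],
    samples: list[SampleInfo],
    panel: PanelDef,
    spec: HotspotSpec,
    rng: np.random.Generator,
    clone_area_scale_mm2: float = 0.15,
    depth: int = 700,
) -> list[MutationRecord]:
    """Add codon-level hotspot mutations to an existing record set.

    Each hotspot draws a Poisson count at ``rate * sampled area`` (rates in
    events per cm^2), lands in a uniformly chosen sample and is emitted as a
    single-sample clone with exponential area. Returns a new record list;
    the input is not modified.
    """
    for change in spec.rates_per_cm2:
        if change not in _HOTSPOT_CHANGES:
            raise ValueError(f"unknown hotspot change {change!r}")
        gene, codon, ref_b, alt_b = _HOTSPOT_CHANGES[change]
        panel.hotspot_site(gene, codon, ref_b, alt_b)  # validates codon exists
    out = list(records)
    total_area_cm2 = sum(s.area_mm2 for s in samples) / 100.0
    for change, rate in spec.rates_per_cm2.items():
        if rate <= 0:
            continue
        gene, codon, ref_b, alt_b = _HOTSPOT_CHANGES[change]
        st, sl = panel.hotspot_site(gene, codon, ref_b, alt_b)
        d = panel.describe_site(st, sl)
        n = int(rng.poisson(rate * total_area_cm2))
        for _ in range(n):
            s = samples[int(rng.integers(len(samples)))]
            area = min(float(rng.exponential(clone_area_scale_mm2)), s.area_mm2)
            vaf_true = 0.5 * area / s.area_mm2
            alt = int(rng.binomial(depth, vaf_true))
            alt = max(alt, 1)  # a spiked hotspot is a called mutation
            out.append(
                MutationRecord(
                    donor_id=s.donor_id,
                    piece_id=s.piece_id,
                    sample_id=s.sample_id,
                    chrom=d["chrom"],
                    pos=d["pos"],
                    ref=d["ref"],
                    alt=d["alt"],
                    mut_class="SBS",
                    consequence=d["consequence"],
                    vaf=alt / depth,
                    alt_reads=alt,
                    depth=depth,
                    gene=d["gene"],
                    protein_change=d["protein_change"],
                    context=CHANNELS[d["channel"]],
                    strand_class="unknown",
                )
            )
    return out


# ---------------------------------------------------------------------------
# heterozygous-SNP read counts for the allelic-imbalance module

def generate_snp_counts(
    samples: list[SampleInfo],
    cna_samples: list[tuple[str, str]],
    loci: tuple[str, ...] = ("NOTCH1", "TP53", "NOTCH4", "FGFR2", "RB1"),
    n_snps_per_locus: int = 4,
    depth: int = 700,
    shifted_fraction: float = 0.65,
    seed: int = 0,
) -> list[dict]:
    """Simulated heterozygous-SNP read counts per sample and locus.

    Balanced samples draw ref reads Binomial(depth, 0.5); samples carrying a
    CNA at a locus draw at ``shifted_fraction`` with a random phase sign per
    SNP. Returns rows for the SNP-count table (donor_id, sample_id, snp_id,
    locus, ref_reads, alt_reads).
    """
    rng = np.random.default_rng(seed)
    cna_map = {sid: g for sid, g in cna_samples}
    phase_sign = {}  # (donor, locus, snp) -> +-1, the donor's true phase
    rows = []
    for s in samples:
        for locus in loci:
            for k in range(n_snps_per_locus):
                key = (s.donor_id, locus, k)
                if key not in phase_sign:
                    phase_sign[key] = 1 if rng.random() < 0.5 else -1
                d = int(rng.poisson(depth))
                if d == 0:
                    d = 1
                if cna_map.get(s.sample_id) == locus:
                    f = 0.5 + phase_sign[key] * (shifted_fraction - 0.5)
                else:
                    f = 0.5
                ref_reads = int(rng.binomial(d, f))
                rows.append(
                    {
                        "donor_id": s.donor_id,
                        "sample_id": s.sample_id,
                        "snp_id": f"{locus}_snp{k}",
                        "locus": locus,
                        "ref_reads": ref_reads,
                        "alt_reads": d - ref_reads,
                    }
                )
    return rows
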