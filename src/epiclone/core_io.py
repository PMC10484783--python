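"""Domain records, tabular I/O and the donor-level germline post-filter.

Coordinates are 1-based and fully closed (VCF convention). Trinucleotide
contexts are always reported on the pyrimidine strand. Variant allele
fraction (VAF) is the proportion of sequencing reads carrying the change;
in diploid tissue without copy-number change, 2*VAF approximates the
fraction of cells carrying the mutation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .contexts import parse_context

log = logging.getLogger(__name__)

MUT_CLASSES = {"SBS", "DBS", "INS", "DEL"}
CONSEQUENCES = {
    "synonymous", "missense", "nonsense", "essential_splice",
    "indel_frameshift", "indel_inframe", "noncoding",
}
NONSYNONYMOUS = {
    "missense", "nonsense", "essential_splice", "indel_frameshift", "indel_inframe",
}
STRAND_CLASSES = {"transcribed", "untranscribed", "unknown"}
COUNTRIES = {"UK", "SG"}

MUTATION_COLUMNS = [
    "donor_id", "piece_id", "sample_id", "chrom", "pos", "ref", "alt",
    "mut_class", "gene", "consequence", "protein_change", "context",
    "strand_class", "vaf", "alt_reads", "depth",
]
SAMPLE_COLUMNS = [
    "donor_id", "piece_id", "sample_id", "x_mm", "y_mm", "area_mm2",
    "mean_depth", "cna_excluded",
]
DONOR_COLUMNS = ["donor_id", "country", "age_band", "sex", "total_area_mm2"]


@dataclass(frozen=True)
class MutationRecord:
    """One called somatic variant in one grid sample."""

    donor_id: str
    piece_id: str
    sample_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    mut_class: str
    consequence: str
    vaf: float
    alt_reads: int
    depth: int
    gene: str | None = None
    protein_change: str | None = None
    context: str | None = None
    strand_class: str = "unknown"

    def validate(self) -> None:
        if self.mut_class not in MUT_CLASSES:
            raise ValueError(f"unknown mut_class {self.mut_class!r}")
        if self.consequence not in CONSEQUENCES:
            raise ValueError(f"unknown consequence {self.consequence!r}")
        if self.strand_class not in STRAND_CLASSES:
            raise ValueError(f"unknown strand_class {self.strand_class!r}")
        if not 0.0 <= self.vaf <= 1.0:
            raise ValueError(f"vaf {self.vaf} outside [0, 1]")
        if self.pos < 1:
            raise ValueError(f"pos {self.pos} must be >= 1 (1-based)")
        if self.alt_reads < 0 or self.depth < 0 or self.alt_reads > self.depth:
            raise ValueError(
                f"bad read counts alt={self.alt_reads} depth={self.depth}"
            )
        if self.depth > 0 and abs(self.vaf - self.alt_reads / self.depth) > 1.0 / self.depth:
            raise ValueError(
                f"vaf {self.vaf} inconsistent with {self.alt_reads}/{self.depth}"
            )
        if self.mut_class == "SBS":
            if len(self.ref) != 1 or len(self.alt) != 1:
                raise ValueError("SBS must have single-base ref and alt")
            if self.context is not None:
                five, cref, calt, three = parse_context(self.context)
                # centre of the pyrimidine-normalised context must match
                # ref after normalisation
                from .contexts import COMPLEMENT, PYRIMIDINES
                ref_n = self.ref if self.ref in PYRIMIDINES else COMPLEMENT[self.ref]
                alt_n = self.alt if self.ref in PYRIMIDINES else COMPLEMENT[self.alt]
                if (cref, calt) != (ref_n, alt_n):
                    raise ValueError(
                        f"context {self.context} does not match {self.ref}>{self.alt}"
                    )
        elif self.mut_class == "DBS":
            if len(self.ref) != 2 or len(self.alt) != 2:
                raise ValueError("DBS must have two-base ref and alt")

    @property
    def variant_key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass(frozen=True)
class SampleInfo:
    """One 2-mm^2 grid sample: geometry and sequencing metadata."""

    donor_id: str
    piece_id: str
    sample_id: str
    x_mm: float
    y_mm: float
    area_mm2: float = 2.0
    mean_depth: int = 700
    cna_excluded: bool = False

    def validate(self) -> None:
        if self.area_mm2 <= 0:
            raise ValueError(f"area_mm2 {self.area_mm2} must be positive")
        if self.mean_depth < 0:
            raise ValueError("mean_depth must be nonnegative")


@dataclass(frozen=True)
class DonorMeta:
    donor_id: str
    country: str
    total_area_mm2: float
    age_band: str = ""
    sex: str = ""

    def validate(self) -> None:
        if self.country not in COUNTRIES:
            raise ValueError(f"unknown country {self.country!r}")
        if self.total_area_mm2 <= 0:
            raise ValueError("total_area_mm2 must be positive")


# ---------------------------------------------------------------------------
# tabular I/O

_OPTIONAL_MUT_COLS = {"gene", "protein_change", "context", "strand_class"}


def _clean_optional(v):
    if v is None or (isinstance(v, float) and np.isnan(v)) or v == "":
        return None
    return str(v)


def read_mutation_table(path: str | Path) -> list[MutationRecord]:
    """Read the mutation TSV dialect; validates every row.

    Optional columns (gene, protein_change, context, strand_class) may be
    missing entirely; strand defaults to "unknown". Malformed numeric fields
    or invariant violations raise with the offending row number.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = [c for c in MUTATION_COLUMNS if c not in _OPTIONAL_MUT_COLS]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    records = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # header is line 1
        d = row._asdict()
        try:
            rec = MutationRecord(
                donor_id=d["donor_id"],
                piece_id=d["piece_id"],
                sample_id=d["sample_id"],
                chrom=d["chrom"],
                pos=int(d["pos"]),
                ref=d["ref"],
                alt=d["alt"],
                mut_class=d["mut_class"],
                consequence=d["consequence"],
                vaf=float(d["vaf"]),
                alt_reads=int(d["alt_reads"]),
                depth=int(d["depth"]),
                gene=_clean_optional(d.get("gene")),
                protein_change=_clean_optional(d.get("protein_change")),
                context=_clean_optional(d.get("context")),
                strand_class=_clean_optional(d.get("strand_class")) or "unknown",
            )
            rec.validate()
        except (ValueError, KeyError) as e:
            raise ValueError(f"{path} line {i}: {e}") from e
        records.append(rec)
    return records


def write_mutation_table(records: list[MutationRecord], path: str | Path) -> None:
    df = mutations_to_frame(records)
    df.to_csv(path, sep="\t", index=False)


def mutations_to_frame(records: list[MutationRecord]) -> pd.DataFrame:
    rows = [
        {c: ("" if getattr(r, c) is None else getattr(r, c)) for c in MUTATION_COLUMNS}
        for r in records
    ]
    return pd.DataFrame(rows, columns=MUTATION_COLUMNS)


def read_sample_table(path: str | Path) -> list[SampleInfo]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in SAMPLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    out = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        d = row._asdict()
        try:
            s = SampleInfo(
                donor_id=d["donor_id"],
                piece_id=d["piece_id"],
                sample_id=d["sample_id"],
                x_mm=float(d["x_mm"]),
                y_mm=float(d["y_mm"]),
                area_mm2=float(d["area_mm2"]),
                mean_depth=int(float(d["mean_depth"])),
                cna_excluded=d["cna_excluded"].strip().lower() in {"true", "1", "yes"},
            )
            s.validate()
        except ValueError as e:
            raise ValueError(f"{path} line {i}: {e}") from e
        out.append(s)
    return out


def write_sample_table(samples: list[SampleInfo], path: str | Path) -> None:
    pd.DataFrame([vars(s) for s in samples], columns=SAMPLE_COLUMNS).to_csv(
        path, sep="\t", index=False
    )


def read_donor_table(path: str | Path) -> list[DonorMeta]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in DONOR_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    out = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        d = row._asdict()
        try:
            m = DonorMeta(
                donor_id=d["donor_id"],
                country=d["country"],
                age_band=d["age_band"],
                sex=d["sex"],
                total_area_mm2=float(d["total_area_mm2"]),
            )
            m.validate()
        except ValueError as e:
            raise ValueError(f"{path} line {i}: {e}") from e
        out.append(m)
    return out


def write_donor_table(donors: list[DonorMeta], path: str | Path) -> None:
    pd.DataFrame(
        [
            {c: getattr(d, c) for c in DONOR_COLUMNS}
            for d in donors
        ],
        columns=DONOR_COLUMNS,
    ).to_csv(path, sep="\t", index=False)


def validate_cohort(
    records: list[MutationRecord],
    samples: list[SampleInfo],
    donors: list[DonorMeta],
) -> None:
    """Cross-table consistency: every record's sample exists, every sample's
    donor exists, and donor total areas match the sum of their samples'
    areas to within one sample's area."""
    sample_ids = {s.sample_id for s in samples}
    donor_ids = {d.donor_id for d in donors}
    for r in records:
        if r.sample_id not in sample_ids:
            raise ValueError(f"record references unknown sample {r.sample_id!r}")
    area_by_donor: dict[str, float] = {}
    max_area: dict[str, float] = {}
    for s in samples:
        if s.donor_id not in donor_ids:
            raise ValueError(f"sample {s.sample_id!r} references unknown donor")
        area_by_donor[s.donor_id] = area_by_donor.get(s.donor_id, 0.0) + s.area_mm2
        max_area[s.donor_id] = max(max_area.get(s.donor_id, 0.0), s.area_mm2)
    for d in donors:
        got = area_by_donor.get(d.donor_id, 0.0)
        if abs(got - d.total_area_mm2) > max_area.get(d.donor_id, 2.0):
            raise ValueError(
                f"donor {d.donor_id}: sample areas sum to {got}, "
                f"metadata says {d.total_area_mm2}"
            )


# ---------------------------------------------------------------------------
# germline post-filter

GERMLINE_POOLED_FRACTION = 0.10


def germline_filter(
    records: list[MutationRecord],
    samples: list[SampleInfo] | None = None,
    threshold: float = GERMLINE_POOLED_FRACTION,
) -> tuple[list[MutationRecord], list[MutationRecord]]:
    """Remove putative germline variants.

    For each distinct variant of a donor, reads are pooled over all of that
    donor's samples; the variant is removed from every sample if the pooled
    alt-read fraction is strictly greater than ``threshold`` (default 10%,
    i.e. present in more than 10% of all reads across all samples of a
    single donor). A germline variant is present everywhere at ~50% of
    reads, while even a large somatic clone dilutes to a small pooled
    fraction across a donor's full grid.

    When ``samples`` is given, donor samples without a call for the variant
    contribute their mean depth (and zero alt reads) to the pool, as the
    rule requires; without it only the calling samples' reads are pooled.
    A variant with zero pooled depth is kept with a warning. Returns
    (kept, removed); the filter removes a variant everywhere or nowhere,
    and is idempotent.
    """
    pooled_alt: dict[tuple, int] = {}
    pooled_depth: dict[tuple, int] = {}
    called_samples: dict[tuple, set[str]] = {}
    for r in records:
        key = (r.donor_id,) + r.variant_key
        pooled_alt[key] = pooled_alt.get(key, 0) + r.alt_reads
        pooled_depth[key] = pooled_depth.get(key, 0) + r.depth
        called_samples.setdefault(key, set()).add(r.sample_id)
    if samples is not None:
        depth_by_donor: dict[str, list[tuple[str, int]]] = {}
        for s in samples:
            depth_by_donor.setdefault(s.donor_id, []).append(
                (s.sample_id, s.mean_depth)
            )
        for key in pooled_depth:
            donor = key[0]
            called = called_samples[key]
            for sid, d in depth_by_donor.get(donor, []):
                if sid not in called:
                    pooled_depth[key] += d
    kept, removed = [], []
    for r in records:
        key = (r.donor_id,) + r.variant_key
        depth = pooled_depth[key]
        if depth == 0:
            warnings.warn(
                f"variant {r.variant_key} of donor {r.donor_id} has zero pooled "
                "depth; kept",
                stacklevel=2,
            )
            kept.append(r)
        elif pooled_alt[key] / depth > threshold:
            removed.append(r)
        else:
            kept.append(r)
    return kept, removed


# ---------------------------------------------------------------------------
# VCF export (minimal VCF 4.2; one donor per file)

_VCF_INFO_FIELDS = [
    ("SAMPLE", "String", "Grid sample identifier"),
    ("PIECE", "String", "Epidermis piece identifier"),
    ("DONOR", "String", "Donor identifier"),
    ("VAF", "String", "Variant allele fraction (full precision)"),
    ("ALT_READS", "Integer", "Reads supporting the variant"),
    ("DEPTH", "Integer", "Total read depth"),
    ("MUTCLASS", "String", "Mutation class"),
    ("CSQ", "String", "gene|consequence|protein_change|context|strand_class"),
]


def write_vcf(records: list[MutationRecord], path: str | Path) -> None:
    """Write records from one donor as a minimal VCF 4.2 file."""
    donors = {r.donor_id for r in records}
    if len(donors) > 1:
        raise ValueError(f"write_vcf expects a single donor, got {sorted(donors)}")
    contigs = sorted({r.chrom for r in records})
    lines = ["##fileformat=VCFv4.2", "##source=epiclone"]
    for c in contigs:
        lines.append(f"##contig=<ID={c}>")
    for key, typ, desc in _VCF_INFO_FIELDS:
        lines.append(
            f'##INFO=<ID={key},Number=1,Type={typ},Description="{desc}">'
        )
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")
    for r in sorted(records, key=lambda r: (r.chrom, r.pos, r.sample_id)):
        csq = "|".join(
            x if x is not None else ""
            for x in (r.gene, r.consequence, r.protein_change, r.context, r.strand_class)
        )
        info = (
            f"SAMPLE={r.sample_id};PIECE={r.piece_id};DONOR={r.donor_id};"
            f"VAF={r.vaf!r};ALT_READS={r.alt_reads};DEPTH={r.depth};"
            f"MUTCLASS={r.mut_class};CSQ={csq}"
        )
        lines.append(
            f"{r.chrom}\t{r.pos}\t.\t{r.ref}\t{r.alt}\t.\tPASS\t{info}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_vcf(path: str | Path) -> list[MutationRecord]:
    """Read a VCF written by :func:`write_vcf` back into records."""
    import pysam

    out = []
    with pysam.VariantFile(str(path)) as vf:
        for v in vf:
            info = v.info
            gene, consequence, protein_change, context, strand = (
                str(info["CSQ"]).split("|")
            )
            out.append(
                MutationRecord(
                    donor_id=str(info["DONOR"]),
                    piece_id=str(info["PIECE"]),
                    sample_id=str(info["SAMPLE"]),
                    chrom=v.chrom,
                    pos=v.pos,
                    ref=v.ref,
                    alt=v.alts[0],
                    mut_class=str(info["MUTCLASS"]),
                    consequence=consequence,
                    vaf=float(str(info["VAF"])),
                    alt_reads=int(info["ALT_READS"]),
                    depth=int(info["DEPTH"]),
                    gene=gene or None,
                    protein_change=protein_change or None,
                    context=context or None,
                    strand_class=strand or "unknown",
                )
            )
    return out
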