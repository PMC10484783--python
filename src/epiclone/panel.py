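"""Gene panel with per-site coding models.

The targeted bait set covers the exons of 74 genes recurrently mutated in
cutaneous squamous cell carcinoma. For burden and selection inference we
need, for every coding site and every possible base change: the trinucleotide
context channel (pyrimidine-centred) and the coding consequence (synonymous,
missense or nonsense). Real coding sequences are controlled inputs; by
default the panel carries synthetic coding sequences (random non-stop
codons, reproducible from a fixed seed) with real protein lengths for the
known driver genes, which preserves every statistical property the analyses
rely on: per-channel opportunity, synonymous fractions, and codon-level
hotspot bookkeeping.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

# base encoding A=0, C=1, G=2, T=3; complement is 3 - b
_BASES = "ACGT"

# standard genetic code over codon index 16*b0 + 4*b1 + b2 (ACGT order)
_TCAG = "TCAG"
_AA_TCAG = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
_CODON_AA = np.zeros(64, dtype="U1")
for _i0, _b0 in enumerate(_TCAG):
    for _i1, _b1 in enumerate(_TCAG):
        for _i2, _b2 in enumerate(_TCAG):
            _idx = 16 * _BASES.index(_b0) + 4 * _BASES.index(_b1) + _BASES.index(_b2)
            _CODON_AA[_idx] = _AA_TCAG[16 * _i0 + 4 * _i1 + _i2]

_STOP_CODONS = np.flatnonzero(_CODON_AA == "*")
_NONSTOP_CODONS = np.flatnonzero(_CODON_AA != "*")

SYN, MIS, NON = 0, 1, 2
CONSEQUENCE_OF_CLASS = {SYN: "synonymous", MIS: "missense", NON: "nonsense"}

# genes in the targeted capture; drivers carry their real protein lengths
PANEL_GENES = (
    "ADAM29", "ADAMTS18", "AJUBA", "AKT1", "AKT2", "APOB", "ARID1A", "ARID2",
    "AURKA", "ADGRB3", "BRAF", "CASP8", "CCND1", "CDH1", "CDKN2A", "CR2",
    "CREBBP", "CUL3", "DICER1", "EGFR", "EPHA2", "ERBB2", "ERBB3", "ERBB4",
    "EZH2", "FAT1", "FAT4", "FBXW7", "FGFR1", "FGFR2", "FGFR3", "FLG2",
    "GRIN2A", "GRM3", "HRAS", "IRF6", "KCNH5", "KEAP1", "KMT2A", "KMT2C",
    "KMT2D", "KRAS", "MET", "MTOR", "MUC17", "NF1", "NFE2L2", "NOTCH1",
    "NOTCH2", "NOTCH3", "NOTCH4", "NRAS", "NSD1", "PIK3CA", "PLCB1",
    "PPP1R3A", "PREX2", "PTCH1", "PTEN", "RB1", "RBM10", "SALL1", "SCN11A",
    "SCN1A", "SETD2", "SMAD4", "SMO", "SOX2", "SPHKAP", "SUFU", "TP53",
    "TP63", "TRIOBP", "ZNF750",
)

_KNOWN_LENGTHS = {
    "TP53": 393, "NOTCH1": 2555, "NOTCH2": 2471, "NOTCH3": 2321,
    "NOTCH4": 2003, "FAT1": 4588, "FAT4": 4981, "ARID2": 1835, "AJUBA": 538,
    "CDKN2A": 156, "RB1": 928, "FGFR2": 821, "FGFR3": 806, "KRAS": 189,
    "NRAS": 189, "HRAS": 189, "PIK3CA": 1068, "PTEN": 403, "EGFR": 1210,
    "KMT2D": 5537, "MUC17": 4493, "APOB": 4563,
}

_ARG_CGG = 16 * 1 + 4 * 2 + 2  # CGG, arginine; C>T at offset 0 gives TGG (Trp)

_DEFAULT_PANEL_SEED = 7331


@dataclass
class GeneModel:
    """One gene's coding model: sequence, strand and genomic anchor."""

    name: str
    seq: np.ndarray  # int8 codes, coding sequence only
    chrom: str
    start: int  # 1-based genomic position of the first coding base
    strand: str = "+"

    @property
    def n_codons(self) -> int:
        return self.seq.size // 3


@dataclass
class PanelDef:
    """Panel of gene models plus precomputed per-site mutation bookkeeping.

    Arrays are concatenated over genes in panel order; ``gene_offsets[i]`` is
    the first global site index of gene ``i``. For each site ``s`` and each
    of its three alternative bases ``k`` (in ACGT order skipping the
    reference), ``cls[s, k]`` is the consequence class, ``chan[s, k]`` the
    96-channel index and ``aa_alt[s, k]`` the resulting amino acid.
    """

    genes: list[GeneModel]
    total_footprint_mb: float = 0.67
    exonic_footprint_mb: float = field(default=0.0)

    # derived, filled by _build()
    gene_index: dict[str, int] = field(default_factory=dict, repr=False)
    gene_offsets: np.ndarray = field(default=None, repr=False)
    seq_all: np.ndarray = field(default=None, repr=False)
    cls: np.ndarray = field(default=None, repr=False)
    chan: np.ndarray = field(default=None, repr=False)
    alt_base: np.ndarray = field(default=None, repr=False)
    aa_ref: np.ndarray = field(default=None, repr=False)
    aa_alt: np.ndarray = field(default=None, repr=False)
    opportunity: np.ndarray = field(default=None, repr=False)  # (96, 3)
    gene_opportunity: np.ndarray = field(default=None, repr=False)  # (G, 96, 3)

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError("panel must contain at least one gene")
        if self.total_footprint_mb <= 0:
            raise ValueError("total_footprint_mb must be positive")
        self._build()
        if self.exonic_footprint_mb == 0.0:
            self.exonic_footprint_mb = self.n_sites / 1e6
        if self.exonic_footprint_mb <= 0:
            raise ValueError("exonic_footprint_mb must be positive")

    # -- construction -----------------------------------------------------

    def _build(self) -> None:
        self.gene_index = {g.name: i for i, g in enumerate(self.genes)}
        lengths = np.array([g.seq.size for g in self.genes])
        self.gene_offsets = np.concatenate([[0], np.cumsum(lengths)])
        self.seq_all = np.concatenate([g.seq for g in self.genes]).astype(np.int8)
        n = self.seq_all.size

        # flanks: within a gene use true neighbours; at gene ends use a
        # deterministic pseudo-flank so every site has a context
        five = np.empty(n, dtype=np.int8)
        three = np.empty(n, dtype=np.int8)
        five[1:] = self.seq_all[:-1]
        three[:-1] = self.seq_all[1:]
        for i, g in enumerate(self.genes):
            a, b = self.gene_offsets[i], self.gene_offsets[i + 1]
            five[a] = (self.seq_all[a] + 1) % 4
            three[b - 1] = (self.seq_all[b - 1] + 2) % 4

        ref = self.seq_all.astype(np.int16)
        # three alternative bases per site, ACGT order with ref removed
        alts = np.empty((n, 3), dtype=np.int16)
        allb = np.arange(4, dtype=np.int16)
        for k in range(3):
            # k-th base of ACGT after skipping ref
            alts[:, k] = np.where(allb[k] < ref, allb[k], allb[k] + 1)
        self.alt_base = alts.astype(np.int8)

        # consequence classes
        offset = np.empty(n, dtype=np.int64)
        codon_of = np.empty(n, dtype=np.int64)
        for i, g in enumerate(self.genes):
            a, b = self.gene_offsets[i], self.gene_offsets[i + 1]
            local = np.arange(b - a)
            offset[a:b] = local % 3
            codon_of[a:b] = local // 3
        pv = np.select([offset == 0, offset == 1], [16, 4], default=1)
        codon_start = np.arange(n) - offset
        codon_idx = (
            16 * self.seq_all[codon_start].astype(np.int64)
            + 4 * self.seq_all[codon_start + 1]
            + self.seq_all[codon_start + 2]
        )
        self.aa_ref = _CODON_AA[codon_idx]
        new_idx = codon_idx[:, None] + (alts - ref[:, None]) * pv[:, None]
        self.aa_alt = _CODON_AA[new_idx]
        self.cls = np.where(
            self.aa_alt == self.aa_ref[:, None],
            SYN,
            np.where(self.aa_alt == "*", NON, MIS),
        ).astype(np.int8)
        self.codon_number = (codon_of + 1).astype(np.int64)

        # channels, pyrimidine-normalised
        is_pyr = (ref == 1) | (ref == 3)
        f = np.where(is_pyr, five, 3 - three)
        t = np.where(is_pyr, three, 3 - five)
        r = np.where(is_pyr, ref, 3 - ref)
        a_ = np.where(is_pyr[:, None], alts, 3 - alts)
        sub = np.empty((n, 3), dtype=np.int16)
        c_ref = r[:, None] == 1
        sub[:] = np.where(
            c_ref,
            np.where(a_ == 0, 0, np.where(a_ == 2, 1, 2)),
            np.where(a_ == 0, 3, np.where(a_ == 1, 4, 5)),
        )
        self.chan = (sub * 16 + f[:, None] * 4 + t[:, None]).astype(np.int16)

        # opportunity tables
        G = len(self.genes)
        self.gene_opportunity = np.zeros((G, 96, 3), dtype=np.int64)
        gene_id = np.repeat(np.arange(G), lengths)
        np.add.at(
            self.gene_opportunity,
            (gene_id[:, None], self.chan.astype(np.int64), self.cls.astype(np.int64)),
            1,
        )
        self.opportunity = self.gene_opportunity.sum(axis=0)
        self.gene_id = gene_id.astype(np.int16)

        # sampling index: (site, alt-slot) pairs sorted by channel
        flat_ch = self.chan.ravel()
        order = np.argsort(flat_ch, kind="stable")
        self._sorted_pairs = order
        self._chan_offsets = np.searchsorted(flat_ch[order], np.arange(97))

    # -- queries -----------------------------------------------------------

    @property
    def n_sites(self) -> int:
        return self.seq_all.size

    @property
    def gene_names(self) -> list[str]:
        return [g.name for g in self.genes]

    def channel_opportunity(self) -> np.ndarray:
        """Total number of possible (site, alt) pairs per channel, shape (96,)."""
        return self.opportunity.sum(axis=1)

    def synonymous_fraction(self, spectrum: np.ndarray) -> float:
        """Spectrum-weighted fraction of possible coding changes that are synonymous.

        ``spectrum`` is a normalised 96-vector; channels with zero panel
        opportunity are dropped and the spectrum renormalised over the rest.
        """
        spectrum = np.asarray(spectrum, dtype=float)
        tot = self.channel_opportunity().astype(float)
        ok = tot > 0
        w = spectrum[ok] / spectrum[ok].sum()
        syn_share = self.opportunity[ok, SYN] / tot[ok]
        f = float(w @ syn_share)
        if f <= 0:
            raise ValueError("panel has no synonymous opportunity under this spectrum")
        return f

    def synonymous_footprint_mb(self, spectrum: np.ndarray) -> float:
        return self.exonic_footprint_mb * self.synonymous_fraction(spectrum)

    def sample_sites(self, channels: np.ndarray, rng: np.random.Generator):
        """Draw one uniform (site, alt-slot) pair for each requested channel.

        Returns (site_idx, alt_slot) arrays aligned with ``channels``.
        """
        channels = np.asarray(channels)
        lo = self._chan_offsets[channels]
        hi = self._chan_offsets[channels + 1]
        if np.any(hi == lo):
            bad = channels[hi == lo]
            raise ValueError(f"panel has no opportunity in channel(s) {bad[:5]}")
        pick = lo + rng.integers(0, hi - lo)
        flat = self._sorted_pairs[pick]
        return flat // 3, (flat % 3).astype(np.int64)

    def site_gene(self, site_idx: np.ndarray) -> np.ndarray:
        return self.gene_id[site_idx]

    def describe_site(self, site: int, alt_slot: int) -> dict:
        """Human-readable description of one possible change at a site."""
        g = self.genes[int(self.gene_id[site])]
        local = site - int(self.gene_offsets[self.gene_index[g.name]])
        codon = int(self.codon_number[site])
        ref_b = _BASES[self.seq_all[site]]
        alt_b = _BASES[self.alt_base[site, alt_slot]]
        aa_r = str(self.aa_ref[site])
        aa_a = str(self.aa_alt[site, alt_slot])
        return {
            "gene": g.name,
            "chrom": g.chrom,
            "pos": g.start + local,
            "ref": ref_b,
            "alt": alt_b,
            "codon": codon,
            "consequence": CONSEQUENCE_OF_CLASS[int(self.cls[site, alt_slot])],
            "protein_change": f"{aa_r}{codon}{aa_a}",
            "channel": int(self.chan[site, alt_slot]),
        }

    def hotspot_site(self, gene: str, codon: int, ref: str, alt: str) -> tuple[int, int]:
        """Global (site, alt_slot) for a specific codon change, e.g. TP53 R248W.

        Searches the codon's three positions for a change producing the
        requested ref>alt bases; raises if the codon does not exist.
        """
        if gene not in self.gene_index:
            raise ValueError(f"gene {gene!r} not in panel")
        gi = self.gene_index[gene]
        if codon < 1 or codon > self.genes[gi].n_codons:
            raise ValueError(f"codon {codon} outside {gene} ({self.genes[gi].n_codons} codons)")
        base0 = int(self.gene_offsets[gi]) + 3 * (codon - 1)
        ref_i, alt_i = _BASES.index(ref), _BASES.index(alt)
        for s in range(base0, base0 + 3):
            if self.seq_all[s] != ref_i:
                continue
            for k in range(3):
                if self.alt_base[s, k] == alt_i:
                    return s, k
        raise ValueError(f"no {ref}>{alt} change available in {gene} codon {codon}")


def _random_coding_sequence(n_codons: int, rng: np.random.Generator) -> np.ndarray:
    codons = rng.choice(_NONSTOP_CODONS, size=n_codons)
    seq = np.empty(3 * n_codons, dtype=np.int8)
    seq[0::3] = codons // 16
    seq[1::3] = (codons // 4) % 4
    seq[2::3] = codons % 4
    return seq


def synthesize_panel(
    gene_names: tuple[str, ...] = PANEL_GENES,
    total_codons: int = 110_000,
    seed: int = _DEFAULT_PANEL_SEED,
    total_footprint_mb: float = 0.67,
) -> PanelDef:
    """Build the default synthetic panel, reproducible from ``seed``.

    Driver genes get their real protein lengths; the remaining genes receive
    random lengths rescaled so the exonic footprint is ~3*total_codons bases.
    TP53 codons 248 and 282 are forced to arginine (CGG) so the recurrent
    R248W / R282W changes exist as C>T transitions.
    """
    rng = np.random.default_rng(seed)
    known = {g: _KNOWN_LENGTHS[g] for g in gene_names if g in _KNOWN_LENGTHS}
    free = [g for g in gene_names if g not in known]
    remaining = total_codons - sum(known.values())
    if remaining < 300 * len(free):
        raise ValueError("total_codons too small for this gene list")
    raw = rng.lognormal(mean=0.0, sigma=0.6, size=len(free))
    sizes = np.maximum(300, (raw / raw.sum() * remaining).astype(int))
    lengths = dict(known)
    lengths.update(dict(zip(free, sizes)))

    genes: list[GeneModel] = []
    chrom_cursor: dict[str, int] = {}
    for i, name in enumerate(gene_names):
        n_codons = int(lengths[name])
        seq = _random_coding_sequence(n_codons, rng)
        if name == "TP53":
            for codon in (248, 282):
                c0 = 3 * (codon - 1)
                seq[c0] = 1  # C
                seq[c0 + 1] = 2  # G
                seq[c0 + 2] = 2  # G
        chrom = f"chr{i % 22 + 1}"
        start = chrom_cursor.get(chrom, 1_000_000)
        chrom_cursor[chrom] = start + 3 * n_codons + 1_000_000
        genes.append(GeneModel(name=name, seq=seq, chrom=chrom, start=start))
    return PanelDef(genes=genes, total_footprint_mb=total_footprint_mb)


@lru_cache(maxsize=2)
def default_panel() -> PanelDef:
    """The packaged default panel (cached; ~0.33 Mb exonic)."""
    return synthesize_panel()


@lru_cache(maxsize=2)
def small_panel() -> PanelDef:
    """A reduced panel (~20 kb) for fast unit tests."""
    names = ("TP53", "NOTCH1", "NOTCH2", "FAT1", "AJUBA", "ARID2", "NOTCH3", "KRAS")
    return synthesize_panel(gene_names=names, total_codons=15_000, seed=11)
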