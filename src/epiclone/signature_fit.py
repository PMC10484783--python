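"""96-channel mutation catalogs and reference-signature refitting.

Signature exposures are estimated by refitting a fixed reference matrix to
an observed catalog with nonnegative least squares (NNLS): with reference
R (96 x K, column-stochastic) and normalised catalog y, solve
``min ||y - R w||_2  s.t.  w >= 0`` and renormalise w to sum to one. This is
the well-posed desk-scale equivalent of running a full NMF decomposition
when the reference signatures are fixed inputs.

Donor-level exposure vectors are compared by average-linkage hierarchical
clustering on Euclidean distance, with an ordinary bootstrap (resample each
scope's mutations, refit, recluster) reporting how often each cluster
recurs.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.optimize import nnls

from .contexts import CHANNELS, channel_of, is_dipyrimidine_ct
from .core_io import MutationRecord

log = logging.getLogger(__name__)

MIN_CATALOG_MUTATIONS = 100


@dataclass
class SignatureMatrix:
    """Column-stochastic 96 x K reference, channels in COSMIC order."""

    matrix: np.ndarray
    labels: list[str]

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape != (96, len(self.labels)):
            raise ValueError(
                f"matrix shape {self.matrix.shape} does not match {len(self.labels)} labels"
            )
        if np.any(self.matrix < 0):
            raise ValueError("reference signatures must be nonnegative")
        sums = self.matrix.sum(axis=0)
        if np.any(np.abs(sums - 1.0) > 1e-6):
            raise ValueError(f"reference columns must sum to 1, got {sums}")

    @property
    def n_signatures(self) -> int:
        return len(self.labels)

    def mixture_spectrum(self, weights: dict[str, float]) -> np.ndarray:
        """96-channel probability vector for a mixture of the columns."""
        w = np.zeros(self.n_signatures)
        for name, val in weights.items():
            if name not in self.labels:
                raise KeyError(f"unknown signature {name!r}")
            w[self.labels.index(name)] = val
        if w.sum() <= 0:
            raise ValueError("mixture weights must have positive sum")
        return self.matrix @ (w / w.sum())


def load_signature_matrix(path: str | Path) -> SignatureMatrix:
    """Load a COSMIC-format reference TSV (96 labelled rows, one column per
    signature); rows are reordered into canonical channel order."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    try:
        df = df.loc[list(CHANNELS)]
    except KeyError as e:
        raise ValueError(f"{path}: missing channel rows ({e})") from e
    return SignatureMatrix(df.to_numpy(), list(df.columns))


def packaged_reference_signatures() -> SignatureMatrix:
    """The packaged synthetic reference set: six signature-shaped columns
    (SBS1/SBS5 aging-like, SBS7a-d UV-like), mutually distinguishable
    (pairwise cosine < 0.9). Stands in for the PCAWG reference signatures,
    which are external data; a real COSMIC TSV can be loaded with
    :func:`load_signature_matrix` instead."""
    ref = resources.files("epiclone.data") / "synthetic_reference_signatures.tsv"
    with resources.as_file(ref) as p:
        return load_signature_matrix(p)


# ---------------------------------------------------------------------------
# catalogs

@dataclass
class Catalog96:
    counts: np.ndarray
    scope: str
    n_excluded_no_context: int = 0
    min_mutations: int = MIN_CATALOG_MUTATIONS

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (96,):
            raise ValueError("catalog must have 96 channels")
        if np.any(self.counts < 0):
            raise ValueError("catalog counts must be nonnegative")

    @property
    def n_mutations(self) -> int:
        return int(self.counts.sum())

    @property
    def usable(self) -> bool:
        """Scopes with too few variants are excluded from signature fitting
        (mirrors dropping samples with fewer than 100 variants)."""
        return self.n_mutations >= self.min_mutations

    def normalised(self) -> np.ndarray:
        if self.n_mutations == 0:
            raise ValueError(f"catalog {self.scope!r} is empty")
        return self.counts / self.n_mutations


def build_catalog(
    records: list[MutationRecord],
    scope: str,
    min_mutations: int = MIN_CATALOG_MUTATIONS,
) -> Catalog96:
    """Count context-bearing SBS records into the 96 channels.

    SBS records without a context are excluded from the catalog (but
    retained everywhere else in the pipeline); the excluded count is logged
    and carried on the catalog.
    """
    counts = np.zeros(96, dtype=np.int64)
    skipped = 0
    for r in records:
        if r.mut_class != "SBS":
            continue
        if r.context is None:
            skipped += 1
            continue
        counts[channel_of(r.context)] += 1
    if skipped:
        log.info("catalog %s: %d SBS without context excluded", scope, skipped)
    return Catalog96(counts, scope, n_excluded_no_context=skipped,
                     min_mutations=min_mutations)


# ---------------------------------------------------------------------------
# exposures

@dataclass
class Exposures:
    scope: str
    weights: dict[str, float]
    n_mutations: int
    residual: float

    def as_vector(self, labels: list[str]) -> np.ndarray:
        return np.array([self.weights[l] for l in labels])


def fit_exposures(catalog: Catalog96, reference: SignatureMatrix) -> Exposures:
    """NNLS refit of the reference to a catalog; weights renormalised to 1."""
    y = catalog.normalised()
    w, resid = nnls(reference.matrix, y)
    total = w.sum()
    if total <= 0:
        # catalog orthogonal to every signature; fall back to uniform
        warnings.warn(f"catalog {catalog.scope!r}: NNLS returned all-zero weights")
        w = np.full(reference.n_signatures, 1.0 / reference.n_signatures)
    else:
        w = w / total
    return Exposures(
        scope=catalog.scope,
        weights=dict(zip(reference.labels, w.tolist())),
        n_mutations=catalog.n_mutations,
        residual=float(resid),
    )


def uv_fraction(exposures: Exposures) -> float:
    """Summed exposure of UV signatures (labels starting with 'SBS7')."""
    return float(sum(v for k, v in exposures.weights.items() if k.startswith("SBS7")))


# ---------------------------------------------------------------------------
# DBS classes and transcriptional strand bias

@dataclass
class DbsStrandSummary:
    n_dbs: int
    cc_tt_fraction: float | None
    n_transcribed: int
    n_untranscribed: int
    strand_ratio: float | None


def dbs_and_strand_summary(records: list[MutationRecord]) -> DbsStrandSummary:
    """CC>TT share of DBS and the transcribed/untranscribed ratio of C>T
    SBS at dipyrimidine contexts (records with unknown strand excluded).

    GG>AA double substitutions are the same event read on the opposite
    strand and count as CC>TT.
    """
    n_dbs = 0
    n_cctt = 0
    n_tr = 0
    n_un = 0
    for r in records:
        if r.mut_class == "DBS":
            n_dbs += 1
            if (r.ref, r.alt) in {("CC", "TT"), ("GG", "AA")}:
                n_cctt += 1
        elif r.mut_class == "SBS" and r.context and is_dipyrimidine_ct(r.context):
            if r.strand_class == "transcribed":
                n_tr += 1
            elif r.strand_class == "untranscribed":
                n_un += 1
    ratio: float | None
    if n_un == 0:
        if n_tr > 0:
            warnings.warn("no untranscribed-strand C>T calls; strand ratio undefined")
        ratio = None
    else:
        ratio = n_tr / n_un
    return DbsStrandSummary(
        n_dbs=n_dbs,
        cc_tt_fraction=(n_cctt / n_dbs) if n_dbs else None,
        n_transcribed=n_tr,
        n_untranscribed=n_un,
        strand_ratio=ratio,
    )


# ---------------------------------------------------------------------------
# exposure clustering with ordinary bootstrap

@dataclass
class ClusterResult:
    scopes: list[str]
    linkage: np.ndarray
    clusters: list[frozenset[str]]
    support: dict[frozenset[str], float]
    n_boot: int


def _leaf_sets(Z: np.ndarray, labels: list[str]) -> list[frozenset[str]]:
    n = len(labels)
    members: dict[int, frozenset[str]] = {i: frozenset([labels[i]]) for i in range(n)}
    out = []
    for i, (a, b, _d, _c) in enumerate(Z):
        merged = members[int(a)] | members[int(b)]
        members[n + i] = merged
        out.append(merged)
    return out


def cluster_exposures(
    catalogs: dict[str, Catalog96],
    reference: SignatureMatrix,
    n_boot: int = 10_000,
    seed: int = 0,
) -> ClusterResult:
    """Average-linkage clustering of per-scope exposure vectors with an
    ordinary bootstrap.

    Each bootstrap replicate resamples every scope's mutations from its own
    catalog (multinomial), refits exposures by NNLS and reclusters; the
    support of a cluster is the fraction of replicates in which exactly the
    same leaf set appears. This replaces multiscale (AU) bootstrap p-values
    with plain bootstrap proportions.
    """
    if len(catalogs) < 3:
        raise ValueError("need at least 3 scopes to cluster")
    if n_boot < 100:
        warnings.warn(f"n_boot={n_boot} is small; support estimates will be coarse")
    scopes = sorted(catalogs)
    labels = reference.labels

    def exposure_matrix(counts_by_scope: dict[str, np.ndarray]) -> np.ndarray:
        rows = []
        for s in scopes:
            cat = Catalog96(counts_by_scope[s], s, min_mutations=0)
            rows.append(fit_exposures(cat, reference).as_vector(labels))
        return np.vstack(rows)

    base_counts = {s: catalogs[s].counts for s in scopes}
    E = exposure_matrix(base_counts)
    if np.allclose(E, E[0]):
        # identical exposures: single zero-height cluster
        Z = hierarchy.linkage(E, method="average", metric="euclidean")
        clusters = _leaf_sets(Z, scopes)
        return ClusterResult(scopes, Z, clusters, {c: 1.0 for c in clusters}, 0)
    Z = hierarchy.linkage(E, method="average", metric="euclidean")
    clusters = _leaf_sets(Z, scopes)

    rng = np.random.default_rng(seed)
    hits = {c: 0 for c in clusters}
    for _ in range(n_boot):
        counts_b = {}
        for s in scopes:
            n = catalogs[s].n_mutations
            counts_b[s] = rng.multinomial(n, catalogs[s].normalised())
        Eb = exposure_matrix(counts_b)
        Zb = hierarchy.linkage(Eb, method="average", metric="euclidean")
        seen = set(_leaf_sets(Zb, scopes))
        for c in clusters:
            if c in seen:
                hits[c] += 1
    support = {c: hits[c] / n_boot for c in clusters}
    return ClusterResult(scopes, Z, clusters, support, n_boot)
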