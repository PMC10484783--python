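# Methods and design notes

This note records the models behind each pipeline stage, the defaults and
why they were chosen, what the synthetic cohort does and does not emulate,
and the numerical choices a maintainer would want to know.

## Study design being modelled

Each donor contributes contiguous pieces of facial epidermis cut into a
grid of 2 × 1 mm samples (2 mm² each), deep-sequenced (~700×) over a
74-gene bait panel (0.67 Mb total, 0.33 Mb exonic). A mutant clone is a
patch of cells sharing a somatic variant; its footprint in a sample is
measured by the variant allele fraction (VAF), and 2·VAF approximates the
mutant-cell fraction in diploid tissue. The cohort defaults are five
Singaporean and six UK donors with the published sampled areas and
genome-wide burden estimates (which make 428 samples in total, 191 of them
Singaporean).

## Synthetic cohort generator

The real data are controlled-access, so every stage is exercised against a
generator whose defaults encode the study conditions:

- **Geometry.** Pieces are grids of up to 4 × 4 samples. Clones are discs
  (64-gon polygons whose area equals the drawn clone area exactly) placed
  on a per-piece torus, so no clone mass is lost at edges and the burden
  calibration below is exact. A clone's true VAF in a sample is
  0.5 × overlap / sample area.
- **Clone sizes.** Exponential area law. The scale differs by country
  (0.116 mm² UK, 0.148 mm² SG), chosen so mean clone size (summed VAF)
  matches the observed 0.029 / 0.037 contrast. The generator does not
  simulate competition between clones; the Moran module supplies the
  mechanism for that contrast, and the generator's defaults encode its
  outcome. Driver clones scale the area by the gene's selection strength.
- **Burden calibration.** The per-piece expected number of mutation
  events is `burden × exonic_Mb × piece_area / (mean clone area ×
  mean mutations per clone)`, which makes the expected per-cell mutation
  count in the exonic bait equal `burden × exonic_Mb` — the quantity the
  synonymous-site estimator divides out. Contexts are drawn from the
  country's signature mixture and sites uniformly within the drawn
  channel, so the realised synonymous fraction equals the panel's
  spectrum-weighted synonymous opportunity by construction.
- **Spectra.** UK: SBS7a–d total 0.66 (UV-dominant); SG: SBS1+SBS5 total
  0.64 (aging-dominant), per the published attribution. DBS are emitted at
  class level only (85% CC>TT), indels likewise; C>T at dipyrimidine
  contexts get a transcribed:untranscribed ratio of 52.7.
- **Drivers, hotspots, CNA.** Per-gene selection strengths multiply both
  the non-synonymous event rate and the clone-area scale, with TP53
  stronger in the UK and NOTCH1/NOTCH2 stronger in Singapore. TP53 R248W
  and R282W are spiked at 3.2 and 2.5 events per cm² in the UK only.
  Samples carry a CNA with probability 0.13 (UK) / 0.01 (SG), mostly
  NOTCH1 LOH; affected-gene allele fractions double in those samples and
  the samples are flagged.
- **Read noise.** Alt reads are Binomial(depth, allele fraction) at fixed
  depth 700; records with zero alt reads are not emitted (undetectable).

Not emulated: realistic genomic coordinates (genes get synthetic coding
sequences with real protein lengths for the drivers), indel/DBS spectra,
sequencing error and calling artefacts, germline contamination, and
UV-dose gradients within a donor. Passing recovery tests therefore shows
the estimators are correct under the stated generative model, not that
they are robust to real-data artefacts.

## Panel and coding models

Synthetic coding sequences are random non-stop codons, reproducible from a
fixed seed; TP53 codons 248/282 are forced to CGG so the recurrent R248W /
R282W changes exist as C>T transitions. For every site and alternative
base the panel precomputes the 96-channel context (pyrimidine-centred) and
consequence (synonymous / missense / nonsense), giving exact per-channel
opportunity tables. A real CDS file can replace the synthetic sequences
without touching the downstream code.

## Estimators

- **Burden.** Per sample `Σ_syn 2·VAF / L_syn`, donor value an
  area-weighted mean over CNA-free samples (areas are equal by default, so
  a plain mean — the aggregation is a package choice). `L_syn` is the
  exonic footprint times the spectrum-weighted synonymous fraction; using
  the spectrum matters because a UV-skewed spectrum changes the synonymous
  opportunity. Zero synonymous counts give a burden of 0; a donor with all
  samples CNA-flagged gets a null estimate.
- **Percent mutant.** Upper bound caps each sample at 100% before
  averaging; the lower bound uses only the per-sample maximum. Clones
  spanning samples contribute their per-sample VAFs, not their summed VAF.
- **Clone merging.** The 10-mm rule is applied as single-linkage
  transitive closure so a long run of adjacent samples merges into one
  clone even though its extremes are >10 mm apart (a known large clone
  spans sixteen 2-mm² samples); whether the original rule was pairwise or
  closure-based is not stated, closure is this package's documented
  choice. Cross-piece merging never happens. Duplicate listings of a
  variant in one sample collapse with summed reads.
- **Nesting.** B nests under A iff B's samples ⊆ A's and
  `VAF_B ≤ VAF_A × 1.25` in every shared sample (the 25% tolerance absorbs
  read noise); the smallest containing clone wins, ties break toward the
  smaller clone as child. In dense tissue a single-sample clone has many
  admissible parents and the choice is genuinely ambiguous; the
  ground-truth recovery test is therefore run in a sparse, large-clone,
  deep-coverage regime where nesting is identifiable (≥90% recovered).
- **Signatures.** NNLS refitting replaces a full NMF decomposition: the
  references are fixed inputs, so refitting is the well-posed desk-scale
  equivalent. No sparsity pruning. Catalog scopes with <100 context-bearing
  SBS are flagged unusable. Cluster support uses an ordinary bootstrap
  (resample each scope's mutations, refit, recluster; a cluster is
  "reproduced" only if exactly the same leaf set appears), not multiscale
  AU p-values — the published a.u. values are not comparable.
- **Selection.** The neutral model is 96 per-channel Poisson rates over
  opportunity — deliberately simpler than dNdScv's 192-parameter
  strand-symmetric model with covariates, so q-values will not match
  dNdScv numerically. Indels and DBS are excluded from ω. When a gene has
  zero observed synonymous mutations, 0.5 is added (flagged) to keep ω
  finite. Non-synonymous pools missense + nonsense + essential splice. BH
  within-cohort, Holm for the country test, matching the original
  reporting conventions.
- **Allelic imbalance.** The het window (alt fraction 0.3–0.7) and the 0.1
  phased-deviation floor are package choices on top of the stated 1,000×
  pooled-coverage rule; the floor is what controls the type-I rate, since
  folding each SNP to its major allele biases the statistic upward.
  Phasing is greedy per sample (align all deviations), making calls
  invariant to ref/alt labelling. LOH vs gain sub-typing is heuristic: a
  single-copy gain cannot exceed a phased fraction of ~2/3, so strong
  shifts (≥0.62) are read as LOH, mild significant ones (≤0.60) as gain,
  the sliver between as unclassified.
- **Hotspot bootstrap.** Replicates resample reference *samples* (not
  mutations) to preserve per-sample clustering, then thin binomially by
  the product of three measured proportions: the per-sample all-mutation
  rate ratio, the conditional C>T/CC>TT share ratio, and the conditional
  TP53 share ratio. The published analysis compares a per-replicate
  "value" against the rule-of-three bound without defining it
  operationally; here it is interpreted as the replicate's implied
  zero-event probability `exp(−λ_i)` (Poisson view of the replicate's
  thinned expectation), isolated in one field of the result. The headline
  expected count (~3 in 191 samples) does not depend on this
  interpretation.

## Moran competition model

Death–birth updating: a uniformly chosen cell dies and is replaced by a
copy of a neighbour drawn with probability proportional to fitness, on a
periodic 100×100 lattice with a Moore (8-cell) neighbourhood; one time
step is L² events (one generation). Update rule, neighbourhood, boundary,
lattice size and the two mutant fitness values are not stated in the
source material; these are the most standard choices and all are
switchable in the config. No new mutations arise during a run.

The sparse preset (fitness 1.4 and 1.8 vs wild-type 1.0, seeding density
0.014) was calibrated once by seeded grid search to the ~50%-mutant
endpoint at 16 steps. The dense run reuses it untouched with 4× seeding;
its ~90% endpoint and smaller mean clone size are emergent, not fitted.
The event loop is a numba kernel (pure-python fallback if numba is
absent); 50 replicates of both presets take seconds.

## Problem sizes and numerical choices

Tests and the acceptance script run desk-scale problems: the full
11-donor cohort (~16k mutation records) for recovery checks, 3,000-draw
catalogs for signature recovery, 50 Moran replicates per preset, and
1,000 bootstrap replicates for the hotspot analysis. Tolerances follow the
noise scale of each statistic (e.g. ±3 points on a 3,000-draw exposure,
±5 points on a 50-replicate Moran mean). Hierarchical-clustering input
order is fixed by sorting scopes; clone ids are assigned after a
deterministic sort so outputs are byte-stable under a fixed seed. The
germline filter pools alt reads over **all** samples of a donor (uncalled
samples contribute their mean depth), removing a variant everywhere or
nowhere at the strictly-greater-than-10% threshold; no lower VAF cutoff is
applied anywhere.

## Known limitations

- The simplified dN/dS model ignores strand asymmetry and covariates;
  with one cohort seed an occasional passenger gene reaches q < 0.01.
- Nesting inference is ambiguous in saturated tissue (see above); the
  published patchwork figures face the same limit ("otherwise, subclones
  are nested randomly").
- The CNA caller sub-types events heuristically and cannot see balanced
  copy-number change at all — inherent to allelic-imbalance detection.
- The strand-bias ratio is reproduced as a labelling convention, not from
  a transcription-coupled-repair model.
- Correlations between burden and UV exposure are flatter in the
  generator than in the real cohort because exposures are country-level
  constants plus sampling noise.
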