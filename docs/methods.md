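# Methods

`olsp` implements a one-locus-several-primer-sets (OLSP) metabarcoding
workflow: several primer sets amplify overlapping windows of the same
locus (the 5' COI barcode region) so that taxa missed by one primer set
— false negatives caused by primer–template mismatches — can be
recovered by another, while the resulting sequences stay comparable and
can be merged into per-taxon contigs. This note describes the model
behind each stage, the tunable parameters, what the synthetic data
generator does and does not emulate, and the numerical choices made
where the procedure left room for judgement.

## Study design model

A *run design* maps (marker, forward tag, reverse tag) combinations to
(sample, PCR replicate). Three markers are bundled as constants
(`simulate.PRIMERS`): MFZR (Uni-Minibar-F1 / ZBJ-ArtR2c), ZFZR
(ZBJ-ArtF1c / ZBJ-ArtR2c) and LFCR (LepLCO / McoiR2). Tags are 11–13 nt,
pairwise different at ≥ 3 positions (compared over the shared prefix,
since tags anchor at the 5' end of the primer construct); 12 forward ×
8 reverse tags give 96 combinations per marker, so every sample is
amplified in 3 replicate PCRs per marker (9 PCRs per sample) and a study
of 107 eDNA samples necessarily spans several sequencing runs. The
generator partitions samples into runs of at most `samples_per_run`
(default 24) eDNA samples, each run carrying its own two mock
communities (Tpos1/Tpos2) and four negative-control kinds (extraction,
aerosol, PCR, tag). The four negative kinds are kept as distinct labels
but treated identically by calibration, which pools them as "negative
controls". Replicate count is a design-table property (default 3), so
degraded designs are expressible.

## Demultiplexing and dereplication

A merged read is expected to be
`fwd_tag + fwd_primer + insert + revcomp(rev_primer) + revcomp(rev_tag)`.
Both the read and its reverse complement are searched; a read is
assigned only when **both** ends match a tag pair known to the design
(one-sided rescue is a known tag-jump vector). Tags are matched exactly
— a tag substitution mis-assigns a sample, so no tolerance is safe —
while primers are matched with IUPAC degeneracy plus at most
`primer_mismatches` substitutions (default 2, no indels); primers are
degenerate by construction, so some tolerance is required and the exact
value is a documented default, not a measured property of the original
protocol. Reads matching more than one construct are binned as
`ambiguous`; nothing is silently dropped (assigned + unassigned = total,
asserted in tests). Trimmed reads are dereplicated into exact variants
scoped to one marker; reads with non-ACGT symbols are discarded and
counted. Variant ids are assigned from the sorted (marker, sequence)
list, making the whole step order-independent.

## Low-frequency-noise (LFN) filtering

Every occurrence (variant *i*, sample *j*, replicate *k*) with count
N_ijk is kept iff

* N_ijk ≥ `t_abs`,
* N_ijk / N_i·· ≥ `t_var` (share of the variant's run-wide total), and
* N_ijk / N_·jk ≥ `t_rep` (share of the replicate's reads).

The three-filter family (absolute, variant-relative, replicate-relative)
is the package's concrete reading of the control-calibrated LFN scheme
used in tag-based metabarcoding; each sub-filter can be disabled by
setting its threshold to 0. Denominators are computed **once on the
input table**, not cascaded between sub-filters, which makes the
operation order-independent and idempotent (re-filtering can only shrink
denominators, so kept ratios never fall below their thresholds).

**Calibration.** Thresholds are chosen per run and per marker from the
controls. The hard constraint is mock retention: every expected
occurrence of a mock-community member must survive. The objective is
elimination: among feasible thresholds, maximize the number of removed
"unexpected" occurrences — everything in negative controls plus
non-expected variants in mocks (and, in the second pass,
habitat-incompatible eDNA detections). Candidate thresholds are the
finite grid of observed occurrence statistics plus an epsilon step above
each (values between observed statistics are behaviourally identical);
ratio grids are clipped to [0, 1]. Because the filter is a conjunction
of per-axis conditions, feasibility and removal factorize per axis; the
implementation exploits this, and an exhaustive 3-D grid search is kept
as an independent oracle in the tests. Among removal maximizers the
lexicographically smallest (t_abs, t_var, t_rep) is returned, so
reported thresholds are as gentle as their effect allows. Unexpected
occurrences that no feasible threshold removes (stronger than the
weakest expected mock occurrence) are reported as *unremovable* rather
than forced out — the honest analogue of a contaminated negative control
that survives filtering. Expected mock occurrences with zero reads are
reported as mock dropouts, not exceptions.

Expected mock variant sequences are predicted by in-silico PCR of each
expected taxon's reference template (ungapped IUPAC site search,
tolerance `anneal_mismatches` = 2), so mock expectations need only name
taxa, not sequences.

**Replicate screening.** Within each (sample, marker), replicate count
profiles are normalized to sum 1 and a replicate is dropped when its
mean Renkonen distance (1 − Σ min of paired relative abundances) to the
other replicates exceeds `renkonen_cutoff`. The cutoff defaults to 0.5
— the source procedure says only "high" — and dropping is simultaneous
(all means computed on the input), so the screen is order-independent.
A variant is then validated in a sample only if present in at least
`min_replicates` = 2 **surviving** replicates (screened replicates
cannot support validation); its pooled count is the sum over surviving
replicates.

**Second pass.** After a first round of filtering and assignment,
detections that are incompatible with their sample's habitat (e.g. a
freshwater-only taxon in a brackish sample, per a user-supplied taxon →
habitats table) join the elimination set, and calibration plus the full
filter chain re-run **from the original dereplicated table**. Taxa
absent from the habitat table are treated as compatible everywhere — the
table can only remove, never rescue. With nothing flagged the second
pass is a fixed point of the first.

## Contig merging (the OLSP core)

Validated variants from *different* markers are merged when they overlap
perfectly over at least `min_overlap` bases (default 100, below the
~130 bp overlap the marker geometry provides, above what random
sequences can reach). Overlaps are located by exhaustive ungapped offset
search (maximal overlap, ties toward smaller |offset|); inside
`build_contigs` candidate offsets are seeded by shared 32-mers, which is
exact for `min_overlap` ≥ 32 and cross-checked against the exhaustive
search in tests. Identity over the overlap must be exact. A connected
overlap component becomes a contig only if it has at most one variant
per marker and all implied base assignments agree; otherwise the whole
component is left unmerged and logged as ambiguous — a deliberately
conservative rule, since a multi-variant component cannot be resolved
without arbitrary choices. Contigs and leftover variants are treated
uniformly downstream as *items*; every validated variant ends up in
exactly one item (asserted).

## MOTU clustering

Items are clustered at 3% divergence with complete linkage, so the
maximum intra-cluster pairwise distance is bounded by the threshold.
Because items span different windows of the locus, distance is measured
on a semi-global pairwise alignment (end gaps free; match +1, mismatch
−1, gap open −2, extend −1): (mismatches + internal gap bases) /
(aligned overlap length), i.e. a gaps-counted p-distance; end overhangs
reflect primer geometry, not divergence, and are ignored. Pairs with
aligned overlap below 20 bases score the maximal distance 1.0.
Agglomeration ties are broken by merging the lexicographically smallest
pair of cluster labels (a cluster is labelled by its smallest member
id), making the partition deterministic and permutation-invariant; the
implementation is verified against both an independently coded
brute-force agglomerator and SciPy's complete-linkage on random
instances.

## Taxonomic assignment (lowest taxonomic group)

Items are aligned against a local reference FASTA with known taxonomy
(semi-global edit distance via edlib; identity = 100 × (1 − distance /
shorter sequence length), floor 80%). Hits are banded by identity
(≥97, ≥95, ≥90, ≥85, ≥80); within the highest non-empty band the item is
assigned to the lowest rank at which a single taxon accounts for ≥ 90%
of the band's hits, capped per band (97 → species, 95 → genus, 90 →
family, 85 → order, 80 → class) so weak identity can never award a deep
rank. The ladder, caps and inclusion fraction fill parameters the
procedure's description leaves unstated; all are configurable and
surfaced in the run manifest. Manual curation (e.g. BOLD look-ups,
phylogenetic arbitration) is out of scope, but a curated override TSV
supersedes automatic assignments, mirroring a "final taxonomic
assignment" step.

The identification-resolution (IR) score maps the assigned rank to
species = 6, genus = 5, family = 4, order = 3, class = 2, phylum = 1,
kingdom or unassigned = 0; a sample's IR is the mean over its validated
Macrometazoan items. The Macrometazoan scope excludes items whose path
contains any taxon on a configurable exclusion list (defaults:
Amoebozoa, Acari, Tardigrada, Rotifera, diatoms, algae, plants,
Acanthocephala, Nematoda — likely passive ingestion, secondary predation
or parasites); unassigned items are conservatively retained and flagged.

## Metrics

All metrics run on the item table (one row per validated item × sample,
with the set of detecting markers) at six levels: phylum, class, order,
family, MOTU, variant. A contig counts as detected by marker *p* in a
sample only if *p*'s member variant itself was validated there — contig
presence alone would hide exactly the primer-set differences these
metrics measure. MNI (minimal number of individuals) is the number of
distinct validated items per taxon per sample; items unresolved at a
level keep a stable pseudo-label derived from their deepest assigned
name so aggregation conserves per-sample totals.

* **Bc** (coverage): |taxa detected by marker p| / |taxa detected by all
  markers|, per sample and pooled.
* **Com** (complementarity): |taxa detected by exactly one marker| /
  |all detected taxa|.
* **Wsd**: Bray–Curtis dissimilarity (1 − 2Σmin/(Σx+Σy)) between one
  sample's per-marker MNI vectors — technical, between-primer noise.
* **Bsd**: Bray–Curtis between samples on combined MNI vectors —
  biological signal.
* **IR** and MNI summaries per sample and per predator group; group
  dispersion uses the sample standard deviation (n − 1), a documented
  choice where "±" was otherwise undefined.

Cells with empty unions/denominators are excluded, not zero-filled.
Kruskal–Wallis testing and plotting are left to the analyst; the
long-format tables are the interface.

## Synthetic data generator

The generator emulates the full study so every stage is testable without
external downloads. Per-species templates (318 nt) embed realized
binding sites for all three primer sets in a fixed geometry
(`simulate.WINDOWS`): trimmed inserts of 213 (MFZR), 183 (ZFZR) and 216
(LFCR) bases whose pairwise overlaps (160–190 bases) are exact template
substrings, so cross-marker contigs reconstruct the template span by
construction. Defaults reproduce the study conditions:

* full eDNA census (107 samples over 17 predator/habitat strata), 3
  markers × 3 replicates, 12 + 8 tags;
* mock communities Tpos1/Tpos2: 7 prey at 0.2 and the predator (*Zingel
  asper*) at 0.8 relative DNA concentration, reads multinomial in those
  weights;
* per-marker amplification success {MFZR 0.50, ZFZR 0.70, LFCR 0.66},
  taken from the observed in vivo MOTU coverage of the three primer
  sets. Dropout is *structural*: a failing (taxon, marker) pair gets
  three mismatches planted in that marker's forward-primer binding
  site, so the dropout is reproducible across replicates and runs, the
  way primer–template mismatch dropout behaves in reality. Mock taxa
  keep at least one working marker; the predator keeps all three.
* noise: per-base substitutions at 0.001 on primer + insert (tags are
  exempt — a tag error under exact-tag demultiplexing is plain read
  loss, which the switch rate already summarizes), tag switching at
  0.01 per read (one tag re-drawn), Poisson(5) contamination reads per
  negative-control PCR, and habitat-incompatible contaminants planted
  in 5% of (eDNA sample, marker) pairs at Poisson(10) reads per
  replicate across all three replicates (so they survive the replicate
  rule and genuinely exercise the second pass).
* sequencing depth 1000 reads per PCR — a deliberate scale-down from
  the ~10k reads/PCR a MiSeq study of this size yields, keeping the
  mock floor (~90 reads per expected occurrence) far above the noise
  processes, which is the regime the calibration targets.

Ground truth records per-PCR composition, per-read provenance, planted
diets and the *detectable* planted taxa (those that received reads in at
least two replicates of some marker — nothing else can pass the
replicate-consensus rule, so exact-recovery claims are stated against
this set). Everything is a deterministic function of the seed; written
outputs are byte-identical across repeats.

**What the generator does not emulate:** quality-score structure (reads
carry constant quality; the pipeline ignores quality), indel sequencing
errors, chimeras, length variation among real COI templates, abundance
amplification bias within a PCR, and databases with missing or
mislabelled references. Passing tests therefore demonstrate the
correctness of the pipeline's logic under the stated noise model, not
robustness to every artefact of real MiSeq data.

## Problem sizes used in tests and the acceptance script

Module and integration tests run on reduced instances chosen as the
package's own test-design decision: typically 2–8 eDNA samples, 16–30
reference taxa and 60–1000 reads per PCR; the mock-retention checks use
the default mock composition and noise model at 600–1000 reads per PCR;
oracle-equivalence checks use 1000 random clustering instances (≤ 8
items) and 200 random calibration tables (≤ 50 occurrences); noiseless
end-to-end identity uses 20 seeds. `scripts/acceptance.py` recomputes
the same quantities from scratch at those sizes under a user-supplied
seed.

## Known limitations

* Demultiplexing is exact-match on tags; platforms with frequent tag
  errors will lose reads rather than mis-assign them.
* The calibration objective counts removed occurrences uniformly; it
  does not weight contaminant abundance.
* `search_reference` computes identity from the edit distance of the
  shorter sequence inside the longer; for references much shorter than
  an item the coverage floor (80% of the item) excludes them entirely.
* Complete-linkage clustering is O(n²) in memory and O(n³) in the worst
  case; it is intended for the hundreds of validated items a study of
  this design produces, not for raw variant sets.
* The multi-variant ambiguity rule never merges conflicted components;
  real haplotype mixtures that share a marker are reported unmerged.
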