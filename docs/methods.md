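# Methods

This note documents the models behind `virobead`, the parameters that
matter, and the choices made where the design was genuinely open.

## Platform model

A viral suspension is mixed 1:1 with molten agarose and dispersed into
~30 µm gel beads, so each bead is an independent reaction vessel.  Particle
capture is modelled as Poisson: the number of particles per bead is
k ~ Poisson(λ), with each particle's genome drawn from the community's
relative abundances.  The observable is the fraction p of beads that stain
positive for amplified DNA, giving the inversion λ = −ln(1 − p) and the
suspension concentration λ / V_bead × 2, with V_bead = (π/6)d³ (d = 30 µm →
V = 1.41 × 10⁻⁸ mL; the factor 2 undoes the agarose dilution).  The
platform's operating rule is to dilute and regenerate beads whenever p
strictly exceeds 20%, because P(≥2 particles | positive) =
1 − λe^(−λ)/(1 − e^(−λ)) grows quickly with p (≈10.8% at p = 0.20,
≈13.7% at p = 0.25).

No fluorescence chemistry is modelled: a bead is "positive" when its total
amplified yield exceeds a threshold (default 0, i.e. any amplification).
This is the one place where the physical platform has a free parameter with
no stated model; it is exposed as `yield_threshold`.

## Multiple-displacement amplification surrogate

phi29 MDA produces strongly non-uniform coverage.  The per-base depth of
each loaded genome is modelled as an exponentiated Gaussian field:
z-scores are drawn per 200 bp window, smoothed by a moving average sized to
a 2 kb correlation length, scaled by σ (default 1.2) and exponentiated with
a −σ²/2 offset so the field has unit mean; whole windows drop to zero with
probability `dropout` (default 0.05 in the pipeline).  ssDNA templates get
a 1.5× yield multiplier.  Bias is quantified exactly as in practice: the
Lorenz curve of sorted per-base depths (zeros included) and its Gini
coefficient G = 1 − 2 × trapezoidal area, which algebraically equals the
mean-absolute-difference form Σ|xᵢ−xⱼ| / (2n²x̄) — the test suite checks
this identity to 1e−9.  At σ = 1.2 / dropout = 0.1 the simulator produces
mean per-bead Gini ≈ 0.6 and breadth ≈ 0.85–0.9; real MDA Ginis for phage
genomes range roughly 0.1–0.4, so the defaults are deliberately on the
biased side to stress the downstream binning.

Assembly is not simulated.  Contigs are the maximal intervals with depth
above a floor and length ≥ 1 kb.  This preserves exactly the property the
downstream logic depends on — one bead yields several fragments of the
same genome, broken at amplification dropouts — without the confounds of a
real assembler.  Consequently the simulated single-contig vSAG fraction is
much lower than a `--sc` assembler would produce, since any dropout
fragments the genome; this statistic is structural, not calibrated.

## Synthetic community

Defaults emulate a freshwater DNA virome at desk scale: lognormal genome
lengths (median 40 kb, σ_log = 0.6–0.7, truncated to 1–300 kb), small
circular ssDNA genomes (1.7–7 kb) at 10%, power-law rank abundances
p_i ∝ i^(−1.5) (the true community abundance distribution is unknown; the
exponent is a parameter), and a 1 Mb bacterial background genome whose GC
is offset +12 points from the viral mean so composition-based separation
is learnable.  Gene content uses shared OG pools: each genus has a private
backbone pool while AMGs come from one community-wide pool, so AMG protein
families recur across unrelated lineages — the pattern the protein-sharing
network analysis is designed to detect.  Planted genes are real coding
sequences (ATG, sense codons, terminal stop) copied from the pool with 2%
per-genome divergence that never introduces in-frame stops, so ORF calling
and protein clustering can rediscover them.

Strain groups model within-species diversity: strains of a parent genome
carry intergenic SNVs (default 5 × 10⁻³/site, capped at 2 × 10⁻² to keep
pairs inside the ANI ≥ 95% species boundary) and strain-specific subsets
of gene cassettes (e.g. methyltransferase subtypes) inserted at inter-gene
positions, never splitting a core gene.  Core genes are byte-identical
across strains, so conserved markers keep 100% identity while whole-genome
ANI stays ≥ 98.9%.  A cassette drawn into every strain is removed from one
so that each used cassette is genuinely flexible.

What the generator does **not** model: real gene synteny, codon usage,
protein structure, chimeras, primer artifacts, or quality-score realism.
Passing tests therefore demonstrate that the decision logic is correct
under its stated statistical assumptions, not that it is robust to every
artifact of real sequencing data.

## vSAG construction

Virality filtering keeps contigs whose score ≥ 0.3.  In simulation mode the
score is the fraction of contig length covered by annotated genes of its
true source genome (background contigs score 0); in real-data mode any
scorer can be plugged in.  Binning distance between contigs is
`tnf_weight` × Euclidean distance of canonical 136-class tetranucleotide
frequencies + `abund_weight` × |log abundance ratio| (defaults 1.0 / 0.5),
clustered by single linkage and cut at 0.25.  The cutoff was calibrated on
fixtures: within-genome contig TNF distances reach ~0.04 (1.5 kb contigs)
plus ~0.14 of abundance noise, while co-encapsulated genomes with a
10-point GC offset and ≥5× abundance ratio sit near 0.8.  Clusters under
10 kb total length are discarded.  Bins are concatenated largest-first with
100-N linkers (any N-run ≥ 10 decodes as a linker), completeness is
100 × min(1, ungapped length / expected genome length) with tiers high
≥ 90% / medium ≥ 50%, and the bead's vSAG is the highest-completeness bin
with completeness > 0 (ties → longer bin, then lexical id); all other bins
are recorded as excluded.  Completeness here is a length-based surrogate
for marker-gene estimators, declared as such: in simulation mode the
expected length is the majority-provenance genome's true length, in real
mode a user-supplied table.

Beads with fewer than 5 000 read pairs are reported as a separate
"small data" category, and a bead library only enters analysis when its
read count strictly exceeds 50 000 (25 000 pairs).

## Clustering layers

**ANI/AF.**  The query is cut into 1 kb fragments; each fragment is placed
on the target by shared 15-mer offset voting and scored with an infix edit
alignment.  Fragments aligning below 95% identity are split in half and
re-seeded (insertions in either sequence corrupt part of a fragment without
invalidating the rest — mirroring how local aligners simply leave indels
unaligned); pieces below 70% identity are discarded.  ANI is the
length-weighted mean identity of retained pieces, AF their total length
over the shorter N-stripped sequence.  vOTUs use greedy centroid
clustering, ranked by completeness then length, with membership at
ANI ≥ 95% and AF ≥ 85%.

**PCs.**  Protein similarity is amino-acid 4-mer Jaccard with edges at
≥ 0.5 (a MinHash sketch prescreen keeps candidate pairs near-linear), and
the graph is partitioned by Markov clustering (expansion 2, inflation 2.0,
pruning 1e−5, ≤100 iterations; clusters are the connected components of
the converged matrix).  At the default threshold, families up to ~5%
amino-acid divergence cluster reliably; more divergent homology detection
is out of scope.

**VCs.**  Genomes with ≥ 2 PCs form a network whose edge weight is −log₁₀
of the hypergeometric upper-tail probability of sharing at least the
observed number of PCs given both genomes' PC counts and the PC universe;
edges below weight 1 are dropped and the graph is partitioned by the same
MCL.  VCs are disjoint (a deliberate simplification relative to
overlapping-cluster approaches), need ≥ 2 members, and are represented by
their highest-completeness member.

## Annotation analytics

Taxonomy voting requires strictly more than 30% of a genome's proteins to
have reference hits, then assigns each rank top-down to the value held by
strictly more than 50% of hit proteins, stopping at the first rank without
a majority.  Marker-based taxonomy keeps hits with score ≥ 40 (inclusive)
and E ≤ 1e−5 and truncates to the longest common lineage prefix of the
surviving markers.  AMG records are genes with auxiliary scores 1–3
(scores 4–5 are annotated but excluded).  The AMG-sharing question — are
AMG-containing PCs over-represented among PCs found in multiple VCs? — is
a 2×2 exact Fisher test computed by enumerating the hypergeometric support
at fixed margins and summing probabilities ≤ that of the observed table
(with a small relative tolerance against floating-point ties); degenerate
margins return p = 1 with a flag, and odds ratios use the Haldane +0.5
correction when a cell is zero.

Recruitment curves keep read alignments with identity ≥ 50%, query
coverage strictly > 80% and E ≤ 1e−5, and smooth the identity density with
a Gaussian kernel at bandwidth factor 0.5 of the data SD on a 50–100%
grid, scaled to integrate to 100%.  A degenerate (zero-variance) identity
set becomes a point mass on the nearest grid value.  Curve spread is
summarised by the IQR of the smoothed distribution: clonal populations
give sub-point IQRs, strain mixtures spanning 95–100% identity give IQRs
of several points.

Within one vOTU, OGs present in every member are core and the rest
flexible; insertion events are maximal runs of flexible-OG genes in one
member's gene order, reported with the nearest core OG on each side.
Detection is OG-order based, not nucleotide-alignment based; whole-genome
aligners are out of scope.

## Numerical and engineering choices

- All randomness flows through `numpy.random.default_rng` seeds; identical
  seeds give byte-identical artifacts.
- Percentages are reported half-up to one decimal from the summary's own
  integer fields.
- The pipeline's per-bead mapped-read counts are drawn multinomially from
  amplified yields (plus a binomial background carry-over fraction) rather
  than materialising every read; `generate_reads` produces actual paired
  reads (and FASTQ) when sequences are needed.
- Stage chain: the CLI subcommands rerun the deterministic chain from the
  seeded config rather than parsing prior artifacts; artifacts exist for
  inspection and for external (real-data) consumers of the formats.
- Desk-scale problem sizes — 25 genomes, 1 500 beads, ~150 sorted — were
  chosen so a full run completes in about a minute on one CPU while every
  downstream layer (multi-member vOTUs, VCs, AMG sharing) is populated.

## Known limitations

- The assembly surrogate understates single-contig vSAG rates (see above).
- The virality filter is ground-truth-aware in simulation mode; it tests
  the filtering *logic*, not viral sequence detection itself.
- MCL is run to a stability tolerance; near-metastable states can admit
  further splitting under continued iteration, so cluster counts should be
  read as tolerance-dependent.
- Fragment ANI is insensitive to rearrangements at scales below the 1 kb
  fragment size and reports NaN when no fragment aligns.
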