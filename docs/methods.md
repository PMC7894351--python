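# Methods

`ulvapop` reimplements, as a tested pipeline on synthetic data, the
organellar population-genomics workflow used to characterize wild foliose
*Ulva* (sea lettuce): iterative reference-baited organelle assembly,
per-strain consensus and SNP-density statistics, SNP-matrix PCA and species
clustering, barcode assignment, distance-tree agreement across markers,
k-mer synteny and inversion detection, and F1-hybrid detection from pooled
45S rDNA allele frequencies. This note documents the models, the defaults
and why they were chosen, the numerical decisions, and what the synthetic
design does and does not show about real data.

## The synthetic panel

The generator emulates the sequencing design of a six-species foliose *Ulva*
survey: circular chloroplast (cp) and mitochondrial (mt) genomes, a
multi-copy nuclear 45S rDNA unit, many pure strains, and one F1 hybrid.

**Mutation model.** Substitution-only Jukes–Cantor (JC69) evolution along a
species tree, simulated node-by-node (per-site substitution probability
`3/4·(1−exp(−4d/3))`, uniform over the three other bases). Indels are not
modeled: the downstream mapper is ungapped and every genome stays on one
shared coordinate frame, which is what the shared-CDS statistics, the common
SNP matrix and the consensus comparisons implicitly assume. Consequently all
species share one cp length and one mt length per run (defaults 103,444 and
79,723 bp, the reference species' printed genome sizes); the real size range
across species (95–118 kb cp, 59–88 kb mt) is *not* reproduced, since
size variation in real genomes comes from indels and intergenic turnover.

**Species tree and divergence calibration.** The input is a symmetric
species×species matrix of observed SNP densities (per kb). An additive tree
is fitted by neighbor joining on the JC-corrected matrix and sequences are
evolved along it; for tree-additive matrices (the defaults are, by
construction) every pairwise realized divergence matches the request in
expectation, with binomial sampling spread. The default matrices come from a
resolved two-clade tree — (laetevirens, rigida), gigantea | pseudorotundata,
(fenestrata, australis) — whose leaf-to-reference distances are calibrated
so each species' observed density against *U. laetevirens* equals the
published per-species values (cp: 6.1, 35.3, 82, 79.8, 91.5; mt: 5.6, 86.1,
196, 194, 222 SNPs/kb). Internal branches take fixed shares (10/15/8%) of
the relevant divergence scale — large enough that even the shortest barcode
carries a recoverable number of substitutions per internal edge. A star
default would leave the inter-species topology unresolved and make
cross-marker tree comparison meaningless.

**Intra-specific variation.** Per-strain substitutions at the published
per-species rates (cp 0.09–1.98, mt 0.03–1.36 SNPs/kb), uniform over the
genome. CDS and non-CDS rates are equal by default (`cds_bias` is a knob);
the source data report CDS densities only.

**Annotation.** Evenly spaced non-overlapping genes with alternating
strands: 69 cp genes totalling 63,775 bp and 29 mt genes totalling 24,854 bp
at full scale (the published common CDS set sizes), including `rbcL`
(1,428 bp) and `tufA` (1,230 bp) barcode genes. The annotation list is in
gene-id order and identical across species, so gene-wise CDS concatenation
is comparable across genomes even after the inversion reorders positions.

**Inversion.** One chloroplast segment (~35% of the genome, breakpoints
placed in intergenic gaps, barcodes excluded) is reverse-complemented in the
australis/fenestrata/pseudorotundata clade, transplanting gene coordinates
(mirrored, strand-flipped). Mitochondria carry no rearrangement.

**45S rDNA.** The ~5 kb unit evolves on the organellar tree rescaled so the
most diverged pair shows 65 fixed differences, with a per-branch floor of
3 substitutions/kb. The floor encodes that rDNA (ITS-bearing) diverges
disproportionately fast between closely related species: purely
organelle-proportional scaling would leave the hybrid's parents
(rigida × laetevirens) with fewer informative sites than any classifier
could use, contradicting the many informative loci observed for that pair.
With the floor, that pair carries ~30 fixed differences at full scale (~15
at unit scale); the chance of falling below the classifier's 5-site minimum
is < 1e−3 per panel. Copy number defaults to 500 (only "high, ≥100" is
known; hundreds is typical for rDNA arrays) so that copy-level noise in the
pooled allele frequency (sd ≈ 0.022 at a 50/50 draw) stays below read
sampling noise. A hybrid's copies are drawn Binomial(copy_number, 0.5) from
parent A's haplotype, the rest from parent B's; its organelles are the
cytoplasm donor's only (uniparental inheritance → homoplasmy).

**Reads.** 150 bp paired-end reads, insert ~ Normal(500, 50) bp, pairs per
molecule = round(coverage·length/(2·read_length)), sampled uniformly over
circular coordinates (fragments may wrap), per-base substitution errors at
`error_rate` (default 0.002), fixed base quality. The insert length was
chosen so that mate rescue in the baited filter extends each assembly
iteration by roughly a full insert per flank. The 45S unit is sampled *and
mapped* as circular: the unit sits in a tandem array, so real fragments run
across unit junctions; linear sampling would create depth troughs at the
unit edges that distort per-site allele frequencies. Contaminant reads are
random sequence — no bacterial genome realism, no quality-score error model.

**What passing tests do not show.** The panel is gap-free, repeat-free
(beyond the 45S array abstraction) and single-contig per compartment; real
organelles contain repeats near or above assembly k, indels, rate
heterogeneity and genuine size variation. Results here validate the logic
and statistics of the pipeline, not its robustness to those features.

## Assembly

Baiting retains a read pair iff either mate shares ≥2 canonical 21-mers with
the bait set — at ~90 SNPs/kb divergence a 150 bp read still contains a
clean shared 21-mer window with high probability, and joint retention pulls
in mates that reach up to an insert length beyond the bait. Assembly is a
minimal de Bruijn unitig assembler over solid canonical 31-mers (count ≥ 3;
no bubble popping — error rates here are low and the contract is exactness
on clean reads). A contig whose first and last 30-mers coincide closes into
a circle; it is trimmed and normalized to the lexicographically minimal
rotation of the canonical strand, making circular sequence equality a string
comparison. The iterative loop (filter → assemble → circularity, re-baiting
with each round's contigs) converges when exactly one contig ≥200 bp is
circular; a diverged seed reference missing a 2 kb species-specific segment
closes the gap at roughly an insert length per flank per iteration
(observed: 3 iterations for a 2 kb gap at 20×). Paired-end information is
used only for retention, not scaffolding.

## Mapping, calling, consensus, statistics

The mapper anchors each read (both strands) by exact 15-mer seeds at
k-spaced offsets, scores candidate placements by mismatch count against the
doubled (circular) reference, breaks ties to the lowest coordinate (forward
strand first) and discards placements with >20% mismatches. It is ungapped
by design (substitution-only data); for real data a SAM import builds the
pileup instead. Calling uses explicit thresholds: depth < 10 → no-call; top
non-reference fraction ≥ 0.9 → variant; within [0.2, 0.8] → heterozygous;
else reference. At 1000× depth a 1% error rate cannot reach the heterozygous
band (binomial tail < 1e−9). Consensus building substitutes variant alleles,
takes the majority base at heterozygous sites (exact ties keep the
reference) and logs no-call positions.

Densities are reported printed-table style — half-up rounding to one
decimal, integers (≥100/kb) to zero decimals — so worked examples from the
published tables check exactly. Inter-specific statistics count CDS
mismatches of each strain's consensus against the reference species'
majority consensus and normalize by the concatenated CDS length (63,775 /
24,854 bp at full scale); intra-specific statistics are per-strain counts
against the species majority consensus (ties → first strain's base,
logged), normalized by full genome length — the source normalization for
within-species variation is ambiguous, and genome length is what "consensus
organellar genome" suggests.

## Clustering and species assignment

The SNP matrix codes genotypes against one common chloroplast reference
(0 ref, 1 alt, 0.5 heterozygous, missing = no-call). PCA uses the standard
population-genetics normalization — columns centred on the allele fraction p
and scaled by sqrt(p(1−p)), missing imputed to p — with the sign fixed so
each component's largest-magnitude loading is positive. Heterozygous coding
at 0.5 places an F1 midway between its parents' clusters on the
discriminating axis, which the pipeline verifies explicitly.

Cluster delimitation is single-linkage on SNP-count distances with an
*inconsistency* cut: a merge is a between-cluster join when its height is
more than `split_z` (default 4) spread-units above the merge heights inside
its own two subtrees. Two details matter. First, heights of merges already
flagged as joins are excluded from the within-cluster scale passed upward —
otherwise one early join (e.g. the two closest species) inflates the scale
estimate of every merge above it and the clade-level joins stop looking
anomalous. Second, the spread estimate is floored at sqrt(mean): SNP-count
distances are Poisson-scale, and tiny subtrees would otherwise produce
near-zero spreads and false splits. A simpler "largest relative gap ≥
factor" cut is kept as `method="gap"`, but it cannot separate the closest
species pair (6.1 SNPs/kb) from the most diverse species' within-species
distances (~4 SNPs/kb pairwise) — that ratio is ~1.9, while the largest gaps
in merge heights sit *between* inter-species joins. The inconsistency cut
exploits the replication inside each species instead and recovers the six
clusters exactly across seeds. The cluster count is always emergent.

Species names come from barcode identity: each strain's rbcL+tufA sequence
against a labelled reference panel, ties reported.

## Synteny and inversions

Anchors are k-mers unique in both genomes (canonical counting, doubled scan
for circular genomes), chained greedily into same-orientation runs with a
consistent diagonal; runs with <10 anchors are dropped and
reverse-orientation blocks are inversions. At cross-clade divergence
(~82 SNPs/kb) substitutions occasionally cluster near a breakpoint and leave
no clean k-mer for tens of bases, so anchor-bounded breakpoints can be
20–50 bp off; each inversion is therefore refined at base level by scanning
both boundaries for the split point minimizing total mismatches under the
mirrored (inside) versus forward (outside) alignment — the same boundary
polish progressive aligners apply to locally collinear blocks. Refined
breakpoints land within 0–2 bp of the simulated truth. The unit-scale
pipeline preset uses anchor k=17 (default 31): at 82 SNPs/kb the density of
clean 31-mers is too low for reliable blocks on a 12 kb genome, while 17-mer
collisions are negligible at that scale.

## Trees and agreement

Distances are p or JC69 (NaN above the 0.75 saturation bound); trees are
standard neighbor joining with deterministic tie-breaking (lexicographically
smallest taxon pair) and negative branch estimates clamped to zero with the
deficit moved to the sister branch (path lengths preserved). Bootstrap
support is site resampling (default 1000 replicates, seeded; the pipeline
default is 200). Agreement reports the Robinson–Foulds distance plus a
species-cluster comparison: whether each species is a clade in both trees
(evaluated on the trees restricted to labelled pure strains, so a hybrid
attached inside its cytoplasm donor's clade does not break monophyly) and
the RF between the trees collapsed to one representative per species.
Across markers, cluster membership agrees; inter-species resolution may
differ by one rearrangement on the shortest barcode — mirroring the real
observation that node support, not strain clustering, differs between loci.

## Hybrid detection

Informative sites are positions where two species' 45S consensuses differ
and each species' pooled reads support its own allele at ≥0.95. A strain's
profile is the per-site frequency of parent A's allele among A+B reads. The
nuclear call is heterozygous_AB when (i) the strain's pooled allele ratio —
the depth-weighted mean of in-band frequencies, which for a genuine F1 is
the binomial copy split of the two parental rDNA arrays, near but almost
never exactly 0.5 — lies inside the heterozygous band [0.35, 0.65]; (ii)
≥90% of informative sites are het-consistent; and (iii) no in-band site
rejects the pooled ratio in an exact binomial test at Bonferroni-corrected
α = 0.01. The design choices, in decreasing order of importance:

- Per-site tests run against the *pooled ratio*, not against 0.5: at high
  depth a test against exactly 0.5 rejects genuine F1s whose copy split is
  legitimately off-centre — the same imbalance the band tolerates — while a
  chimeric or partial pattern, where sites carry genuinely *different*
  ratios, still fails.
- A site is het-consistent when it lies in the band *or* when the binomial
  test cannot distinguish it from the pooled ratio. A hard band edge alone
  creates a discreteness cliff: a site at 0.34 with pooled ratio 0.47 at
  depth 100 is a pure sampling fluctuation, not evidence against F1 status.
- A site pinned near 0 or 1 that firmly rejects the pooled ratio has lost
  its diagnostic allele in that strain (a strain-private rDNA variant
  recodes an informative locus in ~1–2% of strains at the panel's intra
  rates); it is treated as no longer informative for that strain and leaves
  the denominator. At most 20% of sites may be explained away like this, so
  patterns with many flipped loci (chimeras) still fail the call.

Organellar homoplasmy uses diagnostic sites between the two species'
organelle consensuses: the call is the dominating species, and the strain is
homoplasmic unless more than 2% of diagnostic sites show clearly
*intermediate* frequencies (inside [0.2, 0.8]). A genuine heteroplasmic
mixture is intermediate at essentially every site; a strain-private
substitution that happens to recreate the other species' allele flips a
site fully and does not mark heteroplasmy. A 70/30 artificial mixture is
called for the majority species with homoplasmy false.

The verdict is F1 iff the nucleus is heterozygous_AB and both organelles are
homoplasmic for one and the same parent; pure iff nucleus and organelles
agree; a pure nuclear call disagreeing with the organellar assignment is
flagged discordant (possible introgression or a later-generation hybrid —
out of scope to resolve), never F1. Ploidy is not asserted. Measured across
five independent default panels: sensitivity 300/300 read draws at 100×
pooled coverage, zero false positives over 100 pure strains at 1% read
error and 1000× coverage.

## Pipeline, scales and determinism

`run_pipeline` executes simulate → assemble (one strain's chloroplast) →
map/call against both the common reference (SNP matrix, clustering) and the
own-species reference (consensus, statistics) → barcode assignment →
Table-style statistics → marker trees and agreement → synteny → hybrid
verdicts, writing TSV outputs, a Markdown summary and a JSONL log with
sha256 checksums. A single seed drives every stage through spawned
substreams; reruns are byte-identical.

Two scale presets exist: `full` uses the printed genome and CDS sizes;
`unit` (~12 kb cp, 8 kb mt, 2.5 kb 45S, 20 strains) keeps every statistical
contrast of the full design — the same density matrices, intra rates, clade
structure and hybrid — at sizes where an end-to-end run takes seconds. Tests
and the acceptance script run the unit preset for pipeline-level checks and
the full preset for density-calibration checks; problem sizes used are
stated in each test.

## Known limitations

- Substitution-only model: no indels, no size variation, no rate
  heterogeneity across sites or lineages.
- Ungapped mapping and unitig-only assembly; repeats ≥ assembly k are not
  resolved and no polishing step exists.
- Branch lengths are JC69 distances; they are not comparable to posterior
  expected-substitution scales from model-rich Bayesian analyses.
- F2/backcross generations are undetectable by design (single nuclear
  marker); the discordant_non_F1 verdict only flags them.
- The gap-based cluster cut is provided for completeness but is unreliable
  when within-species diversity varies by orders of magnitude across
  species; the inconsistency cut is the supported default.
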