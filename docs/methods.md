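# Methods

This note documents the models and procedures implemented in `attforge`,
the parameters that matter, what the synthetic data emulates, and the
numerical choices made where the design was genuinely open. It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## 1. Comparative boundary detection (`boundary_finder`)

**Model.** A mobile genetic element (MGE) integrating at an attachment site
transforms a pre-integration locus `B1 - D - B2` into the post-integration
locus `B1 - D - P1 - E - P2 - D - B2`: the target-site duplication `D`
(length ≥ 0) appears once before integration and flanks the element `E` on
both sides afterwards. Given an assembled pre/post genome pair, detection is
direct sequence comparison rather than read alignment: the scan walks both
sequences in lockstep, and at the first divergence re-anchors on an
exact-match seed k-mer of the reference (default k = 21, the `min_flank`
parameter) found downstream in the query. The distance between the
divergence point and the re-anchor is the inserted length; the breakpoint is
then slid left through any microhomology between the upstream flank and the
tail of the insert, and the maximal overlap between prefix and suffix
anchors on the reference is reported as `D`.

**Canonicalization.** When microhomology makes the breakpoint ambiguous
(e.g. a junction inside a homopolymer run), all placements describe the same
pair of strings; the reported site is the leftmost valid one. The synthetic
fixtures compute their ground truth with the same leftmost rule — but via
independent closed-form common-prefix/suffix arithmetic on the whole pair,
not via the k-mer scan — so round-trip tests compare exactly. A consequence
worth knowing: chance identity between the element termini and the flanks
can extend the canonical duplication beyond the planted length (e.g. a
planted 4 bp duplication may canonicalize to 5 bp); both sides of the
comparison agree because both apply the same rule.

**Assumptions and limits.** The pair must differ by insertions only; a
substitution or deletion in the query raises an error rather than producing
a wrong call. Nested or overlapping insertions are reported as an error
condition, not silently merged. Elements longer than the quality-control
cap are still reported here — detection and policy are deliberately
separate.

**ANI.** `measure_ani` chops each genome into non-overlapping fragments
(default 500 bp — smaller than typical whole-genome tools use, sized for
desk-scale fixtures), locates each fragment in the other genome by exact
15-mer seeds, scores the best candidate with an edit-distance alignment
(edlib), and averages best-match identity over both directions. Fragments
with no seed hit are excluded; if nothing matches the result is NaN
("no match"). Under a 5% uniform substitution model the expected identity is
95%, which the tests verify to ±0.5 points.

## 2. Attachment-site reconstruction (`attsite`)

attB is rebuilt as `B1 + D + B2` from the flanks on the post-integration
chromosome (equivalently, the reference locus) and attP as `P2 + D + P1`
by wrapping the element termini around the duplication. Both are trimmed to
a fixed window (default 50 bp) centered on the duplication midpoint; windows
truncated by sequence ends are flagged, not rejected.

**Center and core.** The attachment-site center is the stretch identical
between attB and attP containing the crossover core. Inside
`reconstruct_sites` the duplication's window position is known, so the
center is computed by extending the exact match outward from the duplication
— a window-wide longest-common-substring search would let a chance ~6 bp
off-center repeat outcompete a short true duplication (two random 50-mers
share a ~6 bp substring more often than not). The standalone `find_center`
operation, for use when no decomposition is available, does use the longest
common substring, with ties broken by proximity of the substring midpoint to
the sequence midpoints, then leftmost. The core is the central 2-mer of the
duplication (or the junction-straddling 2-mer when `|D| < 2`).

attL/attR are derived by crossing over at the core: attL = attB left arm +
core + attP right arm, attR = the converse; applying the same crossover to
(attL, attR) regenerates the original pair, which is property-tested.

## 3. Candidate quality control (`qc`)

Eight filters, all thresholds configurable with these defaults: ANI ≥ 95%
(same-species comparison), center ≤ 20 bp, ambiguous nucleotides ≤ 5% of the
attachment sites, protein length 400–650 aa inclusive, at least one of the
Pfam domains {Resolvase, Recombinase, Zn_ribbon_recom}, ambiguous amino
acids ≤ 5%, element < 200 kb (larger elements are presumed assembly
artifacts), and recombinase gene within 500 nt of its attachment site.
"More than X removed" thresholds are implemented strictly (exactly X
passes); "between A and B" is inclusive. Domain calling is consumed as an
input table — this module only checks set membership. A missing field marks
its filter indeterminate and fails the candidate, so partial tables can be
screened without crashing.

MGE category assignment is a plurality vote over per-tool annotations with
ties resolved in the fixed order dsDNA Phage → ICE/IME → Plasmid → Other
replicon; an empty annotation set votes "Other".

## 4. Specificity classification (`specificity`)

Sequences are clustered greedily: sorted by decreasing length (ties
lexicographic by id), each sequence joins the first centroid it matches at
or above the threshold, else founds a cluster. Identity is matches over
alignment columns under global alignment with unit match score and affine
gaps (open 10, extend 1); the scheme is configurable because identity
definitions differ between clustering tools.

*Site-specific*: a recombinase cluster (50% identity) whose entire edge set
covers exactly one target-gene cluster (50% identity), where that target
cluster is independently hit by at least three recombinase clusters. We read
"targeted a single target gene cluster" as the cluster's whole edge set —
the alternative (counting targets only after dropping weakly-supported
ones) would let one cluster be labelled both site-specific and
multi-targeting, violating label exclusivity.

*Multi-targeting*: per 90%-identity cluster, count distinct target-gene
clusters; clusters hitting one are removed from consideration; the rest are
binned (2, 3, >3), with ">3" fully multi-targeting; each 50% cluster
inherits the highest bin among its 90% members. Both classifiers are tested
for exact agreement with a brute-force application of the rules on random
bipartite graphs.

Motif eligibility requires more than ten unique attB sequences or more than
ten distinct target-gene clusters; one attB per target cluster is forwarded
to motif building to avoid redundancy.

## 5. Target-site motifs (`motif`)

**Core scoring.** For each adjacent column pair of an aligned attB set:
conservation = mean modal-base frequency of the two columns (gaps
excluded); distance = |pair midpoint − alignment midpoint| / (width/2);
score = 0.5·conservation + 0.5·(1 − distance). Modal-base frequency was
chosen for the conservation term (information content is the plausible
alternative); the weighting is fixed at 0.5/0.5. Ties prefer the pair
nearer the center, then leftmost.

**Core-anchored alignment.** Sites are then re-aligned purely by stacking
on the predicted core — no alignment algorithm, no internal gaps; flanks are
padded with `-`. Width = max left extent + 2 + max right extent.

**Frequency matrices.** Per-column base frequencies with a pseudocount
(default 0.01) and renormalization. Two gap policies: `exclude` (frequencies
over non-gap characters; the default for core-anchored stacks) and
`uniform` (each gap contributes 0.25 per base; used for post-hoc motifs).
A column with no informative characters falls back to uniform and is
flagged. Motifs serialize to MEME minimal format.

**Post-hoc motifs.** For a query enzyme with its own attB: relatives at
≥ 30% amino-acid identity are visited in decreasing identity order (ties by
id); each relative's attB joins the selection only if ≤ 95% identical to
every already-selected attB, until `n_sites` (typically 20, 50 or 100)
accumulate. Each attB is oriented by the strand scoring higher against the
query's attB under global alignment (match 1, mismatch −1, gap −2). The
selected sites are multiply aligned, columns with over 50% gaps are
dropped, the middle 60 columns of what remains are kept (centered on the
post-exclusion midpoint), and frequencies are mapped onto the query attB's
coordinates through the query row; unmapped positions and gap cells get
uniform frequencies. The internal aligner is a progressive
profile–profile aligner over a UPGMA guide tree (match 1, mismatch −1,
linear gap −2, k-mer distances for the tree); it is a pluggable contract —
any `sequences → aligned rows` function can be substituted — and is
adequate for the closely related attachment sites this procedure selects,
not a general-purpose MSA tool.

**Scanning and ROC.** A motif scores a sequence as the maximum over windows
and strands of Σᵢ log2(fᵢ(base)/bg(base)); log base 2 and a uniform
background are defaults, both configurable; non-ACGT characters contribute
zero log-odds. ROC curves sweep thresholds over the union of observed
scores; the trapezoidal area credits ties 0.5 and therefore equals the
Mann–Whitney U statistic normalized by n₊·n₋, which the tests verify
against an independent rank-statistic computation.

## 6. Genome-target search (`genome_target`)

Attachment sites (20–200 bp) are searched against a target genome with
exact-match 11-mer seeds grouped by diagonal; each seed band is extended by
a windowed local alignment (match +2, mismatch −3, gap open 5, extend 2)
and assessed with a Karlin–Altschul expectation value E = K·m·n·e^(−λS).
λ is solved numerically from the scoring scheme under uniform base
composition (≈ 0.32 for +2/−3); K is fixed at 0.3, an order-of-magnitude
constant — adequate because the decision threshold (E < 10⁻³, strict) sits
many orders of magnitude above the E-values of genuine site matches and
below those of chance extensions. Both strands are searched; tests verify
that the top interval agrees with an independent quadratic-time
Smith–Waterman oracle and that reverse-complementing the genome swaps
strands while preserving scores. For bit-compatible substitution of an
external search engine, precomputed hits in BLAST tabular (outfmt 6)
columns can be ingested instead.

Role assignment: the attachment site with the best (lowest-E) genomic hit
becomes **attA** (acceptor), its cognate partner **attD** (donor), and the
hit's genomic span **attH** (the predicted target site). Ties on E-value
break by higher bit score, then attB is preferred.

## 7. Integration-site mapping (`integration_mapping`)

Input is a SAM/BAM of junction reads against a composite reference whose
donor contig is named `donor`, plus the donor geometry (`SiteConfig`:
donor sequence, primer, attD interval, core offset). Filtering keeps
primary, first-in-pair genomic alignments whose soft clip is donor-derived
and begins at the primer, whose attD is not intact in the read (a read long
enough to have contained the full attD but lacking it is "disrupted"; a
shorter read is "undeterminable" and kept), with mapping quality ≥ 30 and
insert size ≤ 1,500 bp. "Uniquely mapped" is operationalized as primary
alignment with mapq ≥ 30. PCR duplicates collapse on (chromosome, anchor,
strand, insert size), or per UMI when the donor carries one (`RX` tag).

Per genomic anchor, the clipped ends are stacked (they all begin at the
primer) and a per-position majority consensus is taken, ties becoming `N`;
the consensus is trimmed to begin at the primer. Each candidate must share
a 9-mer with the attD subsequence (primer through 25 bp after the attD
end), align to it at ≥ 80% identity in either the full local alignment or
the longest contiguous gap-free unambiguous block (Smith–Waterman, match 2,
mismatch −2, gap open 4, extend 1 — the scoring is a package choice), and
place the crossover (where the consensus alignment ends in attD
coordinates) within 15 bp of the predicted core. The genomic core position
is the anchor for '+' calls and anchor − 2 for '−' calls, so both
orientations report the core's first base. Anchors supported by a single
read are kept by default (`min_support` exposes the stricter choice).

Sites within 500 bp merge into loci by single linkage, regardless of
orientation; loci report unique-read (or UMI) counts and their percentage
of the total, which sums to 100. Site motifs take the best-supported site
per locus, extract the core ± flank window on the strand of integration,
and feed the stack to the core-anchored motif builder. Accessibility
enrichment draws two seeded background positions within 100 kb of each
site and tests the 2×2 in-peak table with a two-sided Fisher exact test
(p = sum of hypergeometric probabilities ≤ that of the observed table);
an empty out-of-peak margin reports an infinite odds-ratio sentinel.

## 8. Enrichment statistics (`enrichment`)

Feature enrichment tests each annotation feature occurring in ≥ 5 target
genes with a two-sided Fisher exact test against background genes
(background size is the caller's choice, default 1:1) and adjusts p-values
by Benjamini–Hochberg — the intended reading of an "FDR-adjusted" p.adjust
call. Untested features are reported with their reason. The anti-phage
proximity comparison is a Wilcoxon rank-sum test: exact null for combined
n ≤ 25 without ties, normal approximation with continuity correction
otherwise; all-tied input returns p = 1 with the statistic. Rank-sum
invariance under monotone transforms is property-tested.

## 9. Barcode counting (`barcode_counter`)

Reads are kept when mean quality over all positions ≥ 30 and minimum
quality over the k-bp barcode region ≥ 30 (Phred+33 assumed, configurable).
The tally covers the complete 4^k universe (4,096 for k = 6) with exact
matching only — no mismatch rescue, since the assay counts literal barcode
matches. Dropout = barcodes with ≤ 1 count; under uniform sampling at
effective depth d the expected dropout fraction is the Poisson P(X ≤ 1),
which the tests check within sampling error. The pooled-reporter statistic
is log2((CPM_bound + c)/(CPM_unbound + c)) with counts-per-million depth
normalization (total-sum scaling would differ only by a constant factor
cancelling in the ratio) and pseudocount c (default 1).

## 10. Synthetic data: what it does and does not emulate

The `fixtures` module generates (i) i.i.d. random genomes at a chosen GC
content; (ii) planted integrations with target-site duplications of 0–10 bp
and a chosen core dinucleotide, written into the genome at the duplication
midpoint (or across the junction and onto the element termini when
`|D| < 2`) so that attB and attP genuinely share it; (iii) donor–genome
junction read pairs over planted sites, with truth-derived SAM alignments
against the composite reference (the upstream read aligner is outside the
package's scope, so the simulator emits the alignments an aligner would
produce: genomic portion aligned, donor portion soft-clipped, proper pair
flags, mapq 60), a fixed Q37 quality baseline with seeded per-base
degradation, uniform substitution errors at the requested rate, and a
configurable fraction of positional PCR duplicates; (iv) barcode amplicon
reads with a planted barcode offset and seeded quality degradation.

Deliberately not emulated: repeat structure, GC skew and composition
heterogeneity of real genomes; alignment ambiguity and mapq degradation in
repetitive regions; indel sequencing errors and platform-specific error
profiles; chimeric reads and alignment artifacts. Passing tests therefore
demonstrate correctness of the decision rules and arithmetic on reads and
assemblies that behave as their headers claim — not robustness to
real-data pathologies upstream of the SAM/FASTA inputs.

Problem sizes used by the test suite and acceptance script — 20 kb genome
pairs for the 100 planted-integration round trips, a 100 kb target genome
with 2,000 read pairs over 20 sites for the junction pipeline, 1 Mb for the
planted-site search — are desk-scale choices that keep every stage's
statistics meaningful (e.g. 11-mer seed noise is present at 1 Mb) while the
whole suite runs in well under a minute.

## 11. Known limitations

- `find_insertion` requires the pair to differ by insertions only; it is a
  comparative tool for assembled near-isogenic pairs, not a variant caller.
- The Karlin–Altschul K is approximate and the E-values are for ranking and
  thresholding, not for cross-tool comparison; use the BLAST-tabular ingest
  path when exact engine compatibility matters.
- The internal progressive MSA is adequate for sets of related attachment
  sites; highly divergent inputs should be aligned externally and supplied
  through the pluggable contract.
- The integration-site caller trusts the aligner's mapq and flags; it does
  not re-align reads or resolve multi-mapping.
- Greedy clustering is order-deterministic but, like all greedy centroid
  schemes, can split borderline families that an optimal clustering would
  merge.
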