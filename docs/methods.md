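# Methods

This note documents the models and procedures implemented in `pulseeker`,
the parameters that matter, the synthetic data used to validate them, and
the design choices made where the published workflow left details open.

## Annotation model

Gene roles are evidence labels, not predictions of function: a gene is a
*CAZyme* of family F only when two independent lines of evidence agree —
a profile (HMM) hit to the family model and a similarity hit to a
reference protein of the same family. The filtering stages are:

1. **Model coverage** — aligned model positions / model length ≥ 0.30.
   Coverage is computed on the model, matching the dbCAN parser
   convention, and applied uniformly to CAZyme, sulfatase, SusC and SusD
   models.
2. **Tiered e-values** — independent (per-domain) e-value ≤ 1e-5 for
   alignments > 80 residues, else ≤ 1e-3. These are the standard parser
   defaults; both caps are configuration fields.
3. **Overlap resolution** — among same-gene hits whose query regions
   overlap by more than half of the shorter region, the lowest-e-value hit
   wins (ties: higher bitscore, then lexicographic model id). Overlaps are
   measured on query coordinates, which the domtblout reader takes from
   the ali columns; when a hit is constructed without query coordinates
   they default to the model coordinates. The greedy best-first resolution
   is idempotent and equals the declarative "no better overlapping hit is
   kept" reading (property-tested against a brute-force oracle).
4. **Similarity confirmation** — ≥ 30% identity, ≥ 40% query coverage,
   e-value ≤ 1e-20, same family. Families are compared at subfamily level
   only when both labels carry a subfamily (GH5_46 confirms against a
   family-level GH5 reference but not against GH5_12), because reference
   databases often list entries at family level.

SusC (TIGR04056), SusD (PF07980, PF12741, PF14322, PF12771) and sulfatase
(PF00884) roles need only a filtered profile hit. A gene can hold several
roles at once (the sulfated-xylan patterns contain a sulfatase-domain-
containing GH10).

## Locus model

Markers (genes with any role) on one contig are chained transitively when
strictly fewer than `max_gap = 10` genes lie between consecutive markers
("less than ten genes apart" read literally; the bound is configurable).
Maximal chains with ≥ 3 markers survive unless every marker is GT-only
(all confirmed families glycosyltransferases and no other role). Retained
PULs must contain ≥ 1 susC- or susD-like gene and ≥ 2 genes with a
degradative family — GH or PL only; CE, GT and CBM do not count.

Choices made where the procedure was open: chaining is strand-agnostic;
a chain touching a contig end is reported with a truncation flag rather
than suppressed; several susC/D tandems inside one chain yield one locus
with multiple recorded pairs, and two loci are reported only when two
disjoint chains exist. Because chains are maximal, the order of chaining
and retention filtering cannot change the result.

## Substrate rules

The five substrate classes are recognised from family composition using
ten rules (shipped in `src/pulseeker/data/substrate_rules.yaml`, editable
without touching code): three β-glucan/laminarin variants (GH16+GH3;
GH16+GH30_1+GH17; GH5_46+GH16), simple and complex α-glucan (GH65+GH13;
≥ 2×GH13), sulfated and sulfatase-free α-mannose-rich (≥ 3×GH92 +
≥ 2 sulfatases; GH92+GH130+GH20+GH18 with sulfatases forbidden), two
sulfated-xylan patterns (GH10+GH3+2 sulfatases; GH30+GH10+GH43_1+3
sulfatases), and alginate (any two of PL6/PL7/PL17). Rules are evaluated
most-constrained-first and the first match wins; the number of matching
rules is recorded so ambiguous loci can be flagged. A requirement without
a subfamily suffix accepts any subfamily, mirroring the annotation
convention. A relaxed GH16-less laminarin variant-C rule (GH5_46+GH30_1)
is present but disabled by default, switchable in configuration. The
minima are distillations of prose patterns, so they deliberately live in
configuration rather than code.

## MinHash sketching and species clustering

Sketches are bottom-`s` MinHash sets over canonical k-mers (k = 21,
s = 1000), where canonical means the lexicographically smaller of a k-mer
and its reverse complement; windows containing non-ACGT characters are
skipped and counted. The hash packs the canonical k-mer into a 64-bit
integer (2 bits/base, hence k ≤ 31) and applies a splitmix64 finalizer
XOR-mixed with a recorded seed — a well-mixed, stable, seed-parameterized
hash implemented vectorized in numpy. The Jaccard index is estimated from
the shared fraction among the s smallest hashes of the merged sketch (the
union-sketch estimator), and the distance is
`D = -(1/k)·ln(2j/(1+j))`, defined as 1 when j = 0 and capped at 1.
At s = 1000 the binomial standard error of ĵ is ≤ 0.016, which the
sketch-vs-exact-Jaccard oracle tests bound at 0.05.

Genomes at distance ≤ 0.05 (≈ ≥ 95% ANI) form approximate-species
clusters by single-linkage connected components — the rule that matches
the way such clusters are depicted as edge-connected networks; complete
linkage is available in configuration. Cluster ids are assigned
deterministically by smallest member id, making clustering invariant to
input order. Gates: a multi-genome cluster needs ≥ 2 members at ≥ 70%
completeness; a singleton is excluded only when ≤ 70% complete *and*
≥ 10% contaminated (both boundaries inclusive for exclusion, per the
stated rule). Up to two representatives are picked by highest
completeness (ties: lower contamination, then id). A cluster is flagged
abundant when any per-sample RPKM exceeds 5 or the per-sample sum exceeds
38 — strict inequalities, so a sum of exactly 38 does not qualify.

## SusC/D dereplication and taxonomy voting

Same-kind genes are clustered by greedy centroid assignment at ≥ 95%
global nucleotide identity, processing sequences in descending length
(ties by id) so the outcome is order-independent. Identity is
matches / alignment columns of a Needleman–Wunsch alignment (edlib), so
gaps count against identity — the conservative denominator; at a 100%
threshold the procedure reduces to exact-sequence grouping.

Representative status requires presence in ≥ 4 metagenomes, or ≥ 3 with
proteome support (a metaproteome protein at ≥ 90% aa identity). The
"three metagenomes" arm is implemented as ≥ 3 so that gaining an
occurrence can never revoke status (monotonicity). The representative
member is the one from the most complete source genome.

Taxonomy voting counts members' Mash-cluster assignments; members without
an assignment are excluded from the denominator (the published
denominator is ambiguous — this is the recorded choice). Species-level
assignment requires the top Mash-cluster to hold at least half the votes
*and* be the unique maximum; a unique plurality below half gives a
putative assignment; otherwise, if all voted Mash-clusters share one
clade the cluster gets clade-level taxonomy, else it stays unassigned.
Requiring a unique maximum makes an exact 50/50 split between two
clusters fall through to the clade rule, which is the only reading
consistent with all three voting outcomes at once.

## Quantitation

RPKM follows the formula above exactly; it is linear in mapped reads and
consistent under merging sub-bins with length-weighted combination.
Mash-cluster abundance is the arithmetic mean over its 1–2
representatives. %NSAF is computed per experiment after technical
duplicates are merged (averaged counts by default; summation available),
and is invariant under uniform rescaling of counts. Expressed proteins
link to the representative cluster of highest global aa identity, with a
90% floor; the documented field conversion "2 RPKM ≈ 1% relative
abundance" is a calibration constant from fluorescence in situ
hybridization and is reported here for interpretation only — nothing in
the package computes it.

## Synthetic data: what it emulates, what it does not

The generator plants each locus on its own contig amid role-less
background genes, a configurable fraction of which carry sub-threshold
decoy evidence (failing coverage, the e-value tier, or similarity
identity) so the filters are actually exercised. Planted loci are emitted
both as truth labels and as raw domtblout / BLAST-tabular rows with
passing scores; decoy loci each violate exactly one retention rule
(no susC/D; one degradative CAZyme; markers exactly ten genes apart;
GT-only), and the catalogue is enumerated so precision tests are stable.
Genome pairs are i.i.d. sequences mutated site-wise at a chosen
divergence; read and spectral counts are multinomial with probabilities
proportional to abundance × length and expression × length.

What passing tests therefore show: the rules are implemented exactly and
recover planted truth perfectly under clean evidence. What they do not
show: robustness to real-data phenomena the generator does not emulate —
fragmented assemblies splitting loci across contigs, chimeric bins,
homology-driven correlated annotation errors, repeat-induced k-mer
sharing between unrelated genomes, or proteomics identification biases.
Real data will degrade recall/precision in ways planted data cannot
measure.

Default problem sizes in the test suite (50 planted loci + 40 decoys;
1 Mbp genome pairs; 20 sketch-oracle pairs at 5 kb; 100 abundance-ranking
replicates at 1e5 reads) were chosen as the smallest scales at which the
binomial/multinomial error bounds quoted above are comfortably inside the
asserted tolerances.

## Numerical choices and degenerate inputs

All thresholds sit in one `PipelineConfig` whose hash is stamped into
every output header. Ties are broken deterministically everywhere
(documented per function). Degenerate inputs raise: sequences shorter
than k, empty sequences in alignment, all-zero spectral-count columns,
zero-length genomes or zero total reads in RPKM, asymmetric distance
matrices, missing quality records. An empty RPKM sample list is treated
as all-zero (not abundant); an empty hit list filters to an empty list.

## Known limitations

- Noncanonical PULs whose susC/D tandem lies elsewhere in the genome are
  out of scope by construction of the locus rule.
- Substrate rules are pattern minima, not biochemical validation; loci
  matching several patterns are flagged, not resolved.
- Greedy centroid clustering approximates tree-based grouping; cluster
  boundaries near the 95% threshold depend on centroid choice.
- The pipeline consumes upstream outputs (gene calls, profile/similarity
  searches, completeness estimates, mapped-read counts) as given and does
  not re-derive them.
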