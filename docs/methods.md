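# Methods

This note records the models, conventions, numerical choices and known
limitations behind `barcodeid`, in the order the pipeline runs.

## Consensus assembly and quality control

A sample arrives as a forward/reverse Sanger read pair with per-base Phred
qualities. "Low quality" is operationalized as Phred < 20 — the
conventional Sanger base-call reliability floor — and a stretch qualifies
for removal when at least `min_run = 5` contiguous bases fall below the
threshold. Runs touching a read end are excised together with everything
distal; internal runs are masked to N instead of excised, because excision
would shift codon coordinates and corrupt the downstream reading-frame
screen. Trimming is idempotent.

The two reads are joined by an overlap alignment (match +1, mismatch −1,
gap −2, free end gaps; minimum overlap 50 columns — read pairs of a
~650 bp amplicon overlap almost fully). At each overlapping column the
higher-quality base wins when the strand qualities differ by at least
`similar_q_delta = 10` (a tenfold error-probability ratio); closer calls
emit the two-base IUPAC ambiguity code (R, Y, …; N if either base is N).
No published quality threshold exists for the "similar quality" branch, so
the Q-delta default is this package's choice and is configurable.

Numt screening translates all three forward frames under the vertebrate
mitochondrial code (NCBI table 2, where AGA/AGG are stops), takes the
frame minimizing internal stop codons (a stop occupying the final complete
codon is not "internal"), and flags any aligned gap run whose length is
not a multiple of 3. A sequence passes only with zero internal stops and
no frame-disrupting gap. The reading frame is inferred rather than
supplied because barcode amplicons are not guaranteed to start in frame.

Consensus sequences outside [150, 700] bases trigger a warning: usable
COI barcodes run roughly 200–650 bases.

## Reference search and candidate sets

The top-hit search is exact affine-gap Smith–Waterman (match +2, mismatch
−3, gap cost 5 + 2·length — NCBI-BLASTn-like defaults) over every
reference on both query strands. A desk-scale database (hundreds of
records) makes exactness affordable; a score-only pass ranks all records
and full alignments are computed only for records tied into the top k,
which cannot change the ranking. Percent identity counts identical (or
compatibly ambiguous, non-N) columns over all alignment columns, gaps
included; percent coverage is over the query, so a short clean query
against a full-length reference still reports 100% coverage. Ties in
score break by identity, then accession.

The candidate set for distance assignment is the top hit's entire genus —
including open-nomenclature entries ("Genus sp.", "Rajiformes sp. BOLD
AABB"), which are legal species labels here and model the
undescribed-species outcome — subsampled uniformly to 2–8 records per
species, seeded. Queries are threaded into the existing reference
alignment by a free-end-gap global alignment to the best reference,
projected through that reference's gap pattern; uncovered columns become
'?' and query insertions relative to the reference are dropped. Threading
replaces re-running a multiple aligner and never perturbs the reference
coordinate system.

## Substitution models and distances

Base order is A, C, G, T. The HKY85 transition matrix is evaluated in
closed form (the TN93 solution with equal purine and pyrimidine transition
rates), with JC69, K80 and F81 as special cases; the rate matrix is
normalized to one expected substitution per unit branch length. The
transition/transversion ratio R ("tratio") converts to the rate ratio κ
via κ = R·π_R·π_Y / (π_Aπ_G + π_Cπ_T). Rate heterogeneity uses
equal-probability discrete-gamma categories with category-mean rates (the
convention of the standard phylogenetic tools), and invariant sites mix in
with proportion p_inv. The packaged default model (frequencies 0.3624,
0.2434, 0.0914 for A, C, G with π_T by normalization; R = 6.1561;
α = 0.8490, 4 categories; p_inv = 0.4860) comes from a curated
elasmobranch COI alignment.

Pairwise distances maximize the two-sequence likelihood over t ∈ [0, 10]
by bounded scalar search, tolerance 1e-8; identical retained sites return
exactly 0. Sites are retained under pairwise deletion (both characters
unambiguous A/C/G/T), so '?'-padded threaded queries do not destroy
columns for other pairs. Matrix-scale work (distance matrices, bootstrap
replicates) runs a vectorized equivalent: coarse geometric bracketing plus
simultaneous golden-section refinement across all pairs. Distances are
reported to 4 decimals in tables.

### Model fitting and AICc selection

Candidate models {JC69, K80, F81, HKY85} × {±G} × {±I} are fitted by
composite pairwise maximum likelihood: empirical base frequencies (fixed),
then coordinate ascent alternating vectorized per-pair branch-length
optimization with Nelder–Mead over (log κ, log α, logit p_inv / 0.98).
Up to 25 rounds are allowed because κ and α trade off along a likelihood
ridge that simple alternation traverses slowly. With every pair identical
the likelihood is flat in p_inv and the estimate is reported at the upper
search bound (0.98), read as "all sites may be invariant".

Two calibrations make the composite comparable across candidates the way
a tree likelihood would be. A joint pairwise composite counts each
sequence's stationary-composition term Σ_x n_x log π_x once per pair, so
frequency-rich models (F81/HKY) would absorb the root's base-composition
sampling noise with an advantage that grows with the number of pairs —
a full-tree likelihood spends that information once. The reported
log-likelihood is therefore the *conditional* composite (composition term
subtracted; the subtraction is constant in t, κ, α, p_inv, so fitted
parameters are unchanged), scaled by 1/(n−1) so its information content
matches a disjoint pairing of the sequences. AICc uses this calibrated
value with k counting substitution parameters only (JC 0, K80 1, F81 3,
HKY 4, +1 each for G and I); per-pair branch lengths are shared nuisance
across all candidates and adding a constant to k cannot change the
ranking. n in the small-sample correction is the alignment column count.
With these calibrations, JC-simulated data ranks JC above HKY and
HKY+G+I-simulated data ranks HKY+G+I first, reproducibly — mirroring how
a full model-selection tool behaves on such data.

## Trees and bootstrap

The tree's only role is corroboration: does the query cluster with the
candidate species' references? Neighbor joining (Studier–Keppler
Q-criterion) over the ML distances preserves that decision surface at
desk scale and recovers the generating topology exactly on additive
inputs; ties in Q break deterministically by the lexicographically
smallest pair of subtree representative labels, and negative branch
estimates are clamped to zero with the deficit moved to the sister branch
(affects printed lengths, never topology). The bootstrap resamples
alignment columns with replacement, rebuilds the distance matrix and NJ
tree per replicate, and reports the percentage of usable replicates
containing each full-data bipartition; replicates in which some pair
retains no sites are dropped and counted out of the denominator.

"Clusters with" is operationalized on bipartitions: some side of a split
must consist of the query plus at least one — and nothing but — members of
the candidate species. Usually that side is the smaller one, but a
balanced two-species candidate set can put the conspecific cluster on the
larger side, so both sides are checked. The default corroboration
threshold is 70% support; raw support is always reported so stricter
cutoffs (e.g. 90) can be applied downstream.

## The assignment rule

Per query: top-hit search → congener candidate set → threading → distance
matrix → per-species average distance → candidate = the species with the
minimum average; ties break by the smaller per-species minimum distance,
then lexicographically, always flagged. The distance verdict takes
precedence over the top hit — a mislabeled reference can be any single
query's nearest neighbor, but it cannot drag down a whole species'
average — and the disagreement is preserved in a conflict flag for human
review. Tree corroboration is advisory, not veto: failed clustering
downgrades `decision_basis` from `distance+tree` to `distance-only`
without changing the candidate, because low-support clustering is the
expected behavior in recently diverged genera. No hard identity or
distance cutoff is enforced; the per-sample averages are reported so users
can apply one.

Batch runs isolate failures (one bad sample yields an error row, not an
aborted batch) and are byte-reproducible for a fixed seed.

## Conservation reporting

Composition percentages are reported to one decimal; threat fractions
round half-up to integer percent. "Threatened" is CR ∪ EN ∪ VU; DD, NE
and absent listings never count as threatened but remain in the
denominator. Teleost records are excluded from elasmobranch threat
denominators through a species→group map. The packaged fixtures encode a
63-sample Southern-Brazil market survey (20 species, 17 red-listed
elasmobranchs) and serve as both worked example and regression anchor.

## The synthetic-data generator

The generator emulates the statistical structure of a curated elasmobranch
COI reference set: ~650 bp coding sequences evolved under the default
HKY+G+I model, interspecific ML distances on the 1–15% scale (two-level
trees: Yule genus subtrees scaled to a 0.08 mean and padded so no species
pair sits closer than 0.05, genera hung off a 0.18-deep polytomy),
intraspecific variation below 1% on a star genealogy of pendant length
intra/2 (a star rather than a coalescent keeps the truth analytic — the
pipeline only consumes the resulting distance scale), and 2–8 references
per species. Per-site gamma categories and invariant flags are drawn once
and shared down the tree, as the model assumes. Market sampling is
geometrically skewed over species (a few dominant species, a long tail).

Frame safety: root sequences are drawn stop-free, and any stop codon
arising during evolution is reverted to the ancestral codon — a
purifying-selection touch-up that guarantees every generated reference
passes the Numt screen. This slightly biases composition away from the
model's stationary frequencies, so model-recovery and model-selection
experiments generate with `coding=False` to sample exactly from the
stated model.

Mislabeled reference lineages (emulating database confusion) add one
reference generated at a victim species' star center but labeled with a
congener's name: it is strictly the closest record to every victim query
(wrong top hit) while species averages still favor the truth, so the
conflict flag must fire for 100% of that lineage's queries.
Out-of-database species are withheld from the references but still
queried, emulating undescribed taxa: their top hits are congeners at
moderate identity.

Read-pair simulation covers the template 5′ and 3′ regions with
configurable overlap, declines quality linearly along each read, and
miscalls at 10^(−q/10) per base.

What passing these tests does *not* show about real data: chromatogram
artifacts, indel sequencing errors, heterogeneous reference quality and
lineage-specific compositional drift are not modeled; real reference
databases are taxonomically messier than one mislabel per scenario.

## Problem sizes used in the packaged experiments

Chosen once as representative desk-scale conditions: end-to-end market
runs use 15 species in 5 genera, 650-site barcodes (the standard COI
barcode length), 2 references per species, 0.5% intraspecific and ≥5%
interspecific divergence, 500 queries with one mislabeled lineage.
Model-selection consistency uses 12 taxa × 2000 sites, mean pairwise ML
distance 1.0 for the HKY+G+I direction (heterogeneity signal lives in
saturation, i.e. deep, order-level divergence) and 0.5 for the JC
direction, 20 seeded replicates each. Tree-engine checks use 50 random
6–10-taxon additive matrices and a 100-replicate bootstrap on a
10×-separated two-clade alignment.

## Known limitations

- nst = 6 models (GTR), codon and amino-acid models are out of scope; the
  model family tops out at HKY85+G+I.
- Pairwise composite fitting is not a full-tree likelihood; its parameter
  estimates (especially α and R, which trade off) are rougher than
  jModelTest-style estimates, though model ranking is calibrated.
- NJ + bootstrap stands in for a maximum-likelihood tree search; reports
  label the method honestly.
- Assignment assumes the true species' genus is reachable through the top
  hit; a database lacking the whole genus yields an honest low-identity
  report, not a rescue.
- No E-values or significance on search hits (scores and percents only),
  and no barcode-gap threshold optimization.
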