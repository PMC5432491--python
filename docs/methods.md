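# Methods

## Scope and data model

`pedscan` analyses panels of fully homozygous (inbred or
doubled-haploid) lines. Each line contributes exactly one haplotype, so
a diploid genotype collapses to a single call per marker, coded 0
(reference), 1 (alternate) or missing. Markers live on a physical map
(chromosomes A01–A10 / C01–C09 of the allotetraploid AC genome; the
first character of the chromosome name assigns the subgenome) with
1-based bp positions, strictly increasing within a chromosome. Exported
BED is 0-based half-open. Residual heterozygous calls in VCF input are
set to missing and counted in a QC summary rather than rejected:
SNP-array data from nominally inbred material routinely contain a small
heterozygous fraction.

A diploid A-genome relative in the pedigree (in the motivating study,
*B. rapa* cv. Chengduai) is carried with all-missing C-subgenome
columns rather than excluded; downstream operations skip all-missing
spans.

## IBD detection

Because haplotypes are observed directly, IBD blocks between two lines
are maximal runs of concordant calls. The scanner proceeds left to
right per chromosome:

* concordant markers extend the current run;
* a comparison missing in either line neither extends nor breaks it,
  unless more than `max_missing_gap_markers` (default 50) consecutive
  comparisons are missing;
* a discordant marker is absorbed while the running mismatch fraction
  stays ≤ `max_mismatch_fraction` (default 0.02, sized for array-level
  genotyping error); otherwise the run closes — ties are resolved by
  extending the left run greedily, and the closed run is trimmed to its
  last concordant marker, so every reported block starts and ends on
  direct evidence of sharing;
* runs are reported when they cover ≥ `min_markers` (default 20)
  compared markers and span ≥ `min_length_mb` (default 1.0 Mb).

Segment length in Mb is `end_bp − start_bp` (no +1), the convention
under which Mb totals are conventionally summed. Defaults were chosen
so that error-free simulations recover the planted truth; all four
thresholds are configuration-exposed because no segment-level minima
are forced by the data model.

With zero mismatch tolerance, "maximal run" is well defined
independently of scan order, and the detector is tested for exact
equality against an enumerate-all-runs oracle. With mismatch
absorption the greedy rule is path-dependent; there the tested
invariants are concordant endpoints, the interior mismatch cap, and
per-pair non-overlap.

A caveat that matters for scoring: beyond a true recombination
breakpoint, the neighbouring foreign haplotype remains concordant by
chance (identity in state) with probability Σp²+q² per marker, so the
detected boundary overshoots the true one by a geometrically
distributed number of markers — with founder allele frequencies at 0.5,
a mean of one inter-marker interval. Accuracy is therefore summarised
by markerwise precision/recall plus both the mean and the median
boundary error in inter-marker intervals; the median is the robust
figure (its expectation is 0–1 interval under chance extension, while
the mean sits at ~1 by construction).

## Transfer classification and expected contributions

The pedigree is a directed acyclic graph of parent→offspring edges
(≤ 2 parents per node). A transfer is *direct* iff a single edge
connects ancestor to descendant — even when material also flows through
other routes — and *indirect* when only paths of ≥ 2 edges exist.
Per-pair IBD counts and Mb totals aggregate into per-pedigree
direct/indirect subtotals; pairs absent from the pedigree are flagged
and excluded from subtotals.

The theoretical genome fraction contributed by an ancestor is
Σ_paths (1/2)^(edges), each cross halving the expectation. This ignores
selection and any undocumented parents, so it is an approximation for
real pedigrees whose ancestry is only partially recorded (ungenotyped
parents are known to carry substantial fractions in the motivating
material).

## Selection scan

Panels are the cultivars of one pedigree (five lines each in the study
configuration; n is the panel size, each homozygous line counted once).
Per window of `window` = 15 consecutive *usable* loci, advancing
`step` = 1 locus, with the value assigned to the window midpoint (8th
locus):

* S = segregating sites; π = mean over all C(n,2) line pairs of the
  number of sites where the pair differs (sites missing in either
  member contribute nothing to that pair);
* Tajima's D = (π − S/a₁)/√(e₁S + e₂S(S−1)) with the standard
  constants computed from n; D is undefined for S = 0, a vanishing
  variance term, or n < 3, and undefined windows are excluded from
  genome-wide means (the genome value is the mean over defined
  windows);
* H_S = mean over the 15 loci of 1 − q² − (1−q)², algebraically
  2q(1−q); PIC = mean of 1 − (p² + q²) − 2p²q² (biallelic Botstein
  form — the informativeness measure is bounded by 0.375);

A locus is usable when ≥ 2 panel lines have calls; monomorphic loci are
retained (the 15-locus unit is defined on array loci, not segregating
sites), loci with < 2 calls are dropped, and chromosomes with fewer
than 15 usable loci are skipped with a log entry. Windows never cross
chromosomes.

Note a subtlety of the pair-averaged π: duplicating every line does not
leave π unchanged — identical copies contribute zero-difference pairs,
rescaling π by exactly 2(n−1)/(2n−1). The test suite asserts this
exact relation against the pair-enumeration oracle.

**Quadrant classification.** With thresholds D = 0 and H_S = 0.3, the
default ("main text") convention reads: (D<0, H_S<0.3) → selection in
earlier breeding cycles; (D<0, H_S>0.3) → later cycles; (D>0,
H_S<0.3) → selection predating the pedigree founders; (D>0, H_S>0.3) →
no evidence of selection. Published descriptions of this scheme
disagree internally on the early/late assignment, so an alternative
"figure legend" convention that swaps the two is available behind a
switch; the package does not attempt to adjudicate. Exact boundary
values (D = 0 or H_S = 0.3) return no_selection with a boundary flag.

## LD decay and gene clusters

r² between two markers on one chromosome is computed from observed
haplotype frequencies over lines non-missing at both:
r² = (p_AB − p_A p_B)²/(p_A(1−p_A)p_B(1−p_B)); non-segregating pairs
and pairs with < 2 shared calls are skipped. Pair enumeration is
bounded by a maximum distance (default 10 Mb) and optionally a sliding
marker window (default 50 markers, step = half a window) on dense maps.

The decay curve is r²(d) = 1/(1 + βd): it satisfies the anchor
r²(0) = 1 exactly with a single parameter, and crossing the
conventional threshold r² = 0.2 gives decay distance d = 4/β. The fit
is least squares on log β (keeping β > 0); when β is numerically zero
the decay distance is reported as infinite (threshold never reached).
The Hill–Weir drift expectation is available as an alternative form
(requires the panel size). Both the plain all-pairs mean r² and the
windowed pair set are available, since a mean can be defined over
either.

Gene clusters: on each chromosome, trait genes join a cluster by single
linkage while the gap between consecutive intervals (next start minus
previous end, floored at 0) is at most `gap_mb` — by default the fitted
decay distance (0.7 Mb in the motivating study). Clusters carry the
union of member traits and transfer pedigrees; one-gene groups are
flagged singletons.

## QTL × IBD overlap

A QTL is "in IBD" on ≥ 1 bp of overlap with any segment of the
pedigree's pairs (no minimum overlap — a containment requirement would
silently depend on QTL interval widths). Candidate genes must by
default lie fully inside the QTL∩IBD interval (flag to relax to any
overlap, trading boundary-inflated counts for sensitivity). Donor
lineage lists every pedigree path from the IBD pair's ancestor member
to its descendant member. Selection annotation takes the quadrant of
the scan window whose midpoint is nearest the gene midpoint, ties going
to the lower coordinate; genes on chromosomes without windows stay
unannotated and are logged.

## Synthetic pedigree generator

The generator is the source of ground truth, so its bookkeeping is
exact rather than approximate:

* **Founders** — mutually independent homozygous lines; per-marker
  alternate-allele frequencies drawn from a configured distribution
  (uniform on [0.2, 0.8] by default; fixed 0.5 in truth-recovery runs
  to make identity-in-state maximally unlikely).
* **Crosses** — one recombinant gamete per chromosome per offspring:
  crossover count ~ Poisson(length in Morgans), breakpoints uniform in
  genetic distance; with a uniform cM/Mb map (default 2 cM/Mb) that is
  uniform in bp. The gamete is doubled to homozygosity (DH endpoint),
  matching doubled-haploid breeding material and keeping every line
  fully homozygous. Repeated selfing is not modelled.
* **Ancestry tracks** — every allele records the founder it descends
  from and the parent that transmitted it, so true IBD segments,
  crossover positions and realized genome fractions are read off
  exactly, and truth segments from one generation tile each chromosome
  without overlap.
* **Selection** — directional selection at target loci by gamete
  rejection: whenever a parent carries the favored founder's allele at
  the target, offspring gametes are redrawn until the offspring does.
  This fixes the allele deterministically in all downstream
  descendants, mimicking breeder mass selection, rather than modelling
  a fitness gradient.
* **Noise** — genotyping error flips calls at a configured rate;
  missingness is applied last; diploid-A lines get all-missing
  C-subgenome columns.

Default scale: 4 chromosomes (2 A + 2 C) of 11 Mb with 500 evenly
spaced markers (~45 markers/Mb, the density of a 60K array on the
~650 Mb mapped rapeseed genome), chosen so that full pipeline runs and
replicate-based tests complete in seconds. The generator emulates a
documented breeding history with known founders; it does **not**
emulate coalescent ancestry behind the founders, mutation during
breeding, homoeologous exchange between subgenomes, ascertainment bias
of array probes, or ungenotyped extra parents. Passing truth-recovery
tests therefore demonstrates correctness of the algorithms under the
stated model, not robustness to those real-data features.

## Numerical and reproducibility choices

* Tajima constants are computed per panel size n from their defining
  sums; the window statistic is checked against an independent
  pair-enumeration oracle to 1e-12.
* The decay fit optimises log β, making positivity structural; the
  threshold crossing is analytic for the rational form and bracketed
  brentq for Hill–Weir.
* The pipeline derives per-stage seeds by hashing the global seed with
  the stage name (all below 2³¹), so adding a stage never perturbs the
  randomness of earlier ones; reruns of the same configuration are
  byte-identical, and the run manifest records the seed and a hash of
  the resolved configuration.
* Degenerate inputs fail loudly where silence would corrupt results
  (cycles or >2 parents in a pedigree, unknown marker or sample ids,
  unsorted maps, selection targets off the map) and degrade gracefully
  where the data model predicts them (all-missing chromosomes,
  chromosomes with too few usable loci, unannotatable genes).

## Known limitations

* The concordance-run detector assumes homozygous material; it is not
  a substitute for probabilistic IBD inference in heterozygous or
  unphased panels.
* Direct/indirect classification and expected contributions are only
  as complete as the documented pedigree; missing parents bias both.
* With small panels (n = 5) Tajima's D per 15-locus window is coarse;
  quadrant calls near the thresholds should be read with the boundary
  flag in mind.
* The LD decay distance depends on the assumed functional form at long
  distances; the rational and Hill–Weir forms can differ there.
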