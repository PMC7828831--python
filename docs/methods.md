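# Methods

## Scope and data model

The package analyses bi-allelic SNP panels on the male-specific Y
chromosome. Because the region does not recombine, a sample's calls across
all panel sites form one haplotype, stored relative to an ancestral state
inferred from outgroup consensus: every call is ancestral, derived or
missing (`HaplotypeMatrix`). The packaged panel is a transcription of a
published table of 19 male red foxes × 31 variable sites (plus the
all-ancestral root row); 13 sites carry a validated genotyping assay, and
two Alaskan samples were genotyped at those 13 loci but not successfully
sequenced, so they are missing at the other 18 sites. The locus dropped
during assay validation for amplifying in females is recorded in the
panel's metadata under both names it appears under in the source material
(20_357AT and 20_349AT); the transcription does not guess which is correct.

Apparent heterozygosity in a male is treated purely as a paralogy signal:
het calls are never decoded into the matrix, only flagged on the site.

## Depth-window classification

Classification uses pooled depth (summed over the males of one species),
matching how the windows were defined; per-sample depths are carried along
but not thresholded. Windows are inclusive integer intervals; the defaults
(≤9 error, 10–160 unique, 161–210 two-paralog, >210 multi-paralog) mirror
the published red fox panel. `suggest_windows` estimates windows from data:
a Gaussian KDE with an absolute bandwidth in depth units (default 10×,
roughly the spacing needed to separate an 85× unique mode from a 185×
two-paralog mode without splitting either) is evaluated on a grid extended
below zero (so a near-zero error mode is not a boundary artifact); modes
are local maxima whose prominence is at least 5% of their own height —
relative to the peak, not the global maximum, because the unique mode
dominates the density — and boundaries are the deepest valleys between the
first four modes. With exactly three modes the error class is left empty;
with fewer the function refuses and asks for manual windows. Both the depth
window and the het flag must pass for a site to be UNIQUE_Y; the summary
reports each filter's marginal effect because the original order of the two
filters is not recoverable.

## Site filters

*Orthologous/variable sets*: columns with a gap in any taxon are removed;
the variable set is the strictly-within-ingroup polymorphic subset, in site
order. *Assay validation*: a locus is dropped when it amplifies in more
than `locus_drop_fraction` (default 0.25) of females. The default separates
the two regimes seen in practice — a non-specific locus amplifying in 74%
of females versus sporadic ~3.5% false positives — with a wide margin on
either side. The false-positive rate is computed per call
(female-positive calls / retained loci × females); a per-locus-per-female
alternative would be the fraction of loci with any positive, which is not
what is reported here. *Imputation* is deliberately conservative: a missing
call is filled only when every complete haplotype matching the focal row at
all its non-missing sites agrees at the missing site. Ties or absence of a
matching complete row leave the call missing, which makes the operation
idempotent and incapable of inventing recombinant haplotypes.

## T92 distances and calibration

θ is the GC content pooled over both compared sequences (the standard
convention when no per-branch composition model is wanted); gap/ambiguous
columns are deleted pairwise. The estimator raises a `SaturationError`
outside its log domain rather than clamping. Bootstrap SEs resample sites
with replacement — implemented as a multinomial draw over the nine distinct
column types (identical/transition/transversion × 0/1/2 GC bases), which is
exactly equivalent and runs in vectorised time; saturated replicates are
dropped, and an error is raised only if all replicates saturate. At θ = ½
the distance reduces to the Kimura two-parameter closed form, which the
tests verify to machine precision.

Calibration scales a dated outgroup split: t = t_out · d_in / mean(d_outs).
When several outgroups share one calibration age their distances are
averaged (each can also be reported separately). The interval propagates
only the ingroup distance SE; outgroup distance and calibration age are
treated as fixed, which understates total uncertainty but matches the
reporting convention of the source analysis. Between-group distance is the
mean over between-group pairs. A neighbor-joining tree from the T92 matrix
(scikit-bio) is available for visual checks only — no likelihood search,
bootstrap support or model selection is implemented.

## Median-joining networks

States are binary per site, so the Bandelt quasi-median of a triple
collapses to the sitewise majority vector. Construction: (1) collapse
identical rows into nodes weighted by multiplicity; (2) link nodes with the
ε-relaxed minimum spanning network — a link is kept iff its Hamming weight
is within ε of the level at which its endpoints' components fuse under
Kruskal processing, which at ε = 0 is exactly the union of all minimum
spanning trees; (3) for each triple with ≥2 links, insert the majority
median when its connection cost does not exceed the triple's current
two-link cost plus ε; (4) iterate to fixpoint; (5) prune median nodes of
degree ≤2 lying on no shortest path between observed nodes; (6) attach the
root haplotype (outgroup consensus, by default the all-ancestral vector),
as a multiplicity-0 node if no node already carries that state. ε defaults
to 0, the conventional default when none is stated; character weights are
uniform. All tie-breaks (node processing, triple enumeration, median
naming) are lexicographic, so construction is deterministic. On
homoplasy-free data the result is exactly the generating genealogy with
unsampled ancestors materialised as medians, which the tests verify on 100
simulated histories.

## Rho statistics

Reticulations are resolved to a shortest-path tree from the designated
ancestral node (deterministic lexicographic tie-break) before any rho
computation. rho is the multiplicity-weighted mean path length from the
ancestral node to each member's node; the Saillard standard deviation
treats each unit of edge weight as one mutational link subtending the
members below it. The nested clade's ancestral node is the node carrying
exactly the mutations shared by every clade member, materialised as a
median node when absent. Age bounds move the clade rho by one SD while
holding the total rho fixed — the rule that reproduces the published
ranges from the published rho values exactly — and are reported at two
significant figures.

Recomputing rho from the packaged transcription gives 13.8 (total) and 4.8
(clade) on the 31-site network and 5.7 (total) on the 13-locus network,
versus published 13.00, 3.82 and 4.80; the 13-locus clade estimate (1.77,
SD 0.98) matches exactly. The node choices and any haplotype weighting
inside the original network program are not recoverable from the source
material, so the non-matching values are kept as regression anchors with a
30% tolerance rather than strict expectations, while all ratio/age
arithmetic from the published rho values is tested exactly.

## Synthetic data

The split-haplotype generator emulates the inferred history: a basal
two-clade split at relative depth `t_total` with a nested clade (the
trans-Pacific transfer) at `t_clade`, star genealogies within groups,
Poisson(μ × branch length) mutations under infinite sites (each mutation a
fresh site, so no homoplasy by construction). μ is parameterised in
mutations per lineage per unit depth to match the rho scale; validation
runs use an expected total depth of 13 mutations, matching the observed
panel. It does not model population-level coalescence within clades,
migration after the split, or homoplasy — so network-recovery tests show
correctness of the algorithms on clean genealogies, not robustness to
recurrent mutation. The depth generator draws pooled depths from a
four-component negative-binomial mixture (means 3/85/185/400×, the unique
component at 85.3%, matching the published site fractions; overdispersion
is universal in capture data, with Poisson selectable), splits them
multinomially across males, and assigns het flags with per-class
probabilities (0/0/0.6/0.6 — paralog classes show heterozygosity, unique
sites do not). The T92 generator evolves a stationary ancestor through the
exact transition-probability matrix (matrix exponential of the normalised
generator).

## Problem sizes and numerical choices

Simulation-based checks use sizes at which Monte-Carlo error is small
relative to the tested tolerances: 200 replicates for estimator-consistency
and ratio-recovery means (compared at 2 Monte-Carlo SEs), 100 replicates
for tree recovery and clock-trio calibration (10% tolerance), alignments of
L = 20,000 sites — the scale of the real concatenated Y alignment.
Bootstrap SEs default to 1,000 replicates. All generators and resamplers
take explicit integer seeds; fixed seeds make every stochastic test
reproducible. Degenerate inputs fail loudly: saturated distances, unimodal
depth distributions, matrices with missing calls passed to network
construction, and zero-female validation tables all raise with directions.

## Known limitations

Only bi-allelic sites are supported in networks (multi-allelic VCF records
are routed to filtering, never kept silently). No rate heterogeneity or
relaxed clocks in dating; no reduced-median preprocessing or multistate
characters in networks; no mutation-rate-based rho calibration (ratio
calibration only). The published 470,000-year total split cannot be
recomputed here because the underlying alignment was never deposited; it
enters only as the calibration constant `t_total`.
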