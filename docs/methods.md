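# Methods

This note records the statistical model behind each module, the defaults
and why they were chosen, what the synthetic generator does and does not
emulate, and the numerical conventions.

## Consensus delimitation

Input is a set of ≥ 2 partial partitions of a specimen set, one flagged as
the tie-breaking (integrative) partition, which must cover every specimen.
Cluster labels are opaque; two restricted partitions are equal when their
sets of specimen sets coincide.

The co-clustering graph has an edge between two specimens whenever *any*
method places them in one cluster; its connected components are the
minimal units on which delimitation decisions are independent, and all
resolution happens component-wise. A method votes in a component only if
it covers all of the component's specimens — a partial restriction is not
a well-defined candidate partition, so partial coverage counts as
abstention. The modal restriction wins; when two or more restrictions tie
for the mode, the tiebreaker's restriction is adopted even if it is not
itself modal. A component where every method abstains is an error (it
cannot arise when the tiebreaker is total), as is a tie where the
tiebreaker abstains.

Consensus labels are zero-padded integers assigned in sorted order of each
cluster's smallest specimen id. This makes the output invariant to the
listing order of partitions and specimens, which is asserted by property
tests against an independently written exhaustive reference
implementation on all instances with ≤ 8 specimens and ≤ 4 methods.

`count_splits(a, b)` counts clusters of `a` (restricted to the jointly
covered specimens) whose members fall into ≥ 2 clusters of `b`; a cluster
cut into many pieces counts once. Counting divided clusters rather than
cut events is a deliberate choice — "split N times" is otherwise
ambiguous — and is documented here rather than configurable.

## Accounting

`classify_species` derives categories from consensus clusters joined to
curated specimen metadata: a cluster with no morphospecies on its
specimens is `unidentified`; within a morphospecies that carries a
described name somewhere in the data, the cluster holding a name-carrying
specimen is `known` and the others are `hidden`; morphospecies never
formally described yield `new_phenotype`. Hidden lineages whose
morphospecies lost its name carrier (e.g. unidentifiable material) are
deliberately classed `new_phenotype`: the hidden category is anchored to
presumably known taxa.

The hidden-diversity ratio of a complex is (hidden + described)/described
with described ≥ 1. Class means are unweighted arithmetic means over
complexes (pantropical → R_pantropical; bicontinental and
continental-wide pooled → R_wide; narrow fixed at 1.0, i.e. hidden
diversity in narrow endemics is not extrapolated). A
described-count-weighted mean is available via `weight_by="described"`;
the unweighted default reflects the convention of reporting per-complex
ratios. Classes with no complexes are reported absent rather than zero so
a caller can distinguish "no hidden diversity observed" from "no
information".

## Forecast

G = E + D_narrow + (r − 1)·c + r·(D_pan·R_pan + D_wide·R_wide), with
r the global:sampled area ratio. Two conventions are preserved exactly as
used in practice and deserve flagging:

* D_narrow (and E itself) enter **once**, unscaled by r. The asymmetry is
  intentional in the source methodology; the generalized form (D_narrow
  also scaled) is available behind `scale_narrow=True` for exploration
  only and is never the default.
* The point estimate is rounded half-up, and the multiplicative
  uncertainty band (default ±25%) is applied to the **rounded** point.
  Applying it to the unrounded value produces a .5 rounding ambiguity at
  the upper bound; rounding first gives stable integers.

An alternative bounds mode recomputes G at (E_low, r_low) and
(E_high, r_high). `sensitivity_table` exposes the affine dependence of G
on r: the finite difference per unit of r is exactly
D_pan·R_pan + D_wide·R_wide + c.

## Incidence richness

Chao2 uses the classic form when duplicates exist and the bias-corrected
form otherwise (the standard convention); both are selectable. The
variance uses the classic Q1/Q2 expansion with the (T−1)/T correction, or
the bias-corrected variance when Q2 = 0, and the 95% CI places a
log-normal interval on D̂ = Ŝ − S_obs so the lower bound cannot fall below
the observed richness. Rarefaction is the exact hypergeometric expectation
S(t) = S_obs − Σ C(T−Y_i, t)/C(T, t), evaluated with log-gamma binomials
so large T cannot overflow; extrapolation uses
S(T+t*) = S_obs + Q̂0·[1 − (1 − Q1/(Q1 + T·Q̂0))^t*], which is continuous
with rarefaction at t = T and converges to the Chao2 asymptote. Species
rows with zero incidences are dropped with a warning (curated tables often
list unsampled taxa) rather than rejected.

Curve bands are percentile bootstrap (2.5/97.5) over resamples of sampling
units with replacement; point estimates come from the observed matrix and
are seed-independent. Note that a resampled curve evaluated at t = T
equals the *resample's* observed richness, so the band at the observed
design hugs the resampled statistic rather than centring on S_obs; the
analytic variance expansion was deliberately not used because the bands
reported in practice come from package-specific recipes that are not
printed, and the percentile band is assumption-light.

## Biogeography

Range breadth from a territory set: pantropical requires presence in all
flagged major tropical regions; otherwise ≥ 2 regions → bicontinental,
one region with ≥ 2 territories → continental-wide, a single territory →
narrow. Ranges spanning ≥ 3 regions without covering all tropical regions
are classed bicontinental — they pool into the same wide class either
way. The pantropical rule and thresholds live in one function so
alternatives (e.g. ≥ 2 regions spanning both hemispheres) can be swapped
in.

The phenotype-vs-integrative intercontinental comparison merges species by
morphospecies (union of ranges) before computing the fraction of taxa in
≥ 2 regions. Merging never shrinks a range, but it also shrinks the
denominator, so the phenotype fraction dominates the integrative one only
when lineages sharing a name are each mono-regional — the cryptic-complex
situation this analysis exists for. The property tests generate tables
with exactly that structure; the dominance is *not* claimed for arbitrary
tables, and the fraction can invert when genuinely intercontinental
species are lumped.

Percentages are rounded half-up at the precision customary for each
statistic (whole percent for endemism, one decimal for concept
fractions); similarity values are reported unrounded.

## Synthetic generator

The generator emulates the statistical structure of a global barcoding
study of a hyperdiverse leaf-dwelling lichen family, not its sequences or
trees: partitions are produced directly from the true species partition.

Defaults (chosen once, as study-realistic values): 473 true species; 32
territories in 5 floristic realms mapped onto 4 lichenogeographical
regions (3 tropical); breadth weights 0.84/0.11/0.04/0.01 for
narrow/continental-wide/bicontinental/pantropical, matching the observed
dominance of single-territory endemics; complex sizes geometric with
p = 0.33 truncated at 35 (heavy right tail, mode 1, mean ≈ 3, consistent
with observed per-complex ratios between 1:1 and 28:1 and a largest
complex of 35 lineages); prop_described = 0.76 and
prop_unidentifiable = 0.12, which together reproduce a category mix close
to 104/213/100/56 at 473 species; ~2.7 specimens per species (Poisson);
10 localities per territory; method coverages 0.64/0.76/0.35/1.0
emulating single-locus completeness alongside a complete integrative
partition, with split rates 0.05–0.10 and lump rates 0.02–0.10.

Splitting cuts a cluster into a uniformly random proper bipartition;
lumping merges randomly paired clusters within a morphospecies only.
Errors therefore stay biologically shaped — oversplitting within lineages
and lumping of look-alikes — and never fuse unrelated complexes. One
global seed drives per-operation derived streams (keyed by stable CRC32
hashes, not Python's salted `hash`), so identical configurations yield
byte-identical fixture files and stages can be regenerated independently.

What the generator does **not** emulate: phylogenetic signal (no trees,
no correlation of method errors along branches), correlation between
complex size and range breadth (real pantropical complexes are the
largest; here breadth is drawn per species independently of complex
size), uneven sampling effort across territories, and spatial
autocorrelation of localities. Passing tests therefore demonstrate the
correctness and stability of the inference chain under the stated
generative assumptions, not robustness to every bias of field data.

### True global richness and parameter recovery

The generator states its own implied global richness by applying the
forecast identity to the truth table: the true sampled-species count and
category tallies (a described complex counts as anchored only if its name
carrier was sampled), true per-class mean hidden ratios among sampled
complexes with breadth from true ranges, the configured
unsequenced-described ledger and area ratio. The recovery test demands
that the pipeline — consensus over noisy partitions, category
classification from specimen metadata, ratio re-estimation, forecast —
lands within 15% of this value on average over 20 seeds at ≥ 400 species.
Under the defaults the observed mean error is a few percent; the error
budget is consumed by consensus mistakes, mis-anchored complexes and
breadth misclassification from partially observed ranges.

## Problem sizes in the test suite

Property tests run 100–300 generated cases each (derandomised);
exhaustive oracles are applied on instances small enough to enumerate
(≤ 8 specimens for consensus, T ≤ 10 units for rarefaction subsets). The
end-to-end recovery check simulates 20 studies of 473 species
(~1,250 specimens each), the scale the defaults are calibrated to.

## Known limitations

* The consensus resolves conflicts on minimal components; whether
  manual curation would resolve at whole-clade scope instead is a
  judgement call the module does not attempt to model.
* The forecast is a deterministic accounting identity; no sampling model
  underlies its uncertainty band beyond the multiplicative fraction.
* Chao2 is a lower-bound estimator; with many uniques (as synthetic
  territory matrices produce) the asymptote is far above S_obs and should
  be read as "at least this many".
* Hidden-ratio class means are sensitive to the few large complexes in
  small pools; the described-weighted alternative is provided but no
  variance is attached to either.
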