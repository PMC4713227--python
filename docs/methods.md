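# Methods

## The threshold-logic disc model

The antennal disc is reduced to a 1-D radial axis r ∈ [0, 1] (r = 0 disc
centre, r = 1 periphery) sampled at `grid_size` cell centres
r_i = (i + ½)/N.  Sampling at cell centres keeps ring boundaries off the
sample points, so the segmented code sequence is identical for any grid
that resolves every ring (the suite checks N = 1000 against N = 500).  The
morphogen is the dimensionless E(r) = 1 − r: monotone, highest at the
centre, with no attempt to model real EGF kinetics — only the ordering of
positions matters, and every threshold is a free parameter.

The network is evaluated as an acyclic feed-forward pass in the fixed order
E → Dac → Ap → Rn → Bar → Bab, not as a dynamical Boolean system iterated
to a fixed point.  The biology being modelled is a static late-third-instar
snapshot, and all of the cross-regulatory rules order consistently along
that chain, so introducing unstated dynamics would add assumptions without
adding constraints.  Feed-forward evaluation also makes determinism and
idempotence trivial properties of the contract.

Rules (defaults in parentheses; all thresholds act on E):

| factor | rule | default |
| --- | --- | --- |
| Dac | ON iff E < θ_dac | 0.40 |
| Ap | ON iff E ≥ θ_ap | 0.55 |
| Rn | ON iff θ_rn,low < E ≤ θ_rn,high | 0.12, 0.70 |
| Bar | ON iff Dac OFF ∧ E < θ_bar,centre ∧ (Rn OFF ∨ Ap ON) | 0.85 |
| Bab | per-ring ordinal class (absent/low/mid/high) | see below |

Default ring boundary radii are (0.15, 0.30, 0.45, 0.60, 0.75, 0.88),
centre → periphery; the R(4)/R(5) boundary (r = 0.45) is the central fold,
defined as the outer edge of the Ap-ON region.  The widths are free
geometry, not measurements.

Bar's competence is modelled as "everywhere except the Dac domain and the
centremost zone", with Rn repression gated by Ap.  The identity of the
centremost Bar repressor is unknown; it is represented by the θ_bar,centre
cutoff and nothing more.  This single rule reproduces the wild type, the
rn-null expansion (Bar fills everything between the central zone and Dac's
inner boundary), Ap overexpression (Bar invades R(4) because forced Ap
lifts Rn's repression) and constitutive EGFR signalling (Bar meets Dac).

Bab's authoritative state is an ordinal class per ring — absent in
R(1)/R(2), low in R(3) and R(7), high in R(4)/R(5), mid in R(6) — peaking
near the central fold and decaying toward both edges.  The underlying
evidence is qualitative antibody staining; a calibrated continuous gradient
would imply precision the data lack.  A numeric profile
(class/3 × κ) is carried for plotting only.  The hypomorph multiplier
κ ∈ (0, 1] demotes every ring's class by one step when κ < 0.8 (a single
ordinal step is the finest change the class scale supports); an rn-null
perturbation applies κ = 0.6 automatically, since Rn is a positive
regulator of Bab and Bab staining weakens in rn mutants.

### Two morphogen layers

Perturbations of EGFR signalling (`boost_morphogen`) raise an *effective*
morphogen E_eff read by Ap, Rn and Bar; Dac and the centremost Bar cutoff
are evaluated on the *baseline* E.  Rationale: Dac's domain is established
earlier in development than the snapshot modelled here, and the centremost
repressor is an unknown factor anchored to disc position, not an EGFR
readout.  Reading every rule off the boosted field would make a boost in
the rn domain erase Dac from R(2)/R(3) and extinguish Bar in R(5) —
contradicting the observed phenotype, where Bar expands until it abuts an
intact Dac domain while the central fold moves outward.  With the split,
the default boost magnitude 0.3 in the rn driver domain reproduces exactly
that: Rn silenced where E_eff exceeds θ_rn,high, Bar–Dac abutment, fold
displaced outward.

### Perturbation semantics

One perturbation per gene; a second on the same gene is a validation error
naming both.  `null` clears the factor; `force_on_in_domain` sets it within
a named driver domain (driver predicates are evaluated on the unperturbed
wild-type pattern, emulating GAL4 lines); `scale_level` multiplies Bab's κ;
`boost_morphogen` is EGFR-only.  Ap overexpression represses Rn only where
the driver overlaps the endogenous Ap zone — the observation is consistent
with either a zone-restricted or a dosage effect, and the restricted
reading is the weaker assumption.  It also reduces Dac where the driver
overlaps Dac; since the observation is a decrease rather than a loss, the
Dac call is kept and a `dac_reduced` flag is raised, which propagates into
ring-map diffs.  Bar overexpression abolishes the central fold (a
morphological consequence, flagged on the state) and leaves Ap, Bab and Dac
untouched.

Known model/observation discrepancy, surfaced rather than fudged: under Ap
overexpression the model extends Bar across all of former R(4), giving that
domain the exact quadruple R(5) code, whereas in tissue the extension is
incomplete and a residual Rn+/Bar− subpopulation persists within R(4).
Downstream, the relocated-but-unchanged R(5) label is flagged `relocated`
in diffs and its fates are called unchanged.

## Segmentation and classification

A ring is a maximal run of positions with identical factor ON-sets; Bab's
level class never splits rings (rings are code-defined; the level
sub-specifies fates within a ring) and is recorded as the modal class, ties
resolved toward the higher class.  Extents are half-open [inner, outer)
intervals with boundaries at midpoints between samples, tiling [0, 1].

Perturbed rings are labelled by minimal code distance to the wild-type
reference: Hamming distance over {Dac, Rn, Bab} at weight 1 plus weight ½
for each of Ap and Bar, so the partially redundant Ap/Bar pair jointly
contributes at most 1.  A full merge of Ap and Bar into one presence bit
would make the R(6) and R(7) reference codes indistinguishable; the
half-weight form keeps them apart while still placing the rn-mutant code
{Bar, Bab} nearest R(6) (missing Ap, distance ½) rather than two steps from
R(4).  Ties at the minimum are broken by factor priority
Rn > Dac > Bar/Ap > Bab, then by the outermost reference ring, and are
flagged in the output rather than silently resolved.  Labels need not be
unique after classification (an rn-null map legitimately carries two R(6)
domains); per-label extent sums drive the diffs, where a label expanded iff
its total extent strictly grew.  An unchanged R(7) under rn-null is flagged
`paper_silent`: the source data do not constrain R(7)'s extent there.

## Fate mapping

The bundled reporter table (19 antennal sensilla subtypes, 44 ORN-class
rows, three-valued calls +/w/−) aggregates to per-sensilla codes: positive
for a factor iff any constituent class is positive or weak, with weak-only
support retained in a `weak_set` (weak counts as positive — at1's weak rn
call is what places it in an rn-positive ring).  Four documented overrides
apply, each carrying its provenance: the adult bab-reporter signal in
ab1/ab9/ab3 is dropped (no Bab+Dac+Rn− ring exists in the disc; late or
artifactual reporter expression), the Dac call contributed by IR75d rows is
dropped and its Bar call explicitly kept (IR75d is the only class spanning
several subtypes, and its extra calls cannot be separated from reporter
artifacts), and ab3 is flagged ambiguous with alternate ring R(7).

Assignment is superset matching: adult reporter expression may miss factors
that act only transiently in precursors, so a ring is a candidate when its
code contains the sensilla code — subject to hard constraints that rings
expressing Rn (resp. Dac) admit only rn- (resp. dac-) positive sensilla,
because both reporters faithfully mark their lineages.  Among candidates
the fewest surplus factors win; unresolved ties are reported ambiguous, and
a code with no positive factor is never silently assigned (no positive
evidence, no mapping).  Exact-equality matching would leave ab2/ab8 ({Ap})
and ac4 ({Bar, Bab, Rn}) unplaceable; minimal-surplus subset matching
reproduces every published assignment, including those.  The resulting map
— R(1):{ab1,ab3,ab9}, R(2):{ab10}, R(3):{ab7,ai1}, R(4):{at1,at3,ab5},
R(5):{ac1,ac4}, R(6):{at4,ac2}, R(7):{at2,ab2,ab4,ab6,ab8,ac3} — is frozen
as `expected_fate_map()` and is the module's golden test, basis flags
included.  Palp sensilla (pb1–pb3) are out of scope.

## Perturbation predictions

Territorial deltas compare per-label extents: fates of labels that gained
extent expand, of labels that lost or vanished are reduced or lost, and a
disappeared domain records which labels absorbed its territory.  Within-
ring Bab conversions use a threshold table: donor fates (ai1, at3, ac1,
ab2, ab6) require their ring's full wild-type class; the default fates
(ab7, at1/ab5, ac4, at2) require none; ab4/ab8/ac3 are unconstrained; R(6)
is wide-tolerance and never converts.  A hypomorph below the κ cutoff
demotes the ring class, reduces the donors and expands their
lowest-requirement siblings.  Conversion — not cell death — is the chosen
outcome because it is what produces the observed compensating increases.
Receptor direction calls propagate sensilla status to receptor genes
(expanded → up, reduced/lost → down); genes housed in several subtypes
(IR75d and the IR co-receptors) whose parents disagree are reported as
conflicts with no call.  Concordance against a bundled rn-mutant sign table
is computed, never asserted from provenance; entries supported only by
figure shading are marked low-confidence and excluded from the default
reference.  Predictions are qualitative throughout: the evidence granularity
is direction, not fold change.

## The antenna simulator

One neuron per ORN class per sensillum, so a class count equals its
sensilla count; per-subtype counts are Poisson (no overdispersion by
default, configurable).  Only two census numbers are anchored to printed
data: at4 = 60 sensilla (the wild-type Or47b count) and the rn-null ectopic
at4 complement +30 (the difference of the printed wild-type and mutant
means).  The remaining subtype counts are plausible defaults summing to
~425 sensilla and ~1100 neurons per antenna, near but not equal to the
printed whole-organ totals (~410 and ~1300) — exact joint attainment is not
possible with one-neuron-per-class counting over the bundled class roster
without implausible per-subtype values.  They are calibration inputs, not
claims.  Territorially expanded fates gain +50% of their wild-type census
by default (generalising the only quantified case, at4's 60 → 90); reduced
fates retain 50%; within-ring conversions move half of the donor census to
its recipients.  Clonal mosaics assign each sensillum to the clone
independently with probability f; when the clone's secondary genotype
removes a factor required by an expanded fate's ring code, clone-resident
ectopic sensilla revert while the endogenous census is spared (the
endogenous fate is robust to the loss).  The census and clone draws use
separate seeded substreams, so f = 0 reproduces the clone-free run bit for
bit.  The adult's anterior/medial ectopic zone has no geometry here; "ectopic"
is a census component, not a position.

## qPCR and count statistics

The printed amplification efficiencies cluster at ~1.0 and are read as
fractional efficiency per cycle: per-cycle fold = 1 + e (≈ 2, the standard
doubling), with the alternative fold = e selectable by flag.  Simulation
and quantification share the convention, so round trips are convention-
independent; at σ = 0 the round trip recovers abundance ratios to machine
precision.  Curve intercepts (cycles at unit quantity; default 30) are
instrument plumbing with no printed counterpart.  Normalisation divides
each replicate by its mean factor over the OR panel — reference genes
(ACT5C, GAPDH2) are carried but excluded from that mean — which fixes the
per-replicate panel mean at 1 and makes the output invariant to global
abundance scaling.  The two-sample test is the classic pooled-variance t
(Welch by flag), matching the study's statistics; one-way ANOVA is the
standard decomposition with a full pairwise post-hoc t table.  Degenerate
inputs (zero within-group variance) are flagged, not raised.

## The RNA-seq screen

Size factors are the median-of-ratios estimator (reference genes = nonzero
in all samples), cross-checked in the suite against an independent
reimplementation and against pyDESeq2.  The per-gene test is a pooled t on
log2(normalised count + 1); the screen's claim is the filter cascade, not
the test, which is pluggable.  The cascade order is fixed and each failure
carries its first failing reason: receptor exclusion, count floor, trend
concordance across the hom-vs-wt and hom-vs-het contrasts, then p < 0.1 in
both.  The count floor reads "low in all three genotypes" as: fail iff the
maximum of the three genotype mean normalised counts is below 20 (the
all-genotypes reading makes the max the faithful implementation; the
statistic is configurable).  A zero-sign contrast can never be concordant.
Stage-wise pass sets partition into the seven Venn regions exactly.

The generator draws negative-binomial counts (variance μ + αμ², default
α = 0.05) for the 3-genotype × 3-stage × 3-replicate design, with planted
effects in the homozygote only — heterozygote tracks wild type, which is
precisely the structure the concordance filter exploits.  Background base
means are log-normal (median ≈ 55); planted genes draw from a higher,
tighter log-normal (median ≈ 200), since the misregulated genes of interest
are expressed developmental regulators.

## What the synthetic data do and do not establish

The generators emulate the study's *designs* — Poisson antenna censuses,
Gaussian cycle noise through shared standard curves, NB counts with
hom-only effects — under known ground truth, so passing tests demonstrate
that the algorithms are correct and calibrated (type-I ≈ 5%, null screen
pass ≤ 10%, planted 4-fold recall ≥ 0.8), not that real antennae obey the
model.  Real data carry biology the generators omit: overdispersed counts,
sex differences, correlated sensilla losses, amplification-curve artifacts,
batch structure, and image-derived measurement error.  Quantities that
depend on the deposited animal data (receptor heatmaps, antibody intensity
levels, the real qPCR bars) are deliberately out of scope.

## Problem sizes and numerics

Validation uses a 1000-point grid (re-checked at 500), 200–400 antennae per
simulated genotype, 500-repeat type-I calibration, and screens of 1000–2000
genes — sizes at which every stochastic check sits several standard errors
from its threshold.  Floating-point extents are compared with small
absolute tolerances; all randomness flows through `numpy` Generators seeded
explicitly, with spawned substreams where two noise sources must not
interact.

## Known limitations

1-D geometry only: no dorsoventral structure, proliferation, or temporal
dynamics across larval stages.  Thresholds and ring widths are free
parameters chosen to reproduce the reference code sequence, not inferred
from images.  The Bab scale is ordinal with a single demotion step, so
allele strength maps onto one cutoff rather than a dose-response.  Leg
gustatory patterning, though governed by the same network, is not
implemented.
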