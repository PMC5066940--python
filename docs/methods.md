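# Methods

This note documents the models, conventions and numerical choices behind
`duplexlens`, and what its synthetic-data validation does and does not
establish about real data.

## Backbone substates

The two B-DNA backbone substates are separated by the phosphodiester
torsions of a dinucleotide step: ε = C4′ᵢ–C3′ᵢ–O3′ᵢ–Pᵢ₊₁ and
ζ = C3′ᵢ–O3′ᵢ–Pᵢ₊₁–O5′ᵢ₊₁. All backbone and glycosidic torsions are
reported in [0°, 360°); the difference ε − ζ is wrapped into (−180°, 180°]
before classification, which places canonical BI near −80° and canonical
BII near +90° on either side of a single threshold. A step is **BII** when
ε − ζ > 20° and **BI** otherwise; the boundary value of exactly +20° is
assigned to BI (the defining phrasing — "less than 20°" is BI, "over 20°"
is BII — leaves the point itself open, and BI is the majority state).
Step k spans nucleotides k → k+1, so the 3′-terminal nucleotide of a strand
has no step; classification there is an explicit null, not an error.
Torsion signs follow the IUPAC convention (clockwise positive looking from
the second to the third atom); the implementation was cross-checked against
the chemical-component dictionary's ideal deoxyguanosine geometry, whose
stereocentre chiralities and δ/ν torsions pin the sign unambiguously.

BII frequency of a step is the fraction of classifiable models (or frames)
whose call is BII.

## Sugar pucker

Pseudorotation uses the standard relations on the five endocyclic torsions
ν₀ = C4′–O4′–C1′–C2′ … ν₄ = C3′–C4′–O4′–C1′:

    tan P = ((ν₄ + ν₁) − (ν₃ + ν₀)) / (2 ν₂ (sin 36° + sin 72°)),
    τₘ = ν₂ / cos P,

with P placed in [0°, 360°) by the atan2 quadrant and τₘ kept non-negative
by shifting P half a turn when needed. ν₂ ≈ 0 together with a vanishing
numerator makes the phase indeterminate; the result is then flagged
ambiguous instead of raising. C2′-endo is P ∈ [144°, 180°), the B-form
norm.

## Base reference frames and twist

Each base's frame comes from least-squares (Kabsch) superposition of an
embedded standard base geometry onto the observed six-membered-ring atoms
N1/C2/N3/C4/C5/C6 — shared by purines and pyrimidines, so 8-oxoguanine is
fitted exactly like guanine and its O8 plays no role. The embedded tables
are expressed in the standard reference frame (x toward the major groove,
y toward the sugar of the sequence strand, z along the base normal); in
that frame an ideal Watson–Crick partner is the 180° rotation about x,
which is also how the synthetic builder places the complementary strand.

The pair frame averages the two base frames (partner flipped about its x)
by polar decomposition of the rotation sum — the geodesic midpoint — with
the mean origin. Twist between successive pair frames is measured about
their mid-frame z-axis (projection of the two y-axes onto the plane normal
to it, signed by the axis), and rise is the origin displacement along that
axis. This is the mid-step-triad convention; no global helix axis is
fitted, because the target statements (a local twist dip at the lesion)
are robust to the convention, which is recorded in output metadata.

## Hydrogen bonds

Geometric detection over embedded donor/acceptor tables for the five base
types (8-oxoguanine adds the N7–H donor and O8 acceptor while keeping
guanine's Watson–Crick edge). Defaults: heavy-atom D···A ≤ 3.5 Å and, when
the donor hydrogen is present, D–H···A ≥ 120°; both are arguments. With
hydrogens absent the angle criterion is skipped and flagged per bond.
Occupancy is the per-bond presence fraction over models, optionally
restricted to a site such as the GAATTC hexamer. Note that at a 3.5 Å
cutoff genuine non-Watson-Crick contacts (minor-groove N2→O2 of a
neighbouring pair, for instance) are legitimately reported; analyses that
mean "the Watson–Crick bonds" should filter by the canonical atom pairs.

## NOE restraint compilation

Volumes calibrate to distances by the isolated-spin-pair law
r = r_ref (V_ref/V)^{1/6}, independently within each mixing-time set; the
reference is the fixed covalent cytosine H5–H6 distance, default
r_ref = 2.45 Å (config-overridable — the synthetic closure tests pass the
generator structure's own H5–H6 distance so the inverse is exact). A pair
observed in every mixing-time set contributes its arithmetic-mean distance
("averaged"); otherwise the highest-volume observation — the operational
reading of "most reliable cross-peak" — supplies it ("non-averaged").
Distances group as short < 3.0 Å, medium 3.0–5.0 Å, long > 5.0 Å, with
default no-penalty tolerances (±0.4, ±0.7, ±1.0 Å respectively; package
defaults, deliberately declared config rather than literature values).
A restraint involving a methyl proton is classed "methyl" regardless of
length and its upper bound gains a +1.0 Å pseudoatom correction. In the
ledger, methyl restraints are counted as their own class, apart from the
averaged/non-averaged split, so averaged + non-averaged + methyl = total.

Restraints on a self-complementary duplex are duplicated through the
palindromic dyad, which swaps the strands while preserving the 5′→3′
position (residue i of one strand maps to residue i of the other); the
lesion X is guanine-like for this symmetry. Self-symmetric restraints are
emitted once and flagged.

Watson–Crick heavy-atom restraints (target 2.9 ± 0.2 Å; three per G:C or
8OG:C pair, two per A:T) are emitted for non-terminal pairs only, since
terminal-pair imino signatures fray. Backbone dihedral restraints hold all
canonical residues in BI ranges; the lesion's linkage gets ε ∈ [215°, 295°]
and ζ ∈ [155°, 205°] (the BII ranges), and the two dihedrals on either side
of that pair — δ and γ of the lesion, α and β of the next residue — keep
their parent ranges broadened by ±20°. The BI parent ranges are package
defaults centred on canonical values (α 270–330°, γ 18–78°, δ 110–170°,
ε 155–245°, ζ 235–325°); β is given a deliberately broad 106–246° because
it occupies a wide trans basin and tightens strongly only through the
crankshaft coupling at BII steps.

Violations: per model, a distance restraint scores max(0, d − upper,
lower − d); a dihedral restraint scores the angular distance outside its
arc. Maxima and the offending restraints are reported per model;
unresolvable atoms exclude the restraint with a warning rather than
aborting the scan.

## Ensembles

Superposition solves the orthogonal Procrustes problem via SVD with the
proper-rotation correction. Selections: all-atom, all-heavy (no
hydrogens), backbone ({P, OP1, OP2, O5′, C5′, C4′, C3′, O3′}) or custom.
"Backbone RMSD" between two structures has no universal atom-set
convention, so cross-structure comparisons carry that caveat. The
mean-coordinate representative superposes all models onto the first and
averages — no force-field minimization is applied, unlike the common
practice of minimizing an averaged NMR model, so comparisons against
deposited "averaged minimized" coordinates should use the deposited frames
directly. The medoid alternative picks the member minimizing summed RMSD
to the rest.

## The synthetic generator

Two builders, because exact helical placement and exact backbone torsions
cannot be guaranteed simultaneously; every validation uses the builder
that owns its ground truth.

**build_helix** stacks ideal base pairs along a straight axis with exactly
the requested per-step twist (default 36°) and rise (default 3.38 Å, the
B-form fiber values), the strand-B partner placed by the 180°-about-x flip.
Nucleosides are the package's standard template: base tables plus a
C2′-endo deoxyribose (P = 162°, τₘ = 38°) solved once by least-squares ring
closure, hydrogens from ideal sp²/sp³ geometry, glycosidic χ = 243° (anti).
Phosphates are bridged afterwards: P lies on the circle where the two
bond-length spheres (O3′–P 1.607 Å, P–O5′ 1.593 Å) intersect, and the
circle angle minimizes bond-angle error plus soft ε/ζ targets, keeping the
backbone in the BI region (emergent ε − ζ ≈ −42°).

**build_torsion_exact** grows strand A 5′→3′ by internal-coordinate (NeRF)
chaining, so requested ε/ζ are realized to machine precision at the
requested linkages. The uniform-chain parameters (α, β, γ, χ, δ) are
calibrated once, by least squares over a two-residue probe, so that the
default linkage realizes twist ≈ 36°, rise ≈ 3.38 Å and a bridgeable
complementary-strand backbone. A BII-injected linkage is compensated by
α/β of the following residue only — the optimization lands on β ≈ 100°,
the crankshaft that accompanies a BI→BII transition in this idealized
geometry — which leaves every downstream step exactly default. The
complementary strand is placed from the strand-A base frames and bridged
like build_helix; its linkage across from an injected lesion emerges BII,
an unforced echo of what simulations report for the cytosine opposite the
lesion, but it is not a controlled ground truth and is never asserted.

8-oxoguanine derives from the guanine template by placing O8 on C8 along
the former C8–H8 direction at 1.23 Å and protonating N7; the Watson–Crick
edge is untouched, so the lesion pairs and fits frames exactly like
guanine.

**make_ensemble** adds iid per-coordinate Gaussian jitter (scale σ per
model, deterministic under the seed). The expected pairwise RMSD is then
σ√6 — the per-atom squared distance sums three coordinates of variance
2σ² — a useful closed form for sanity checks. Uncorrelated jitter is a
deliberate simplification: it does not mimic the collective covariance of
physical ensembles, so tests on jittered ensembles validate bookkeeping
and thresholds, not conformational realism.

**synth_peaklist** emits one peak per proton pair within the 5 Å NOE
horizon per mixing time (defaults 70/140/200 ms), with volume
c_t · r⁻⁶ · exp(noise · g), g ∼ N(0,1) — multiplicative log-normal noise on
an ideal isolated-spin-pair transform. Cytosine H5–H6 reference pairs are
always included. Spin diffusion, relaxation-rate buildup differences and
peak overlap are not modelled; a 10 % volume noise maps through the 1/6th
power to ≈ 1.6 % distance error, comfortably inside the no-penalty
tolerances, which is why the noisy round trip scores zero violation.

## Kinetics

Specificity is the exact quotient V_max/K_M (min⁻¹ with V_max in nM·min⁻¹
and K_M in nM); relative efficiency is the ratio of specificities against
an undamaged reference. Records allow a directly supplied specificity for
substrates that never reach saturation (read from the linear slope of v₀
vs [S]). Published constants are treated as printed inputs; the
Michaelis–Menten refit exists only to validate parameter recovery on
synthetic rate data (8 substrate points, 5 % multiplicative noise recovers
V_max and K_M to ≈ 5 % median error).

## Problem sizes and determinism

The validation suite runs on 12-mer duplexes (the natural size for this
system), ensembles of 10–20 models, ~650 unique proton pairs per peak
list, and 20-seed stochastic repeats; everything derives from explicit
seeds, and identical configs give byte-identical pipeline outputs.

## Known limitations

- The builders produce idealized geometry: uniform sugars, planar bases,
  a straight helical axis; sequence-dependent fine structure (propeller,
  roll, slide) is absent, and only twist/rise of the 6 step parameters are
  computed.
- Jittered ensembles have no physical covariance (above).
- Deposited-ensemble statistics require local copies of the public
  coordinate files (see `data/deposited/README.md`); they are analysed
  with the same machinery but cannot be validated in an offline checkout.
- The mean-coordinate representative is not energy-minimized, so bond
  geometry of the average can be slightly non-physical, as with any
  coordinate-averaged NMR model.
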