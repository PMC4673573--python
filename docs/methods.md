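# Methods

## Chain model and conventions

A linear β-glucan chain of DP *n* is represented by its linkage vector
(ℓ₁…ℓₙ₋₁), ℓᵢ ∈ {1→3, 1→4}, indexed from the nonreducing terminus
(residue 1) to the reducing terminus (residue *n*); bond *b* joins
residues *b* and *b*+1. This left-to-right orientation matches the
field's shorthand (`G3G4G3G4G` reads β-Glc-1,3-β-Glc-1,4-β-Glc-1,3-
β-Glc-1,4-Glc) and is inherited by every other module: enzyme subsites
−2/−1/+1/+2 straddle the scissile bond with the negative subsites on the
nonreducing side, A/B/C/D/E/G fragment indices count residues from the
nonreducing end, V/X/Y/Z from the reducing end. Only β-anomeric 1→3 and
1→4 linkages are representable; branched glycans and 1→6 bonds (laminarin
side chains) are deliberately outside the type system, so laminarin-like
substrates are modeled as their linear 1,3 backbones.

Masses derive from one atomic-mass table and elemental compositions
(`mlgkit.constants`). Native chain mass is n·C₆H₁₀O₅ + H₂O; reduction
adds H₂; permethylation adds one CH₂ per free hydroxyl, with the
free-hydroxyl count of a linear chain equal to 3n+2 (4 at the
nonreducing terminus, 3 per internal residue, 4 at the reducing
terminus; +1 after ring-opening reduction). Both monoisotopic and
average conventions are carried throughout because published fragment
tables mix nominal, monoisotopic and average spacings; the sodium adduct
constant is fixed at 22.9898 (monoisotopic) / 22.99 (average).

## Subsite-rule digestion

An `EnzymeRuleSet` declares: the scissile linkage types; the required
−2/−1 linkage (the bond preceding the scissile bond), with an occupancy
flag for the −2 subsite; the required +1/+2 linkage, with a flag
allowing the +2 subsite to be empty; and a minimum substrate DP.
Constraints that reference an empty subsite fail unless emptiness is
explicitly allowed (+2 only); −2 emptiness never licenses cleavage in
the shipped rule sets. Limit digestion is simultaneous mark-and-cleave:
each round cleaves every currently cleavable bond in every current
product, until a fixed point. This is deterministic, conserves residues,
and is idempotent on its own products. A sequential mode (one random
cleavable bond per step, explicit seed) exists for route exploration; it
is genuinely route-dependent — on `G3G4G3G4G` the GH16 rule set reaches
either {2×G3G, G} (reducing-side bond first) or the stranded state
{G3G, G3G4G} (interior bond first, after which the DP-3 fragment is
below the minimum substrate size) — which is precisely why the
deterministic simultaneous mode is the default for limit-digest
specificity. A `max_rounds` knob supports qualitative partial-digestion
curves; no kinetics are modeled.

The shipped rule sets are reverse-engineered from limit-digest product
identities, not from sequence or structure databases:

* **GH12_aniger** (endo-β-1,4-glucanase): cleaves 1,4 with −2/−1 = 1,4
  and +1/+2 = 1,3, +2 must be occupied, min DP 4. Consequences: canonical
  MLG is cut once per unit, releasing G3G4G / G3G4G4G; the products
  themselves resist re-digestion; a cellobiosyl–cellotriosyl motif
  yields the resistant pentasaccharide G3G4G3G4G.
* **GH16_trichoderma** (endo-β-1,3(4)-glucanase): cleaves 1,3 or 1,4
  with −2/−1 = 1,3; +1/+2 = 1,3 or +2 empty; min DP 4 (smallest
  substrate G3G4G3G). Consequences: G3G4G3G4G → 2×laminaribiose +
  glucose; G3G4G4G and G3G4G resist; all-1,3 chains are degraded;
  all-1,4 chains are untouched; on canonical MLG the only cleavable
  bonds are inside cellobiosyl units. Whether the natural enzyme also
  cleaves 1,3 bonds in MLG context is not decidable from limit products
  alone (both bonds it cleaves in G3G4G3G4G are 1,4); the rule set
  permits both, which is the weaker assumption.
* **GH17_barley** (endo-β-1,3-glucanase): cleaves 1,3 with −2/−1 = 1,3,
  min DP 3 (laminaritriose motif). Inert on MLG lacking consecutive
  1,3 bonds.
* **GH_lichenase** (EC 3.2.1.73): cleaves 1,4 with −2/−1 = 1,3, min DP 4;
  classical G4G3G / G4G4G3G products.

## Methylation analysis

For a reducing-end-reduced, permethylated chain, residue 1 reports as
t-Glc, internal residue *i* as 3-Glc or 4-Glc according to the linkage it
accepts, and the terminal alditol as 3-Glcol or 4-Glcol. Profiles are
blind to linkage order, so candidate enumeration (exhaustive over the
2^(DP−1) vectors, bounded at DP 12) generally returns several sequences
per profile — three for the (1, 2, 1, 0, 1) profile at DP 5. Observed
molar ratios deviate from integers through recovery and derivatization
bias; ranking therefore uses the sum of squared deviations from the
t-Glc-normalized integer profile and reports equal scores as explicit
ties. No bias-correction model is attempted (the depressed alditol
recovery seen in practice is left unexplained by design).

## CID fragment chemistry

All fragment m/z values are computed from composition tables written as
multiples of the permethylated anhydroglucose residue R = C₉H₁₆O₅
(204.0998 monoisotopic / 204.222 average) plus a fixed per-series
correction: B = +CH₂, C and Y = +CH₄O, Z = +CH₂, D = +0, E and G = −CH₄,
V = −CH₂O, ³,⁵A = (i−1)R + C₅H₁₀O₂, ⁰,²X = +C₄H₈O₂, all sodiated.
Published pentasaccharide values serve as validation only; the tables
reproduce all eleven within 0.25 Da (monoisotopic) and the suite checks
them at ±1.0 Da, the slack needed because published series are printed
with mixed nominal/average spacing. An exploratory "anchored" mode
(per-series constant offset estimated from anchors) exists for
leave-one-out exercises and plays no role in normal prediction.

Feasibility encodes the linkage diagnostics. ³,⁵A cleavage of ring *i*
retains the C4–C5–C6 fragment, hence the glycosidic oxygen of a 1,4 bond
into that ring: the ion exists only when bond *i*−1 is 1,4. Internal Dᵢ
ions form from Cᵢ-type fragments by elimination of the residue-*i*
3-O-methyl as methanol, which exists only when bond *i*−1 is 1,4 (a 1,3
bond puts the rest of the chain at O3 instead). D₁ always exists — the
terminal residue always carries a 3-O-methyl — and its intensity
relative to the isobaric E₁/G₁ pair (16.03 below D₁) flips with the
terminal linkage: D₁ dominant for 1,3, E₁/G₁ dominant for 1,4. That
flip, and the position-dependent behavior of the V series (strong for a
1,4 bond; for 1,3 weak at internal positions but absent at the
nonreducing-terminal bond), are encoded as category data generalized
from the pentasaccharide panels: Vᵢ diagnoses bond DP−i, an
extrapolation beyond DP 5 that the exhaustive DP 4–6 recovery test
exercises. ⁰,²X and the glycosidic B/C/Y/Z series are always possible
and carry no linkage information in this model; their intensities are
not modeled beyond presence.

## Inference

For a spectrum of known DP, every candidate linkage vector predicts a
strong/weak/absent pattern over the diagnostic ions (³,⁵A₂…³,⁵A_DP,
V₂…V_{DP−1}, D₂…D_{DP−1}); the spectrum is classified once per ion
(absent < 1 %, weak 1–10 %, strong ≥ 30 % of base peak, in-between
values weak-with-borderline-flag) and candidates score weighted
agreement: presence/absence diagnostics weight 2 (half credit for
strong↔weak confusion), the D₁/E₁ ratio test weight 1 (ratio > 2 ⇒ 1,3;
< 0.5 ⇒ 1,4; else inconclusive), and, when homopolymer reference spectra
are supplied, one extra point per ion whose observed category matches
exactly one of the two references. All thresholds and weights are
package conventions quantifying the qualitative strong/weak/absent
vocabulary; they are centralized in `ClassifierThresholds` and module
constants. Because every diagnostic bears on a single bond, the score
factorizes per bond; exact ties are returned as explicit ambiguity with
the co-optimal set, never broken arbitrarily. An optional PMAA profile
constrains the candidate set so the call can never contradict the
methylation analysis. The per-bond confidence is the weight fraction of
informative diagnostics concordant with the call.

## Synthetic data: what it emulates and what it does not

The chain generator draws units — cellobiosyl (probability q, default
0.01), otherwise cellotriosyl : cellotetraosyl at 0.697 : 0.303 —
concatenated with single 1,3 bonds, all intra-unit bonds 1,4. With
forcing on (default) a cellobiosyl draw emits the
cellobiosyl–cellotriosyl pair, honoring the placement of the motif on
the nonreducing side of a cellotriosyl unit; realized unit counts
therefore slightly exceed draw counts, and the resulting cellobiosyl
unit frequency q/(1+q) ≈ 1 % stays below the 2 % upper bound reported
for barley. The triosyl:tetraosyl ratio is a literature-typical value
for barley (the exact ratio is preparation-dependent); q = 0.01 makes
the closed-form DP-5 mass fraction after GH12-style limit digestion
100·5q/(5q + (1−q)·3.303) = 1.51 %, the minor-fraction yield the
workflow is built around. Chains default to 4000 unit draws (DP ≈
13,000, Mr ≈ 2 MDa, a high-viscosity barley β-glucan): long chains keep
the chain-end artifact small — a chain ending in a cellotetraosyl unit
leaves an uncleaved G3G4G4G4G (DP 5) terminal fragment, a ~30/(units
per chain) relative inflation of the DP-5 yield, under 1 % at the
default length. The end-to-end closure property ("the only DP-5 limit
product is G3G4G3G4G") is accordingly asserted over chain-interior
fragments. Optional long 1,4-stretches and a free (non-forced)
cellobiosyl mode exist for exploring other unit grammars and are
documented as extrapolations. The generator does not model chain-length
polydispersity beyond the configured unit-count distribution, block
correlations between units, or continuous 1,3 runs.

The spectrum simulator draws strong-feasible ion intensities uniformly
from [0.5, 1.0] and weak-feasible from [0.02, 0.08] of base peak, omits
infeasible ions, jitters m/z by N(0, 0.1² Da), and adds 10 uniform noise
peaks below 0.05 intensity; exact isobars (E₁/G₁) collapse to the
stronger draw. It reproduces the qualitative presence/intensity pattern
that drives the comparative logic and nothing else: no isotope
envelopes, no detector response, no precursor survival peak, no
chemical noise structure. Passing recovery tests therefore show the
inference logic is sound against this noise model, not that it is robust
to every instrumental artifact of real spectra. Reference fixtures
(cellopentaose, laminaripentaose) are simulated with pinned seeds
(41, 17), shipped as TSVs marked `synthetic`, and regenerate
byte-identically.

## Numerical and problem-size choices

* Fragment matching tolerance 0.5 Da by default, 1.0 Da when comparing
  across mass conventions; m/z jitter (σ = 0.1 Da) sits far inside the
  matching window.
* Annotation is greedy on absolute mass error with a deterministic
  tie-break toward the lower-m/z ion; each peak and each ion is used at
  most once.
* Degenerate inputs are errors, not guesses: DP 1 has no PMAA class;
  fragment enumeration covers DP 2–10 and inference DP 3–8 (the tested
  regime); an empty peak list annotates to nothing but cannot support
  inference; an empty substrate population cannot be digested.
* The DP-5 yield computation uses 250 chains × 4000 draws = 10⁶ units,
  at which sampling noise (~1 % relative, ~10⁴ cellobiosyl events) and
  the chain-end artifact (<1 % relative) are both comfortably inside a
  two-significant-figure readout; the whole computation takes ~2 s.
* All randomness flows through seeded `numpy` generators; every output
  file records its seed, and pipeline outputs contain no timestamps so
  identical configs produce identical bytes.

## Known limitations

* Subsite rules capture limit-digest specificity only; relative
  activities, kinetics, and processivity are out of scope, so
  polysaccharide-level activity comparisons are qualitative
  (activity vs no activity, average-DP decrease vs none).
* The D/E/G/V feasibility categories are generalized from
  pentasaccharide evidence; outside DP 5 they are model extrapolations,
  validated only against the simulator's own ground truth.
* PMAA ratio bias is not modeled; ranking is shape-based least squares.
* Only singly sodiated, permethylated, unbranched species are treated in
  the mass-spectrometric modules.
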