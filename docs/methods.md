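# Methods

This note documents the models, conventions and numerical choices behind
`silnas`, in the order data flows through the package.

## Coordinates, molecules and modifications

Positions are 1-based and inclusive everywhere ("70A" is the 70th
residue); conversion to 0-based indices happens only inside slicing
expressions. An `RnaMolecule` carries explicit end chemistry: 5′-hydroxyl,
5′-monophosphate, 5′-triphosphate or TMG cap; 3′-hydroxyl, 3′-linear
phosphate or 2′,3′-cyclic phosphate. DNA input is accepted with T mapped
to U, since sequences are commonly distributed as DNA.

Modification types are a closed registry:

| type | Δ composition | blocks 3′ cleavage | mass-silent | default RT shift |
|---|---|---|---|---|
| 2′-O-methyl | +CH₂ | yes | no | +0.5 min (later) |
| pseudouridine | none | no | yes | −0.7 min (earlier) |
| base-methyl / N6-methyl | +CH₂ | no | no | +0.3 min |

2′-O-methylation removes the 2′-OH required by the transesterification
mechanism of RNase T1 and RNase A, so cleavage immediately 3′ of the
residue is suppressed; base methylations do not block. Pseudouridine has a
free 2′-OH and is cleaved after normally. The RT shifts are reversed-phase
conventions used by the simulator and, with their sign only, by the
assignment of same-m/z species; in a real analysis they would be
calibrated with standards.

Label schemes describe the heavy internal standard transcribed in vitro
from ¹³C-labeled NTPs: the T1 scheme substitutes all 10 carbons of every
guanosine, the A scheme all 9 carbons of every cytidine and uridine.
Labels live on the nucleoside carbons, so a modification methyl stays
¹²C and the heavy−light mass difference is exactly
(label count) × 1.0033548 Da, independent of modifications.

## Digestion

RNase T1 cuts after G, RNase A after pyrimidines; products carry 5′-OH and
a 3′-phosphate. The default 3′ product chemistry is the linear
monophosphate — reported species are written with a terminal "p" and
prolonged incubation opens the cyclic intermediate — with the 2′,3′-cyclic
form (one water less) selectable per rule. Terminal fragments keep the
molecule's own end group on the uncut side. Missed cleavages count
*retained internal cuts*; a methyl-blocked position is not cleavable at
all and therefore never counts as missed. RNase H splitting is
guide-directed: `rnase_h_split(molecule, cut_before)` returns the upstream
piece with a new 3′-OH and the downstream piece with a 5′-monophosphate
(the "p" prefix of species like pUUGp), with modification sites
re-indexed and the coordinate offset preserved.

Correctness is checked against an independent brute-force enumerator (a
regex scan for cut points followed by enumeration of all boundary pairs)
on thousands of random sequences, including blocking methyls.

## Mass and ion computation

A chain of n nucleosides has n−1 phosphodiester linkages, each adding
HPO₃ and removing H₂O relative to the free nucleosides; end groups and
per-site modification deltas are added on top. All atomic masses come
from one packaged table, because ±5 ppm matching requires every module to
use identical constants. Negative-mode ions use
m/z = (M − z·1.00727646)/z, filtered to the survey-scan window
(m/z 480–1980 by default); the smallest observable charge is used as the
quantification channel. Isotopologue envelopes are not modeled — the
quantification reads monoisotopic species only.

The TMG cap (2,2,7-trimethylguanosine joined 5′-5′ through a
triphosphate bridge) is a package default composition
(trimethylguanosine + 3 HPO₃ − H₂O relative to 5′-OH) and can be
overridden per run, since cap mass chemistry is a property of the sample.

MS2 ladders implement the dominant CID series of RNA with the
conventions: c = 5′ fragment with the full 3′-phosphate, y = 3′ fragment
with 5′-OH, w = 3′ fragment with 5′-phosphate, a−B = c − HPO₃ − H₂O −
nucleobase (the base leaves with its methyl if base-methylated; a ribose
2′-O-methyl stays with the fragment). These satisfy the closure
mass(c_i) + mass(y_{n−i}) = M + H₂O at every backbone position, which the
tests assert to 10⁻⁶ Da.

## Identification

The search space enumerates fragments per molecule × enzyme up to the
missed-cleavage cap (default 1), in the variants a search engine
considers: unmodified, every single variable 2′-O-methyl placement (at
most one variable methyl per fragment), and the fixed known-site variant
— known sites are exempt from the variable cap so multiply-methylated
species (GmGmC) remain reachable. MS1 matching is ±5 ppm; all co-matching
species are kept, and species with identical base composition collide
exactly (the CACUCCG/ACCCCUG permutation pair) and form one ambiguity
group. MS2 scoring counts matched ladder ions within ±20 ppm with the
explained-intensity fraction as tie-break. Resolution policy: highest MS2
score, then smallest |ppm| error, otherwise the group is reported
ambiguous — never silently dropped. Pseudouridine variants and
positional methyl isomers with identical ladders cannot be resolved by
MS2; for those the pipeline uses elution order (the unmodified species
co-elutes with its heavy standard; Ψ elutes earlier, methyls nearer the
3′ end later).

## Quantification

Two estimators, deliberately independent:

- **Isotope dilution (silnas)**: `f = 1 − L/(k·H)` where L and H are apex
  intensities of the light-unmodified fragment and its co-eluting heavy
  counterpart. The correction factor k (the realized light:heavy mixing)
  is the arithmetic mean of per-pair ratios over unmodified fragment
  pairs — ten by default, warning below ten, error below five; a median
  policy is available for outliers. Being a depletion readout, it also
  covers mass-silent pseudouridine. When the modified species is
  measured too, `(L_unmod + L_mod)/(k·H)` is attached as a consistency
  diagnostic (≈1 when mixing, correction and responses cohere; apex
  sampling on a discrete scan grid can depress it by up to ~2%, which
  cancels in the co-eluting ratio but not in the diagnostic).
- **Peak area**: `f = ΣA_mod/(ΣA_mod + ΣA_unmod)` over trapezoid-integrated
  XIC areas at ±5 ppm. Isomeric modified species are summed (the
  "GmGmC + GmGC" composite-row convention); mass-silent modifications are
  quantified from RT-resolved same-m/z peaks. Peak boundaries are
  automated — the contiguous region around the apex above
  max(apex × 0.01, noise floor) — replacing the manual start/end
  selection of interactive software; explicit boundaries remain available.

Raw estimates outside [0, 1] are clamped and flagged, never silently
altered. Both estimators are ratios, invariant to rescaling a replicate.
Replicates aggregate to mean ± SEM (sd/√n); conditions are compared by
Welch's t-test (two conditions) or Tukey's HSD versus the reference
(more), at α = 0.05.

## The synthetic-data generator

No raw instrument data accompanies this kind of analysis, so the
generator defines the study conditions. The default scenario uses
**synthetic** U1-like (164 nt) and U2-like (188 nt) sequences — the real
snRNA sequences are not among the package inputs — engineered so every
benchmark fragment occurs at its reference coordinate (CACUCCG at 69–75
with its composition-isobar ACCCCUG at 85–91; UUGG at 17–20; AAGAU at
23–27; GGC at 11–13; UAG at 34–36; the RNase H cut before residue 17).
Filler regions are concatenations of blocks with pairwise-distinct base
multisets, so filler fragments have unique m/z in both digests and
provide ≥10 clean mixing-correction pairs per run.

Ground-truth stoichiometries follow the reference control values, with
the two knockdown conditions at the reference siRNA values for the six
TDP-43-dependent sites (70Am, 19Gm, 25Gm, 40Cm, 47Um, 61Cm) and exactly
the control value at the invariant sites (caps, 11Gm, 12Gm, 30Am, 34Ψ).

Error model (standard LC-MS structure; the defaults are the benchmark
conditions):

- intensity: lognormal, 5% CV per species per replicate, on top of a
  lognormal per-fragment-region response factor (σ = 0.4) shared across a
  blocking-merge family so boundary-changing species stay comparable;
- mass: Gaussian, 2 ppm per scan — feature-level m/z
  (intensity-weighted) averages well below the ±5 ppm tolerance;
- RT: Gaussian jitter (0.02 min) on Gaussian elution profiles
  (σ = 0.05 min, 0.02 min scan spacing); methylated species elute +0.5
  min per methyl plus +0.4 min per position toward 3′ (separating
  positional isomers), Ψ −0.7 min; heavy species co-elute with light;
- mixing: nominal 1.0 by default (0.9 in the recovery benchmark), read
  back through the correction pairs;
- biology: replicate effects on the true fraction, sd 0.01, drawn
  sum-to-zero within each condition and rescaled, so realized condition
  means equal the prescribed truths exactly and the expected significance
  pattern is structural rather than a per-seed accident; the effect sd
  shrinks near the [0, 1] boundaries (min(sd, f/3, (1−f)/3)) so no
  clipping occurs and boundary sites still carry within-condition
  variance. This scale makes fixture SEMs comparable to reported
  replicate scatter.

Everything is deterministic given the scenario seed (default 17), via a
spawned seed tree; the ledger records every species' amplitude, RT and
weight plus the realized per-replicate truths, sufficient to recompute
every expected estimate exactly.

What passing tests show — and don't: the generator reproduces the
*statistical structure* the analysis assumes (paired light/heavy species,
partial-modification splitting, RT-separable silent species, ppm-scale
mass error). It does not reproduce isotope envelopes, co-elution
interference beyond the engineered isobars, ion suppression, or missing
data, so estimator accuracy here bounds real-data accuracy from above.

## Benchmark problem sizes

The recovery benchmark uses one 60-nt molecule with five methyl sites at
truths {0.05, 0.25, 0.50, 0.75, 0.95}, 3 replicates, mixing 0.9; its mean
absolute error is computed on per-site means over replicates. Under these
conditions the isotope-dilution estimator's expected MAE is ≈1.6
percentage points (per-replicate error (1−f)·√2·CV), so the 2-point bound
holds in expectation but individual seeds vary around it; the peak-area
estimator, which cancels the shared response factor, sits near 0.5
points. The digestion oracle runs 1000 random sequences (≤60 nt) × both
enzymes × 0–2 missed cleavages × with/without a blocking methyl. The
end-to-end benchmark is the default scenario: 2 molecules, 12 site
groups, 4 digests, 3 conditions × 3 replicates (~36 peak lists, ~1300
scans each).

## Known limitations

- Digestion is all-or-none per missed-cleavage variant; no kinetic
  partial-digestion model.
- Monoisotopic-only matching; no isotope-envelope fitting, no FDR/decoy
  machinery (inputs are candidate molecules, not a genome-scale search).
- MS2 chemistry is fixed to c/y/w/a−B without neutral losses.
- The elution-order convention for same-m/z species is an assumption of
  the simulator and pipeline, not a measured property; real analyses
  should anchor it with standards or discriminating MS2.
- The TMG cap composition is a configurable default, not a measured
  value; cap-carrying fragments are excluded from the independent
  residue-mass cross-check for that reason.
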