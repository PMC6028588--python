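# Methods

`csramod` implements a statistical-thermodynamic model of how the bacterial
global regulator CsrA binds mRNA 5' regions and changes their translation
initiation.  This note documents the model, its assumptions, the defaults,
and what the synthetic test data does and does not emulate.

## Binding-site energetics

A CsrA homodimer recognizes 5-nt ANGGA-like elements.  Candidate sites are
scored with a position-specific mono-nucleotide free-energy matrix (RT
units) whose only non-zero entries reward the consensus AAGGA:

| position | A     | C | G     | U |
|----------|-------|---|-------|---|
| 1        | -2.63 | 0 | 0     | 0 |
| 2        | -2.20 | 0 | 0     | 0 |
| 3        | 0     | 0 | -3.14 | 0 |
| 4        | 0     | 0 | -3.14 | 0 |
| 5        | -1.65 | 0 | 0     | 0 |

The site energy is the sum of the five lookups (consensus: -12.76 RT) and
every window with a strictly negative score is a candidate site.  The model
is additive by construction; non-additive (epistatic) sequence effects are
out of scope.  Sites matching ANGGN are labeled high-affinity.

## Cooperativity

A single homodimer bridging two sites at start-to-start distance `d` nt
contributes

    dG_coop(d) = 0.001 (d-5)^2 + 0.05 (d-5) - 5.0  RT    for 10 <= d <= 55
    dG_coop(d) = +20 RT                                   for d < 10 (steric clash)
    dG_coop(d) = 0                                        for d > 55

so the interaction is strongest at d = 10 (-4.725 RT) and decays to zero at
d = 55.  Distance is measured 5'-start to 5'-start, which makes `d - 5` the
nucleotide gap between the 5-nt footprints: d = 5 means immediately
adjacent windows, and the steric penalty covers gaps below 5 nt.  The
anchor convention is a package choice; measuring between other anchor
points would shift the window by a constant.

## Structural unfolding

Both bound sites must be single-stranded.  The cost is

    ddG_unfold = dG(MFE | sites forced unpaired) - dG(MFE),

computed with ViennaRNA (Turner 1999 parameters, 37 degC, dangling-end
energies disabled, lonely pairs allowed; the engine version and settings
are echoed into every output).  Forced-unpaired positions may still sit
inside loops of other helices.  The quantity is non-negative and exactly
zero when both sites are already unpaired in the MFE structure.  Absolute
folding energies depend on the engine version; comparisons across engine
versions are only qualitative.

## Ensemble

Every unordered pair of distinct, non-overlapping sites (start-to-start
distance >= 5 nt) is one two-site CsrA-bound conformation with

    dG_total = dG_site1 + dG_site2 + dG_coop + ddG_unfold.

Pairs at any distance are retained: beyond the cooperative window the
cooperativity term is simply 0, and sterically clashing pairs carry +20 RT
(they stay in the ensemble but essentially never reach the top ranks).
Overlapping windows are excluded outright, since one homodimer cannot
occupy two overlapping footprints.  Boltzmann probabilities use
p(a) = exp(-beta dG_a) / sum_i exp(-beta dG_i) with beta = 1 (energies in
RT), evaluated with a log-sum-exp guard.  The top K = 15 conformations by
ascending dG_total (ties broken lexicographically on coordinates, for
reproducibility) are selected and their probabilities renormalized.  The
per-record summary reports both the unweighted and the probability-weighted
mean of the top-K energies; the unweighted mean is the headline value.

## Translation model

The ribosome-binding model is a deliberately simplified thermodynamic
RBS-calculator variant.  For the free mRNA

    dG_total,free = (dG_mRNA:rRNA + dG_start + dG_spacing + dG_standby) - dG_initial

* `dG_mRNA:rRNA`: best duplex between the 25 nt upstream of the start codon
  and the anti-Shine-Dalgarno tail ACCUCCUUA (ViennaRNA duplexfold),
  clamped at <= 0.
* `dG_start`: AUG -1.94 RT, GUG -0.12 RT, UUG -0.07 RT, otherwise 0.
* `dG_spacing`: quadratic penalty around the optimal 5-nt aligned spacing
  (0.078 RT/nt^2 stretched, 0.41 RT/nt^2 compressed, capped at 12 RT),
  never negative.
* `dG_standby`: MFE energy with the ribosome footprint — 15 nt upstream of
  the start codon through the start codon plus 13 nt of CDS — forced
  single-stranded (the mRNA structure that can coexist with a bound
  ribosome).
* `dG_initial`: unconstrained MFE energy.

For a CsrA-bound conformation the initial state is the conformation's
constrained fold (both CsrA footprints single-stranded).  In the final
state the ribosome footprint and any surviving CsrA site are forced
unpaired; a CsrA site overlapping the footprint is evicted, and the
eviction cost — the lost site energy plus the lost cooperativity when the
pair is broken — is charged once to `dG_mRNA:CsrA:rRNA`.  This bookkeeping
keeps binding bonuses out of double counting and yields the three expected
regimes: a far-upstream pair leaves the rate ratio near 1, footprint
occlusion raises it, and melting an inhibitory structure lowers it.

Rates follow r ~ exp(-beta_r dG_total) with beta_r = 0.45 /(kcal/mol) =
0.277 /RT at 37 degC.  Each conformation's ratio R_i = r_free / r_CsrA,i is
labeled repressed (R > 1.2), activated (R < 0.8), or not impacted.  The
ensemble verdict is the label whose summed top-K probability is at least
1.8-fold larger than each alternative (boundary inclusive); otherwise the
record is heterogeneous.  Because the simplified calculator's absolute
energies are parameterization-dependent, only the qualitative labels are
meaningful across implementations; the thresholds themselves (1.2 / 0.8 /
1.8) are the model's calibrated constants.

## Pockets and contingency statistics

The unique sites of the top-15 conformations (deduplicated by start and
sequence, with occurrence counts) are chained into pockets whenever
consecutive windows overlap, abut, or have at most one nucleotide between
them.  Pockets with 7-10 non-ANGGN members are flagged as candidate
extended regions of weak, "flexible" CsrA binding; larger runs are reported
but not flagged.  Conformations are classified by high-affinity-site count
(0/1/2), strong cooperativity (dG_coop <= -4 RT and d < 25 nt), and large
structural change (ddG_unfold >= 3 RT); cohort counts are tested with exact
hypergeometric tails computed by log-space summation of the probability
mass (cross-validated in the tests against scipy and exact rational
enumeration).  A point-probability (non-cumulative) variant is also
provided because published contingency analyses of this kind sometimes
report that quantity; inference should use the tails.

## Titration analysis

Reporter fluorescence measured across a ladder of CsrA expression levels
(the RBS design proxy, in AU; uninduced points are the RBS level times the
promoter-leakiness factor 0.000645) is converted to repression ratios
(dataset maximum of the average mean fluorescences over each point's value,
so the brightest point has ratio 1) and min-max normalized.  Treating the
normalized ratio as fractional occupancy theta, K_d is fitted from
theta = [CsrA]/(K_d + [CsrA]) by least squares on log K_d with multi-start
initialization.  Because the data are min-max normalized, the fitted model
is the same hyperbola passed through the identical normalization over the
measured expression levels; this self-consistent form recovers K_d exactly
from noiseless data, which the raw hyperbola cannot (normalization rescales
theta whenever the design does not span occupancy 0 to 1).  Non-convergent
fits are returned flagged, never silently.

## Synthetic fixtures

The generator plants features in a strictly alternating C/U background:
C/U-only sequence contains no favorable CsrA window, cannot base-pair with
itself, and offers no stable pairing partner to planted G-rich elements,
so every energy term traces to a planted feature.  Kinds: consensus pairs
at controlled spacing far upstream (expected: no impact), a consensus site
inside the Shine-Dalgarno region or on the start codon with an upstream
partner (expected: repression), a weak ~6-RT stem that sequesters the early
CDS and is melted by the most favorable pair (expected: activation), a
hairpin-sequestered SD for free-state energetics, a C/U-only null, and a
tiled AAG-repeat cluster that produces one flexible pocket.  Everything is
deterministic per seed.

Real mRNAs differ from these fixtures in ways that matter: natural
sequences carry many competing sites and structures, GU wobble pairing
makes even pyrimidine-rich backgrounds foldable, and 5'-UTR boundaries are
uncertain.  Passing the fixture battery therefore demonstrates the internal
consistency and the qualitative mechanics of the model, not genome-scale
predictive accuracy.

## Numerical choices and limitations

* Energies are carried in RT end to end; RT = 0.61633 kcal/mol at 37 degC
  is the only conversion constant.
* Boltzmann weights are computed in log space; probability sums are tested
  to 1e-9.
* Tiny negative constrained-minus-unconstrained differences from engine
  round-off are clamped to zero.
* Ties in dG_total are broken by site coordinates so reruns are
  byte-identical.
* Problem sizes in the tests and the acceptance script (records of
  100-130 nt, cohorts of ~100 fixtures, 100 titration replicates) were
  chosen so the whole battery exercises every code path in well under a
  minute each while leaving every invariant binding.
* Single MFE structures are used throughout (no partition-function
  ensembles for the mRNA fold), no pseudoknots, one homodimer per mRNA,
  no CsrA concentration dependence, and no translational coupling or
  ribosome re-initiation; mRNAs regulated through those mechanisms are
  outside the model.
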