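# Methods

## Scope and data model

`chemprof` profiles compound libraries for drug-likeness and DMPK
compliance. A library is an ordered list of records; each record is a
structure (RDKit molecule, optional) plus verbatim property tags. Every
numeric quantity lives in a `DescriptorVector`: a sparse map from
canonical descriptor names to values, each entry tagged `native`
(computed here from the structure) or `imported` (parsed from tags
written by external ADMET predictors). Absent entries are *missing*, and
missingness is always explicit downstream: a record with a missing
required descriptor is never silently passed or failed by a rule — it is
marked not-evaluable and tallied separately.

Imported and native values are merged per descriptor under a policy
(`prefer_imported` by default, since external predictions are usually
the point of carrying tags); disagreements beyond 10% relative are
logged. Counts are stored as floats because imported library-average
rows legitimately carry fractional counts (e.g. a mean HBD of 1.67).

## Native descriptors

* MW: standard-atomic-weight sum including implicit hydrogens.
* log *P*: Wildman–Crippen atom contributions. External tools use
  proprietary predictors, so native and imported log *P* can differ by
  several tenths; comparisons involving native log *P* carry that caveat.
* HBA/HBD: Lipinski convention (N+O count; N–H/O–H hydrogen count) by
  default, because that is the convention the rule-of-five context
  assumes. A perception-based mode (`hb_mode="perception"`) exists for
  pharmacophore-style counting.
* NRB: non-ring single bonds between heavy atoms of degree ≥ 2, amide
  C–N excluded (RDKit strict definition).
* NR: SSSR ring count. NO/NCC: oxygen/carbon atom counts (NCC is
  interpreted as carbon count; configurable, since usage varies).
* TPSA: Ertl fragment contributions.
* Multi-fragment records (salts): largest heavy-atom fragment, ties by
  MW then input order.

### Surface family

SASA is computed by Shrake–Rupley sampling: each atom's Bondi vdW sphere
is inflated by the probe radius (default 1.4 Å, water-sized) and sampled
with a golden-spiral lattice (default 960 points/atom); a point is
accessible if outside every other inflated sphere. The lattice is
seedless and fixed, so SASA is reproducible bit-for-bit. Exactly
coincident identical spheres are collapsed before sampling so the
degenerate surface is counted once. At 960 points/atom the sampling
error is well under 1% against a 10⁴-point Monte-Carlo oracle (tested on
a fixed methane geometry); the closed-form single-sphere case is exact.

FOSA is the surface contribution of carbons and carbon-bound hydrogens;
if a conformer lacks explicit hydrogens, their contribution is absent
from both totals. Molecular volume is the grid volume enclosed by the
same inflated spheres (default spacing 0.4 Å). Records without 3D
coordinates report the whole family as missing.

Derived indices:

* Globularity Glob = 4π*r*²/SASA with *r* the equal-volume sphere
  radius — exactly 1 for a sphere, decreasing as shape departs from
  spherical. Values slightly above 1 are possible from sampling noise.
* Cohesion index Ind_coh = HBA·√HBD/SASA, a crystal-packing proxy.

## Rule sets

All rule sets are data (criterion label, descriptor, comparator,
threshold), shipped in `rules.RULESETS` and overridable from YAML.

* **ro5**: violations among MW > 500, log *P* > 5, HBA > 10, HBD > 5.
  Thresholds inclusive ("≤ 500" does not violate); strict mode exposed
  because published percentages rarely state their convention. NRB ≤ 5
  is advisory only and never counted — violation histograms
  conventionally top out at 4.
* **Subsets**: drug-like (MW < 500, log *P* < 5, HBD ≤ 5, HBA ≤ 10),
  lead-like (150 ≤ MW ≤ 350, log *P* ≤ 4, HBD ≤ 3, HBA ≤ 6),
  fragment-like (MW ≤ 250, −2 ≤ log *P* ≤ 3, HBD < 3, HBA < 6, NRB < 3).
  Each printed criterion is applied literally, strict/inclusive mix as
  printed. Lead-like provably implies drug-like; fragment-like does not
  imply lead-like (MW below 150).
* **ro3**: log *S* > −5.7, Caco-2 > 22 nm/s (strict), primary
  metabolites < 7 (strict). The solubility threshold is Jorgensen's
  published value and is config-exposed, since quoted variants of the
  rule differ in how they state it.

## #stars

One star per descriptor outside its "range for 95% of known drugs";
the shipped table is the 19 descriptors with published bounds, closed at
both ends (a value equal to a bound is in range). Scores computed from
fewer than the full 24-descriptor set used by commercial tools are an
approximation; the five unpublished ranges cannot be shipped.

Three bounds deserve comment:

* Caco-2 and MDCK are one-sided: their anchors ("<5 low"; "<25 poor,
  >500 great") make only *low* permeability a concern, so exceeding the
  upper anchor never costs a star. The 25–500 nm/s MDCK band is kept
  separately (`MDCK_BAND`) for range-compliance reporting, where the
  fraction-within-band statistic is conventionally quoted.
* logB/B and log *K*<sub>HSA</sub> have two published upper bounds
  (1.0 vs 1.2; 1.2 vs 1.5); the tabulated (tighter) pair is the default
  and the wider pair ships as the `prose` variant.
* logHERG is one-sided: concern below −5.

## DMPK closed forms

**Similarity-adjusted solubility.** External solubility predictors blend
their regression output with the experimental value of the most similar
training-set compound when the similarity *s* exceeds 0.9. Only the two
boundary conditions of that blend are public (below 0.9 the raw
prediction; at *s* = 1 the experimental value exactly); the implemented
form is the unique affine interpolation satisfying both:
λ = (s − 0.9)/0.1 clamped to [0, 1], P_adj = P_pred + λ·(P_exp − P_pred,analogue).
It is continuous at the knee and monotone in *s*.

**Transdermal rate.** J_m = C · 10^log *K*ₚ · 10^log *S* · MW. The
constant C = 1000 comes from dimensional analysis of
cm hr⁻¹ × mol L⁻¹ × g mol⁻¹ → µg cm⁻² hr⁻¹ (1 L = 1000 cm³); it is
config-exposed, as is the 100 µg cm⁻² hr⁻¹ reporting cutoff.

## Diversity analysis

Descriptor matrices (default panel MW, HBA, HBD, NCC, NO, NRB, log *P*,
NR, TPSA) are completed by dropping incomplete records (or mean
imputation), standardized to mean 0 and *sample* variance 1 (ddof = 1 —
fixed by the convention that a 3-point column (1, 2, 3) maps to
(−1, 0, 1)), then decomposed by PCA on the correlation structure.
Components are sign-fixed (largest-magnitude loading positive) so score
exports are reproducible. Two-library overlays fit standardization and
PCA on the pooled matrix by default — per-library fitting would place
the clouds in incomparable coordinates — and report per-library outlier
counts at a configurable Mahalanobis radius in PC space.

## RECAP fragmentation

Cleavable bonds are identified by an own bond-SMARTS table covering the
eleven published RECAP bond types (amide, ester, acyclic and cyclic
amine, urea as a pair of amide cuts, ether, olefin, quaternary N,
aromatic N–aliphatic C, lactam N–aliphatic C, biaryl, sulphonamide);
ring bonds are never cut. All matching bonds are cut simultaneously in
one pass, so the fragments partition the parent's atoms: non-attachment
heavy atoms sum exactly to the parent's heavy-atom count, and
re-fragmenting a fragment returns it unchanged (atoms adjacent to an
attachment point are excluded from further matching). This differs
deliberately from hierarchy-style decompositions, whose retro-reactions
delete linker atoms (the urea carbonyl, the ether oxygen) and so break
both properties; here linkers survive as small fragments and are
suppressed from rankings by the minimum-size filter (default 4 heavy
atoms — a convention of this package, not a published value).

Ranking is by number of distinct parents, then fragment size, then key —
fully deterministic. Molecules above the MW cutoff (default 700 Da) are
excluded first. Frequency ranking stands in for hierarchical
maximum-common-substructure clustering; it finds the same "most common
cyclic cores" reading but is not an MCS reproduction.

## Synthetic data

The generators make every test and the acceptance run self-contained.

* **Boundary fixtures**: ~30 real structures (shipped SMILES, from water
  through reserpine and a triglyceride) exercising parsing, 3D IO and
  fragmentation, plus 32 pure descriptor vectors sitting exactly on and
  adjacent to every rule threshold (MW 249/250/251 … 724/726, log *P* −2
  and 6, HBA 6/10, HBD 3/5, NRB 3/15 and neighbours). Exact boundary
  values are expressed as vectors because real molecules essentially
  never hit MW 500.000. Expected truths are derived by a brute-force
  checker local to the generator module that shares no code with the
  rule engine, and re-verified independently in the test suite.
* **Random libraries**: seeded draws, one distribution family per
  descriptor (normal, mean-matched lognormal, Poisson for counts,
  clipped normal for bounded scales). The default profile emulates a
  diverse natural-product screening library of 1,008 compounds: location
  parameters sit at that setting's published averages (MW 406 Da,
  log *P* 3.99, HBA 5.76, HBD 1.67, NRB 6.30, log *S* −5.11, …) and
  spreads are fixed a priori by the same setting's published marginal
  tail fractions where available (e.g. log *P* sd 1.0 from ~16% above 5;
  log *S* sd 0.93 from 73.8% above −5.7; Caco-2 log-sd 3.22 jointly from
  mean 1516 nm/s and 38.2% above 22 nm/s; MDCK log-sd 2.0 from ~53%
  inside 25–500; the oral-absorption clip from 47% at 100% and 63.1%
  above 90%), otherwise by typical drug-library spreads. The surface
  family is internally consistent by construction (volume and
  globularity drawn; SASA from the globularity definition; FOSA a drawn
  fraction of SASA; Ind_coh derived), so physical invariants hold on
  every record.
* **Two-population libraries** offset one profile's location parameters
  for PCA-separation tests; **factor-structured matrices** provide
  9-column data with a known 3-factor covariance and a closed-form
  generating variance fraction for PCA parameter-recovery checks.
  Seeds expand to per-component seeds via `numpy` seed-sequence
  spawning; all values pass through a fixed decimal format, so equal
  inputs give byte-identical libraries.

### What the generator does *not* emulate

Descriptors are drawn **independently**. Real libraries correlate them
strongly (big molecules carry more acceptors, poor solubility
accompanies high log *P*, permeabilities co-vary), which has two visible
consequences: joint statistics are depressed relative to real libraries
(the all-descriptor zero-star fraction and the all-three-criteria ro3
compliance come out much lower than any single-descriptor compliance),
and a 9-descriptor PCA finds little shared variance (first three PCs
≈ 36% on synthetic data vs. ~60–80% typical of real libraries). Passing
tests therefore demonstrate correctness of the computations, not
distributional realism of joint properties. Structure-mode generation
decorates eight shipped ring scaffolds with ten substituents and covers
parsing/fragmentation paths, not natural-product scaffold diversity.

## Numerical and reporting choices

* Histogram bins are half-open [lower, lower + width) anchored at a
  configurable origin and labeled by lower edge; axes conventionally
  printed "301–400" appear as 300–400 (a one-unit cosmetic difference).
  Enhancement between two libraries sums percentage-point differences
  over bins whose centers fall in the queried range; over the full range
  it is zero by conservation.
* Summary means are arithmetic means over evaluable records; rule
  percentages are reported over both the full library and the evaluable
  subset, since published figures rarely state their denominator.
* All report outputs (JSON with sorted keys, TSV) are byte-identical
  across runs on identical input; no unseeded randomness exists outside
  the generators.
* The acceptance script sizes its run at the study-condition library
  size (1,008 records) plus a 300-record structure library; the whole
  run completes in a few seconds.

## Known limitations

* Native #stars uses 19 of the 24 ranges used by commercial tools; the
  remaining five are not public.
* Native log *P*/TPSA replace proprietary predictions, so star scores
  and ro5 counts computed natively can differ near thresholds from those
  computed with imported tags.
* SASA/FOSA depend on the conformer provided; no conformer generation or
  minimization is performed.
* The `.ldb` library dialect is proprietary and unsupported; SDF is
  V2000 only (V3000 is rejected with a clear error).
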