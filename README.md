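# chemprof

Drug-likeness and DMPK compliance profiling for small-molecule compound
libraries.

Screening collections — especially natural-product libraries, whose
members range from rigid polycyclic cores to 60-rotor macrolides — are
routinely triaged by physico-chemical rules before any assay or docking
campaign. `chemprof` reads a library (SDF V2000 with embedded property
tags, SMILES lists, or plain descriptor tables), computes or imports the
standard descriptors, and reports how the library fares against the
canonical oral-bioavailability filters and ADMET property ranges.

## What it computes

**Rule of five (ro5).** A violation is any of MW > 500 Da, log *P* > 5,
HBA > 10, HBD > 5 (Lipinski N+O / NH+OH counting). The rotatable-bond
criterion NRB ≤ 5 is reported as advisory but never enters the violation
count. Inclusive boundaries by default; a strict mode is exposed.

**Screening subsets.** Drug-like (MW < 500, log *P* < 5, HBD ≤ 5,
HBA ≤ 10), lead-like (150 ≤ MW ≤ 350, log *P* ≤ 4, HBD ≤ 3, HBA ≤ 6) and
fragment-like (MW ≤ 250, −2 ≤ log *P* ≤ 3, HBD < 3, HBA < 6, NRB < 3),
each criterion applied exactly as conventionally printed.

**#stars.** For 19 descriptors with published "range for 95% of known
drugs" bounds (MW 130–725 Da, log *P* −2–6, … log *K*<sub>p</sub>
−8.0–−1.0, #metab 1–8), one star per descriptor outside its range;
0 stars is full DMPK compliance. Missing descriptors are skipped and
reported, never scored.

**Rule of three (ro3).** Jorgensen's oral-availability heuristic:
log *S* > −5.7, Caco-2 permeability > 22 nm/s, predicted primary
metabolites < 7.

**Native descriptors.** MW, Wildman–Crippen log *P*, HBA/HBD, rotatable
bonds, ring/atom counts and TPSA from the structure via RDKit; the
surface family by Shrake–Rupley sampling at probe radius 1.4 Å
(SASA, hydrophobic SASA, molecular volume) with the derived shape and
packing indices

> Glob = 4π*r*²/SASA with *r* = (3*V*/4π)^⅓,  Ind_coh = HBA·√HBD/SASA.

External ADMET predictions (log *S*, log B/B, Caco-2, MDCK, HERG, …)
are consumed from SDF property tags, never re-derived.

**DMPK closed forms.** Similarity-adjusted solubility (predictions blend
linearly toward the experimental value of the nearest training-set
analogue once similarity exceeds 0.9) and the maximum transdermal
transport rate *J*<sub>m</sub> = 1000 · 10^log *K*ₚ · 10^log *S* · MW in
µg cm⁻² hr⁻¹.

**Diversity and substructures.** Correlation-matrix PCA of a 9-descriptor
panel (MW, HBA, HBD, NCC, NO, NRB, log *P*, NR, TPSA) with 3-PC score
overlays for library-vs-library comparison, and RECAP fragmentation with
fragment-frequency ranking (molecules above 700 Da excluded first).

## Worked example

```python
from chemprof import (
    DescriptorVector, attach_descriptors, lipinski_violations, profile,
    random_library, star_score, transdermal_rate,
)
from chemprof.dmpk import attach_jm

# one molecule against the rules
dv = DescriptorVector.from_dict({"MW": 406.0, "logP": 3.99, "HBA": 6, "HBD": 2})
out = lipinski_violations(dv)
print(out.violations, out.passed)        # 0 True   -> orally available by ro5

print(star_score(DescriptorVector.from_dict(
    {"MW": 1000.0, "logS_wat": -7.0})).violated)
# ('MW', 'logS_wat')                      -> 2 stars, both out of range

print(transdermal_rate(-2, -3, 300))     # 3.0 ug/cm^2/hr

# a whole library (synthetic natural-product-like profile, seeded)
lib = random_library(1008, seed=42, name="demo")
desc = attach_descriptors(lib)
attach_jm(desc)
p = profile(lib, desc)
print(round(p["ro5"]["pct_zero_of_evaluable"], 1))      # 61.8  (% with 0 violations)
print(p["rows"]["Drug-like"]["size"],
      p["rows"]["Lead-like"]["size"])                   # 623 99
print(round(p["rows"]["Total"]["descriptors"]["MW"]["mean"], 1))  # 407.2
```

The same pipeline is available from the shell:

```sh
chemprof profile library.sdf -o out/        # profile.json + histograms/*.tsv
chemprof stars library.sdf -o out/          # #stars distribution + per-record table
chemprof subset library.sdf --rule lead_like -o out/
chemprof diversity a.sdf b.sdf -o out/      # pooled PCA scores + variance
chemprof fragments library.sdf -o out/      # ranked RECAP fragments
chemprof compare a.sdf b.sdf --descriptor MW --range 300 500
chemprof synth --kind boundary -o fixtures/
```

All reports are byte-identical across runs on identical input; the only
randomness lives in the synthetic generators, which take seeds.

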