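# foxcoop

Quantitative analysis of cooperative binding of forkhead-box (FOX)
transcription factors to homotypic DNA site clusters — for structural
biologists and biophysicists characterising multi-site protein–DNA
assembly with gel shifts (EMSA), titration calorimetry (ITC),
light-scattering masses (SEC-MALS) and crystal-structure geometry.

A promoter can carry two adjacent binding elements for the same factor: a
canonical FOX-binding element (FBE, 5′-RYAAAYA-3′, R = A/G, Y = C/T) plus
a second, non-canonical site created when the first binding event narrows
the DNA minor groove (DNA allostery).  `foxcoop` implements the pieces
needed to detect and quantify that behaviour:

* **Two-site lattice model.**  With microscopic association constants
  K₁, K₂ and cooperativity factor ω, the partition function is
  Z = 1 + (K₁+K₂)p + ωK₁K₂p², giving the band fractions
  f₀ = 1/Z, f₁ = (K₁+K₂)p/Z, f₂ = ωK₁K₂p²/Z.  Free protein p is solved
  under ligand depletion.  ω is estimated per lane as 4f₀f₂/f₁² (exact
  for equivalent sites) or by full least-squares fitting; ω > 1 means
  positive cooperativity.
* **ITC.**  Simulation and fitting of one-site vs sequential two-site
  isotherms with proper cell-displacement bookkeeping, AICc model
  selection, and a biphasic index flagging non-monotone isotherms — the
  calorimetric signature of two distinct binding events.
* **Stoichiometry.**  Integer protomer counts per duplex from SEC-MALS
  masses plus the duplex mass computed from sequence.
* **Minor-groove geometry.**  Per-level widths (closest cross-groove P–P
  distance − 5.8 Å) from PDB files or from a built-in ideal fiber B-DNA
  generator that reproduces the canonical 5.7 Å baseline.
* **Synthetic data.**  Seeded generators for every input (EMSA tables,
  ITC traces, promoter sequences, B-DNA coordinates), so the whole
  pipeline runs and is tested without any downloads.

## Worked example

```python
from foxcoop import (estimate_omega, simulate_series, scan,
                     annotate_homotypic_pairs, duplex_mass,
                     infer_stoichiometry, make_fiber_bdna,
                     minor_groove_widths)
from foxcoop.reference import (P53_DNA, FBE_CONSENSUS, FBE2_PATTERN,
                               DEFAULT_WT_PARAMS, DEFAULT_D_TOTAL,
                               DEFAULT_MOLAR_RATIOS)

(hit,) = scan(P53_DNA, FBE_CONSENSUS)
print(f"FBE hit: [{hit.start}, {hit.end}) strand {hit.strand} site {hit.site}")
(pair,) = annotate_homotypic_pairs([hit], FBE2_PATTERN, P53_DNA)
print(f"homotypic pair: FBE2 {pair.secondary.site} overlap {pair.overlap} bp")

lanes = simulate_series(DEFAULT_WT_PARAMS,
                        [r * DEFAULT_D_TOTAL for r in DEFAULT_MOLAR_RATIOS],
                        DEFAULT_D_TOTAL)
est = estimate_omega(lanes)
print(f"omega = {est.omega_hat:.2f} +/- {est.se:.2f} "
      f"({est.classification}, {est.n_used} lanes)")

mass = duplex_mass(P53_DNA)
print(f"duplex mass = {mass:.2f} kDa -> "
      f"{infer_stoichiometry(32.7, 12.4, mass).n_protein} protomers per duplex")

widths = minor_groove_widths(make_fiber_bdna(16)).widths()
print(f"ideal B-DNA minor groove width = {widths.mean():.2f} A")
```

prints

```
FBE hit: [3, 10) strand - site TATTTAT
homotypic pair: FBE2 ATTATCG overlap 2 bp
omega = 3.00 +/- 0.00 (positive, 4 lanes)
duplex mass = 9.92 kDa -> 2 protomers per duplex
ideal B-DNA minor groove width = 5.74 A
```

Reading: the 16-mer promoter probe contains exactly one consensus FBE on
the reverse strand (plus-strand interval [3, 10), site TATTTAT) with the
second site overlapping it by two bases; a cooperative titration
(ω = 3) is read back exactly by the lane estimator and classified
positive; the 32.7 kDa complex mass corresponds to two 12.4 kDa protomers
on the 9.92 kDa duplex; and the ideal B-DNA reference groove width is
5.74 Å, against which narrowed (allosterically deformed) duplexes are
compared.

The same analyses are available from the shell:

```bash
foxcoop groove --fiber 16 --out bdna_profile.tsv
foxcoop simulate emsa --scenario WT --seed 1 --out lanes.tsv
foxcoop emsa-omega --table lanes.tsv
foxcoop run --config demo.yaml     # scan -> EMSA -> ITC -> groove report
```

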