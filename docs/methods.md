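# Methods

## The statistic

For one OTU with pooled relative abundances h₁₃, l₁₃ (heavy/light pools of
the ¹³C incubation) and h₁₂, l₁₂ (the ¹²C control),

    REF = (h₁₃ / l₁₃) / (h₁₂ / l₁₂).

The control ratio h₁₂/l₁₂ removes the OTU's intrinsic density preference
(GC content), so REF > 1 indicates a density shift attributable to isotope
incorporation. An OTU is called *active* when REF > 1.0 and its
whole-community (unfractionated) relative abundance exceeds 1.0%; both
inequalities are strict, and the abundance screen is applied to the
whole-community value, not the heavy-pool value (the reference dataset
contains an OTU with heavy abundance 0.52% but community abundance 1.32%
that is active, which fixes this reading). REF > 1 is a deliberately loose
screen — it trades specificity for detectable diversity — which is why the
community-abundance screen and the downstream trophic classification are
part of the calling procedure rather than afterthoughts.

Zero handling: l₁₃ = 0, h₁₂ = 0 or l₁₂ = 0 makes REF undefined; the OTU is
reported with REF = NaN and is never active. h₁₃ = 0 gives REF = 0. No
pseudocounts are added by default; `pseudo` (a pseudo-abundance added to
all four terms) exists for exploratory use because it changes rankings and
must be an explicit choice.

Active labeled OTUs are classified against a lineage reference table:
exact lineage match first, then (under the default
`nearest_annotated_lineage` rule) the most specific annotated rank of the
lineage; anything without autotrophy evidence defaults to *transformer* —
the conservative reading that an unexplained labeled heterotroph acquired
carbon by cross-feeding, not fixation. `unknown` is available as a default
for non-SIP uses.

Relative biomass of a group is RA × C with RA the group's whole-community
relative abundance and C the extractable DNA concentration (μg per g
soil). It is exactly additive over group members; the packaged dataset
carries no per-sample DNA concentrations, so biomass is exercised as a
property (additivity), not as a reproduced number.

## Stratification and pooling

Fractions with BD above the threshold (default 1.7274 g/mL) are heavy,
below are light. A fraction exactly at the threshold goes heavy by
default: reported heavy-pool BD ranges start *at* the threshold value,
while the verbal rule is a strict inequality — the two readings conflict,
so the tie rule is configurable (`equality_rule`).

Pooled abundance is Σ_f w_f · share(taxon in f) over the pool's fractions.
The default weight is the fraction's DNA yield (`dna_quantity`), emulating
the physical pooling of fraction DNA before a single sequencing run; the
actual pooling volumes of any real experiment are unrecoverable, so this
is a modeling choice, not a reconstruction. `counts` weighting (equivalent
to summing raw counts) is exact for purely in-silico reanalyses, and
`equal` averages per-fraction proportions. Taxa absent from a pool get
abundance 0, not missing — the REF zero policy then applies.

## The gradient simulator

The simulator emulates the statistical consequences of isopycnic
ultracentrifugation, not its hydrodynamics. Each taxon's DNA takes a
normal BD distribution:

- mean = Schildkraut GC relation, 1.660 + 0.098·GC g/mL, plus a linear
  label shift of 0.036 g/mL per unit atom-fraction excess (AFE; full ¹³C
  labeling ≈ +0.036 g/mL). These constants are standard SIP physics,
  exposed in `GradientConfig` so nothing downstream depends on them;
- within-taxon spread `density_sd` = 0.004 g/mL;
- the gradient spans 1.690–1.775 g/mL, cut into 12 equal-width bins
  ("fractions") numbered densest-first, so heavier DNA appears in
  lower-numbered fractions; bins are half-open [low, high) with the
  densest bin closed, realized exactly by CDF-difference integration; each
  fraction reports its bin-midpoint BD;
- per-taxon bin masses are the normal integral over the bin, renormalized
  to the in-range total (truncation), so each taxon's mass is conserved to
  1e-9; a taxon whose peak lies essentially outside the gradient raises an
  error naming it;
- `smear_fraction` (default 0.01) of every taxon's DNA is spread uniformly
  over all fractions. This represents the diffusive tailing and
  fraction-collection carryover that make unlabeled heavy fractions
  sequenceable in real gradients. It is essential, not cosmetic: with a
  pure normal at sd 0.004, a fully labeled taxon (shift ≈ 8 sd) has no
  light-side mass and an unlabeled taxon no heavy-side mass, every REF of
  interest becomes 0/0, and the statistic cannot be studied at all. 1% is
  at the scale of the whole-community background routinely amplified from
  ¹²C-heavy fractions;
- sequencing is a per-fraction multinomial of `depth_per_fraction` reads
  (default 50,000) with probabilities proportional to per-taxon mass in
  the fraction — fixed depth per library, as in practice, and no
  PCR/compositional bias term: the simplest null that preserves
  relative-abundance semantics;
- total loaded DNA defaults to 5 mass units (≈ the ~5 μg loaded per tube).

The paired experiment simulates the ¹³C run and a ¹²C control sharing the
community (all AFE forced to 0) **and the random stream** (common random
numbers): re-running with one seed is byte-deterministic, and with no
labeled taxa the two runs are identical tables, so the no-labeling null
has REF exactly 1 for every taxon. With labeled taxa present the
multinomial probabilities differ between runs and genuine sampling noise
enters every REF. The unfractionated community library is drawn with a
separately derived stream.

`random_community` builds the default study scenario: 50 taxa, GC uniform
on 0.55–0.70 (soil Actinobacteria/Proteobacteria territory; unlabeled
peaks then fall at 1.714–1.729 g/mL, straddling the pooling threshold the
way a real unlabeled community peak near 1.72 does), lognormal baseline
abundances, and 5 labeled taxa at AFE 0.9 with baselines of 2–4% so they
clear the 1% community screen when recovered.

What the simulator does **not** model: gradient deformation, chimeras,
PCR and copy-number bias, replicate-to-replicate variation (replicates
are pooled before ultracentrifugation, so one gradient per treatment), or
read-level error. Passing recovery tests therefore show that the
inference chain is correct and well calibrated under clean SIP physics —
not that real communities with compositional bias would be recovered at
the same rates.

## Numerical and interface choices

- Percentages are rounded half-away-from-zero to 2 decimals only in the
  summary layer; all internal arithmetic is unrounded.
- Active lists are ordered by descending REF, ties broken by natural
  taxon-id order; all readers/writers are plain text (TSV matrices, CSV
  metadata, JSON summaries, YAML configs), UTF-8, Unix newlines.
- Original (pre-incubation, "OS") samples describe community composition
  but never enter REF calling — no ¹³C OS treatment exists.
- The packaged reference table stores abundances exactly as reported
  (2 decimals). Two reported BSC fixer community fractions are not the sum
  of their listed per-OTU abundances: recomputation gives 5.72 (RP) and
  9.62 (SHP) against reported 5.71 and 9.71. The RP gap is input rounding;
  the SHP gap (0.09) suggests an unlisted contributing OTU and cannot be
  resolved from the per-OTU listing, so the module exposes both values and
  tests do not assert exact equality for that group. All other summaries
  reproduce exactly.

## Problem sizes

Calibration suites run at the scenario defaults: null calibration over 50
seeded simulations (50 taxa, no labeling, 50,000 reads/fraction) checks
median REF within 1 ± 0.15 and a spurious active-call rate ≤ 10% among
taxa above the 1% screen; recovery over 10 seeded simulations (5/50 taxa
labeled at AFE 0.9) checks mean sensitivity ≥ 0.9 with no abundant
unlabeled taxon exceeding REF 1.5 in more than 20% of seeds; REF
monotonicity in AFE is checked at AFE ∈ {0, 0.3, 0.6, 0.9} over 20 seeds
(REF saturates once the labeled peak sits fully inside the heavy pool, so
full sequencing depth is needed for the median ordering to be signal
rather than noise). The entire suite completes in a few seconds.
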