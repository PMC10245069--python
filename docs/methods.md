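# Methods

This note records the models implemented in `mlascan`, the defaults and why
they were chosen, and what the synthetic-data generator does and does not
emulate.

## Screen design being modelled

A complete single-mutation NNS library over a 211-residue periplasmic
carrier protein (signal peptide included, positions 1–21), split into two
amplicon sub-libraries covering positions 1–107 and 108–211 so each amplicon
fits a merged 2×250 paired-end read. The sub-libraries are counted and
normalized independently and concatenated by position only at the landscape
level. Two biological replicates of a paired selection / no-selection
plating are simulated, and the default per-variant sequencing depth is 300×,
inside the ~306–462× coverage band of the experiment the pipeline mirrors.

## Fitness estimator

For variant *x* at position *i*, with counts-per-million frequencies `f` in
the selected and unselected populations,

    ΔE_ix = log(f_ix,sel / f_ix,unsel) − log(f_iWT,sel / f_iWT,unsel)

- **Log base.** Natural log. The underlying quantity is a log enrichment
  ratio whose base is a unit convention; `log_base` is exposed on
  `compute_fitness` for anyone who needs log2 or log10 scores.
- **Pseudocount.** Default 1 read added to every variant cell and to the
  wild-type tally of both conditions before CPM normalization. This keeps
  strongly depleted variants finite instead of −∞ and is applied identically
  to both conditions so neutral variants are unbiased. With
  `pseudocount=0`, zero-frequency cells are masked NA rather than scored.
- **Replicates.** Cell-wise mean; a cell is NA only when unobserved in every
  replicate, and cells averaged from a strict subset of replicates carry a
  `partial` flag.

## Selection model in the simulator

Post-selection frequencies are proportional to pre-selection frequencies
times `exp(ΔE_true)`, renormalized; the wild type multiplies by 1. This is a
modelling choice, not a claim about bacterial growth on selective plates: it
makes the log-ratio estimator the exact algebraic inverse of the simulator,
so the package can verify a closed-form round trip (max absolute error at
machine precision) before any read sampling enters. A real plating
experiment has an unknown effective number of generations, so the absolute
scale of ΔE is only self-consistent — a caveat that applies equally to the
real screen.

Planted effects default to a mixture: 65% near-neutral (Normal(0, 0.15)),
35% deleterious (Normal(−3, 1.5) truncated at 0), stops strongly deleterious
(Normal(−6, 0.5) truncated at 0). The mixture puts most variants where the
estimator must distinguish small effects, with a deleterious tail deep
enough to exercise the depletion regime.

## Read simulation and counting

Reads are a multinomial draw over variants plus wild type, each variant
encoded by one fixed NNS codon; per-base substitution errors at 10⁻³
(Illumina-like after merging) and a 50% reverse-complemented fraction are
applied. Indels are not simulated: the exact-length filter in the counting
stage would discard them, so they would only re-measure the filter.

Counting discards, with per-reason tallies: wrong-length reads; reads whose
orientation is ambiguous (equal Hamming distance both ways); reads
translating outside the 21-letter alphabet; and reads with ≥2 protein
mismatches. Multi-mutants are discarded rather than decomposed because the
library is single-mutant by construction — a second mutation is almost
always a sequencing error and its variant assignment would be ambiguous.
`orient_and_translate` is the reference single-read implementation; the
pipeline uses a vectorized byte-matrix path (`translate_reads`) that is
tested for read-by-read equality with it, which is what makes full-depth
simulation (≈5M reads) tractable in minutes on one core.

**What the generator does not emulate:** PCR amplification bias, library
bottlenecking, colony-sampling noise, quality-score structure, adapter
read-through, or chimeric reads. Passing recovery tests therefore shows the
estimator and bookkeeping are correct under multinomial sampling with
substitution noise — not that a real experiment's covariates are handled.

## Residue selection rule

A position is selected when ≥ k (default 5) of its mutations score more than
m (default 1) standard deviations beyond the mean of all observed mutation
scores. Conventions, fixed here because the rule is stated loosely wherever
it is used in the field:

- μ and σ are computed over all non-NA mutation cells of the
  replicate-averaged landscape, stop variants included;
- σ is the population SD (ddof = 0) — this is what reproduces the
  hand-computable oracle (60 cells, six at −3: μ = −0.3, σ = 0.9 exactly);
- the default is one-sided (ΔE < μ − mσ), since the screen is a
  loss-of-function selection and essentially no variants score above
  neutral; `two_sided` is available and both settings are exercised in
  validation against deposited scores.

Group classification (signal peptide > pocket > buried > surface precedence)
consumes a user annotation; the package ships no structural annotation of
its own.

## Interface mapping

- Heavy atoms only (predicted models carry no hydrogens anyway); altlocs
  resolved to highest occupancy; strict `<` at the cutoff (default 4.0 Å).
  The deposited-model residue counts are convention-sensitive at the
  boundary; the convention here is fixed and reported.
- Contact search uses a KD-tree over one group's atoms; equality with the
  O(n²) brute-force oracle is asserted over hundreds of random fixtures.
- Residue numbering: models that omit residues (e.g. a mature-protein model
  without its 21-residue signal peptide, or a ring subunit missing
  termini) carry per-chain offsets applied when footprints are reported, so
  overlaps with screen hits are in full-length coordinates. Disjoint
  footprint/hit ranges trigger a numbering warning.
- Hinge analysis: models sharing a ring scaffold are superposed on the first
  via common ring Cα atoms (Kabsch, proper rotations only); the pairwise
  carrier angle is the rotation angle of the transform mapping one aligned
  carrier Cα set onto another. The inward/outward score is the distance from
  the carrier Cα centroid to the ring symmetry axis, taken as the
  least-variance principal axis of the ring Cα cloud through its centroid —
  minimum score is labelled "inward", maximum "outward". An alternative
  metric (pocket-entrance to tunnel distance) would need a pocket
  definition and is deliberately not the default.

## 1:1 kinetics fitting

Forward model (association from the start of the association window at t₀,
dissociation decaying from the model value at the end of association —
continuity is built in, not penalized):

    R_assoc(t)  = R_eq (1 − exp(−(k_on C + k_off)(t − t₀))),  R_eq = R_max C / (C + K_D)
    R_dissoc(t) = R_end exp(−k_off (t − t₁))

- Baseline: mean of the final 10 s of the baseline phase subtracted per
  trace; its SD is the noise floor.
- Global fit: k_on, k_off and (by default) R_max shared across all traces of
  a sensor, mirroring single-sensor experimental practice; per-trace R_max
  optional. Nonlinear least squares in log₁₀(k_on), log₁₀(k_off) with a 3×3
  log-spaced multi-start grid; bounds k_on ∈ [10², 10⁸] M⁻¹s⁻¹,
  k_off ∈ [10⁻⁵, 10] s⁻¹.
- Detection: the trace set is "unfittable" when the mean baseline-subtracted
  response over the final 20% of the association window stays below 3× the
  baseline noise SD. The plateau mean is used instead of the raw peak
  because a single noise spike should not promote a signal-free sensor to
  fittable.
- Binding calls vs a reference fit: "none" if unfittable at the highest
  tested concentration; "diminished" if K_D fold-change > 3; else
  "wt_like". The 3× threshold sits between replicate-level K_D scatter
  (tens of percent) and the ~10× shifts seen for genuinely impaired
  variants.
- Recovery-study conditions: k_on = 10³ M⁻¹s⁻¹, k_off = 1.8×10⁻² s⁻¹
  (K_D = 18 μM, in the weak-micromolar regime typical of this system),
  R_max = 1 nm, five concentrations 5–80 μM spanning K_D, 60/30/100 s
  baseline/association/dissociation at 5 Hz, Gaussian noise as a fraction of
  R_max. Zero-noise fits recover parameters to machine precision; at 2%
  noise the K_D error stays within 10% in ≥90 of 100 seeded replicates.
  Experimentally measured K_D values are properties of the molecules, not of
  this software, and are never used as fit-validation truth.

## Numerical and degenerate-input choices

- All randomness flows from explicit seeds; pipeline stage seeds are derived
  from the single run seed by hashing, so runs are byte-reproducible and
  sub-streams are independent.
- Frequency tables must total 10⁶ CPM within 10⁻⁶ relative; landscapes
  enforce ΔE(WT) = 0 exactly.
- Superposition rejects < 3 points and collinear sets; reflections are
  excluded by construction (det = +1).
- Zero-variance landscapes (no spread across mutations) are an error for the
  selection rule rather than an empty result, since the rule is undefined.
- Toy-complex generation places each planted contact at an isolated site and
  verifies the realized contact map against the request before returning.

## Problem sizes used in the shipped checks

Full-scale recovery runs use the complete study geometry (211 positions,
4220 variants, two sub-libraries, two replicates, 300× depth, ≈5M reads);
unit tests use a 30-codon library and the same code paths. The Monte-Carlo
kinetics study uses 100 seeded replicates per noise level. These sizes are
the package defaults and are stated in the run reports.

## Known limitations

- The selection simulator is multiplicative and noiseless between
  generations; it cannot probe growth-rate nonlinearity, epistasis with
  expression level, or bottleneck variance.
- The fitness scale is arbitrary (unknown effective generations), so only
  rank and sign structure, not absolute ΔE, transfer to real data.
- No error-variance shrinkage or Bayesian scoring across variants; scores
  are per-cell maximum-likelihood ratios.
- The contact convention (heavy atoms, strict 4 Å) can shift deposited-model
  residue counts by a few residues relative to other reasonable conventions.
- Mass-transport limitation, heterogeneous-ligand and avidity effects are
  outside the 1:1 kinetic model; multivalent constructs need a different
  model, not a reparameterization of this one.
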