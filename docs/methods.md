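# Methods

This note documents the models behind `bsforge`, the conventions chosen where
the underlying biology is only characterised qualitatively, and what the
simulator does and does not establish.

## Chemistry model

Each molecule of a template is treated independently. For every cytosine the
simulator draws, in order: methylation status (from the template's
per-position probability), sulfonation (C → dhU6S, written `S`) with
probability `p_conv` if unmethylated, and desulphonation (S → U) with
probability `p_desulf`. Methylated cytosines are inert. After conversion,
every position acquires a blocking lesion (`X`) with probability `p_lesion`
and every phosphodiester bond breaks with probability `p_frag`; a molecule
whose amplicon span is interrupted by a break is not amplifiable. All events
are independent Bernoulli draws — no neighbour cooperativity is modelled
because none is characterised. Coordinates are 0-based half-open; only the
top strand is modelled, since bisulfite treatment makes the strands
non-complementary and amplicon analyses are strand-specific.

The two diastereoisomers of dhU6S are collapsed into the single state `S`;
whether both can template at all is an open question in the chemistry, and
the model does not guess.

### Condition presets

The named regimes are **calibration conventions**, not measured efficiencies:
the literature orders them by harshness but does not quantify them.

| name  | p_conv | p_desulf | p_lesion | p_frag | rationale |
|-------|--------|----------|----------|--------|-----------|
| BS1   | 0.99   | 0.99     | 0.001    | 0.001  | standard heat + pH 10.5: near-complete, damaging |
| BS1T  | 0.99   | 0.999    | 0.001    | 0.001  | BS1 plus extra heat |
| BS2   | 0.99   | 0.50     | 0        | 0      | no heat: substantially incomplete |
| BS3   | 0.99   | 0.95     | 0        | 0      | pH 11.5, no heat: nearly complete |
| WATER | 0.99   | 0.00     | 0        | 0      | no desulphonation control |

Damage probabilities are attached to the heated regimes only and are
deliberately mild (0.001/position ≈ 30% of 350-mers fragmented); published
degradation figures (up to ~96% input loss) describe whole-genome workflows
and are not reproduced here.

## Polymerase model

A profile assigns each non-canonical template state a per-encounter
read-through (bypass) probability; canonical bases always extend. Walking
the template 3′→5′, the effective bypass at an encounter is

    min(1, bypass[state] · penalty^run · (1 + k·ln(1 + t)))

where `run` counts consecutive U/S positions beyond the first of a
homopolymeric run, and `t` is the extension time in minutes. dA is inserted
opposite U and dhU6S (and, A-rule-like, opposite bypassed lesions), so on the
top-strand representation every bypassed non-canonical position copies as T.

Defaults are conventions calibrated to reproduce the qualitative
gel/qPCR contrasts (the source experiments report band patterns, not rates):

| parameter | Taq-like | 5D4-like |
|---|---|---|
| bypass U | 0.80 | 0.99 |
| bypass S (dhU6S) | 0.05 | 0.60 |
| bypass X (lesion) | 0.00 | 0.30 |
| homopolymer penalty | 0.85 | 0.99 |
| error/cycle | 4×10⁻⁵ | 1.5×10⁻⁴ |
| time factor k | 0.25 | 0.25 |

`k = 0.25` was chosen so that a 5–10 min first-cycle extension rescues the
Taq-like enzyme on uracil-rich (desulphonated) templates but never on
sulphonated ones, and so that blends amplify a fully sulphonated ~350 bp
29%-C amplicon only with the extended first cycle — the observed qualitative
pattern. The per-cycle error defaults are taken from measured cumulative
fidelities of the two enzyme classes in this assay family (0.2–0.4%/70
cycles for Taq, 0.8–1.2%/70 cycles for blends). Blends draw the acting
enzyme per molecule per cycle by weight; distributive polymerases re-bind
between events, and nothing finer is identifiable from blend-level data.

## PCR simulator

Molecule counts are propagated exactly: per cycle every treated template
yields a clean full-length copy with its closed-form full-length probability
(binomial draws over template counts), clean copies duplicate
deterministically, and the count trajectory is capped at a plateau
(default 10¹²) where synthesis — and hence error accrual — stops. Ct is the
fractional cycle at which the trajectory crosses a threshold (default 10⁹),
interpolated in log₂ space, so a tenfold input difference gives the textbook
ΔCt = log₂10 ≈ 3.32 exactly.

Sequence-level state is carried by a fixed-size pool of representative
molecules. Each slot tracks one uniformly random *lineage* of the product:
it is reassigned to a newly-born founder with the founders' current share of
the pool (low-variance systematic resampling over founder weights), and
otherwise independently undergoes a synthesis event with the new-copy share,
accruing substitution errors and incrementing its lineage synthesis count.
Because slots never copy from one another, the sample suffers no artificial
coalescent drift — the variance of, e.g., a CpG methylation fraction across
the final pool reflects only true founder sampling. Each lineage also
carries its accumulated per-base error probability, whose pool mean is the
analytic expectation of the cumulative error (`PcrRun.expected_error_fraction`);
under perfect doubling a random final molecule has experienced ≈ cycles/2
synthesis events, recovering the classic ε·k/2 cumulative error.

Nested PCR is modelled by `dilute()`: the representative pool (with its
errors and lineage statistics) carries into a fresh reaction at a reset
molecule count, so errors keep accruing across all 70 cycles of the default
20+30+20 schedule even though each stage plateaus.

Reads are sampled uniformly from the final pool, anchored at the amplicon
5′ end at fixed length (117–120 nt is typical for this assay class), with
flat substitution sequencing error and constant quality.

## Analysis

The reference is converted in silico (every C → T). Alignment scores
C→T-collapsed strings (match +1, mismatch −2, linear gap −3), global in the
read and local in the reference, banded (width 16) around the best seeded
diagonals; ties break to the leftmost placement; original read bases are
preserved for calling. Reads below 90% collapsed identity are counted and
excluded ("high-quality read" thresholds in this assay family are not
standardised; 90% is this package's convention). Since simulated reads are
5′-anchored and indel-free, a vectorised ungapped check at offset 0 serves
as a fast path; anything below 97% identity there falls back to the full
banded DP, which is property-tested against an exhaustive full-matrix DP.

Statistics and their exclusion rules:

- methylation fraction C/(C+T) per CpG cytosine; A/G observations counted
  as "other" and kept out of the denominator, so sequencing error is not
  conflated with methylation; sites under 10× depth are flagged, not
  dropped;
- conversion = T/(T+C) over non-CpG original-C positions only (returns an
  explicit undefined, never 0, when no eligible observation exists);
- error rate excludes C and T observations at original-C positions from
  numerator *and* denominator (A/G observations there still count as
  errors), making the statistic exactly invariant to injected C→T events;
  the per-base breakdown covers original G/A/T only;
- per-cycle rate = cumulative fraction / total cycles, with
  `rate × cycles == fraction` exact before display rounding (percentages
  display at 1 decimal, rates at 2 significant figures).

No hypothesis tests or multiple-testing corrections are applied: the
analysis is descriptive, as in the assay it models.

## Reproducibility

A single master seed expands via SHA-256 into named substreams (treatment,
pcr, reads), each folded with the amplicon name, so stages and amplicons are
independently reproducible: changing the reads seed leaves treatment output
byte-identical. All derived seeds are 31-bit.

## Simulation resolution

Two knobs trade fidelity for speed and are distinct from the biological
parameters: `n_distinct_molecules` (how many distinct treated molecules
represent the input pool; each carries `n_input_copies / n_distinct` copies)
and `max_reps` (the representative-pool size). Pipeline defaults
(500 / 4000) are adequate for qualitative work; the acceptance-level
parameter-recovery runs use 20,000 / 10,000 with 10⁶ input copies so that
simulator sampling noise (molecule-level methylation draws, founder
sampling) stays below read-sampling noise at 10⁴ depth. Input of ~10⁶
amplifiable copies matches the plasmid-scale inputs typical of the modelled
experiments.

## What a green test does not establish

The generator emulates conversion chemistry, enzyme stalling, blend
behaviour, per-cycle error and read sampling — it does not emulate
mispriming on the reduced three-letter alphabet, PCR bias between molecules
of different conversion states beyond their bypass probabilities,
strand-specific effects (bottom strand, CHH/CHG contexts), indel errors, or
quality-score structure. Parameter-recovery results therefore validate the
internal consistency of simulator and analysis and the correctness of the
statistics' implementations, not the accuracy of the convention-chosen rate
constants. The qualitative polymerase contrasts are asserted as directions
only, matching the resolution of the gel and qPCR evidence they echo.

## Known limitations

- The 0.62 kb / 152-C region cannot be amplified fully sulphonated under
  these conventions (per-molecule full-length probability ~10⁻⁹ even at
  10 min extension with bypass[S] = 0.6); the sulphonated-template
  behaviour is exercised on the ~350 bp / 101-C amplicon, for which the
  effect is observed experimentally as well.
- Once the trajectory plateaus, error accrual stops; cumulative error per
  cycle is therefore slightly protocol-dependent, which is physically
  reasonable but means the per-cycle statistic depends on the cycle
  schedule, not only on the enzyme.
- Treated templates continue converting during the resampled phase but
  their contribution is negligible by weight once the clean pool is large.
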