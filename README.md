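# bsforge

Simulation and analysis of targeted (amplicon) bisulfite sequencing, built
around an explicit model of what an engineered lesion-bypassing polymerase
changes in the workflow.

## The problem

Bisulfite treatment deaminates unmethylated cytosine to uracil through a
sulfonated intermediate, 5,6-dihydrouridine-6-sulfonate (dhU6S), while
5-methylcytosine (5mC) is protected — so surviving Cs in sequencing reads
report methylation. The catch is chemical: resolving dhU6S to uracil
(desulphonation) requires heat and strong base that damage and fragment the
DNA, while milder conditions leave dhU6S adducts that stall ordinary
polymerases such as Taq. Taq additionally struggles with uracil itself in
homopolymeric runs. Amplifying bisulfite-treated DNA is therefore lossy and
biased, which matters whenever input DNA is limiting.

`bsforge` models the whole chain as a stochastic simulator plus the standard
analysis:

1. **Chemistry** (`bsforge.chemistry`): per-molecule conversion
   C → S (dhU6S) → U with condition presets of graded harshness
   (`BS1`, `BS1T`, `BS2`, `BS3`, `WATER`), 5mC protection, blocking lesions
   and fragmentation; plus generators for the benchmark templates (a 20 nt
   mixed-run template, a 5′ dC₈ homopolymer, its dU₈ analogue) and synthetic
   CpG-bearing amplicons.
2. **Polymerases** (`bsforge.polymerase`): a Taq-like and a 5D4-like profile
   with per-state bypass probabilities (U, S, lesion), homopolymer stalling,
   an extension-time factor, per-cycle misincorporation, and weighted enzyme
   blends; primer-extension assays, qPCR with fractional Ct, nested PCR with
   dilution, and 5′-anchored Illumina-style read generation.
3. **Analysis** (`bsforge.analysis`): in-silico converted references,
   bisulfite-aware banded alignment (C→T-collapsed scoring, original bases
   kept for calling), pileups, per-CpG methylation fractions, the conversion
   statistic, and error rates with the bisulfite exclusion rules.
4. **Pipeline/CLI** (`bsforge.pipeline`, `bsforge.cli`): one config drives
   treatment → nested PCR (20+30+20 = 70 cycles by default) → reads →
   analysis, reproducibly from a single master seed.

## The statistics at the core

With a pileup of original read bases over reference positions, writing
$C_i, T_i$ for the C/T counts at position $i$:

- **Per-CpG methylation** at CpG cytosine $i$:
  $\hat m_i = C_i / (C_i + T_i)$ (A/G observations are reported separately).
- **Conversion efficiency** over non-CpG cytosines only (assumed
  unmethylated): $\mathrm{conv} = 100 \cdot \sum T_i / \sum (T_i + C_i)$.
- **Error rate**: mismatch fraction over all counted observations, where
  C and T observations at original-C positions are excluded entirely —
  a C→T there is conversion, a T→C is methylation/incomplete conversion,
  neither is a polymerase error. The per-nucleotide breakdown is reported
  for original G, A and T positions only. The per-cycle rate is the
  cumulative fraction divided by the total cycle count:
  $r = (\mathrm{err}/100) / N_\mathrm{cycles}$.

## Worked example

```python
import bsforge as bs

template = bs.make_amplicon_template(
    name="promoter", length=350, n_cpg=10, cpg_methylation=0.8, seed=17
)
config = bs.RunConfig(master_seed=11, condition="BS1", polymerase="5/1",
                      n_reads=10000, read_len=120)
result = bs.run_end_to_end(config, [template])
err = result.errors["promoter"]
print(f"conversion: {err.conversion_pct:.2f}%")
print(f"cumulative error: {err.overall_error_pct:.3f}% over {err.total_cycles} "
      f"cycles -> {err.per_cycle_rate:.1e}/cycle")
print(result.methylation["promoter"].table[["cpg_index", "pos0", "fraction"]].head(4))
```

prints

```
conversion: 98.88%
cumulative error: 0.300% over 70 cycles -> 4.3e-05/cycle
 cpg_index  pos0  fraction
         1    10  0.775807
         2    46  0.787366
         3    82  0.775043
         4   119  0.838506
```

Read it as: the `BS1` chemistry preset (99% sulfonation, 99% desulphonation)
yields ~98.9% measured conversion over non-CpG cytosines; a Taq/5D4 5/1
blend in the first PCR round followed by Taq-only nested rounds accumulates
0.30% substitutions over 70 cycles (4.3×10⁻⁵ per cycle); and the four CpGs
covered by 120 nt reads are recovered near their simulated 80% methylation.
Only the first four of the ten CpGs fall inside the 5′-anchored reads — the
remainder are flagged `low_depth`, not dropped.

The same pipeline runs from a shell:

```
bsforge run-all --template amplicons.fa --meth meth.tsv --seed 11 --out out/
bsforge analyze --ref amplicons.fa --reads out/promoter.reads.fastq --cycles 70 --out reanalysis/
```

## Acceptance script

`scripts/acceptance.py` re-runs the full pipeline from scratch — synthesises
a 350 bp amplicon with 10 CpGs at 80% methylation, treats it at a non-CpG
conversion probability of 0.995 with complete desulphonation, amplifies it
through the nested 70-cycle schedule with a 5/1 blend, samples 10,000 reads
of 120 nt, analyses them — and writes the measured conversion percentage as
JSON:

```
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

## Layout

```
src/bsforge/       chemistry.py  polymerase.py  analysis.py
                   pipeline.py   fileio.py      cli.py
tests/             unit + property + acceptance suites
docs/methods.md    model assumptions, parameter conventions, limitations
```
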