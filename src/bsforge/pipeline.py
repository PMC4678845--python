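"""End-to-end pipeline: treatment -> nested PCR -> reads -> analysis.

The default cycle schedule mirrors a two-round nested amplicon PCR followed
by an indexing PCR (20 + 30 + 20 = 70 cycles total); per-cycle fidelity is
reported against that total.  All randomness derives from one master seed
expanded into named substreams (treatment, pcr, reads), so each stage is
independently reproducible: changing the reads seed leaves treatment output
byte-identical.
"""

from __future__ import annotations

import json
import sys
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np

from . import __version__
from ._rng import substream_seed
from .analysis import (
    ErrorReport,
    MethylationReport,
    align_reads,
    build_pileup,
    cpg_methylation,
    error_rates,
    insilico_convert,
)
from .chemistry import CONDITIONS, MethylatedTemplate, TreatmentCondition, treat_pool
from .polymerase import BLENDS, P5D4, TAQ, Blend, PolymeraseProfile, dilute, generate_reads, run_pcr
from . import fileio

__all__ = ["RunConfig", "PipelineResult", "run_end_to_end", "resolve_polymerase"]


def resolve_polymerase(spec: str) -> Union[PolymeraseProfile, Blend]:
    """Resolve a profile/blend name: TAQ, P5D4, or a blend ratio like 5/1."""
    if spec.upper() == "TAQ":
        return TAQ
    if spec.upper() in ("P5D4", "5D4"):
        return P5D4
    if spec in BLENDS:
        return BLENDS[spec]
    raise ValueError(f"unknown polymerase/blend {spec!r} (try TAQ, P5D4, 10/1, 5/1, 1/1)")


@dataclass
class RunConfig:
    """Configuration of one end-to-end run.

    ``cycle_schedule`` is (first PCR, nested PCR, indexing PCR); its sum is
    the total cycle count used for the per-cycle fidelity statistic.
    Per-stage seeds default to substreams of ``master_seed`` and can be
    overridden individually.
    """

    master_seed: int = 0
    condition: str = "BS1"
    polymerase: str = "5/1"
    second_round_polymerase: str = "TAQ"
    cycle_schedule: Tuple[int, int, int] = (20, 30, 20)
    n_input_copies: float = 1e5
    n_distinct_molecules: int = 500
    carryover_copies: float = 1e5
    n_reads: int = 10000
    read_len: int = 120
    seq_error: float = 0.001
    ct_threshold: float = 1e9
    max_reps: int = 4000
    min_depth: int = 10
    min_identity: float = 0.9
    first_cycle_extension_min: float = 0.5
    extension_min: float = 0.5
    out_dir: Optional[str] = None
    custom_condition: Optional[TreatmentCondition] = None
    treatment_seed: Optional[int] = None
    pcr_seed: Optional[int] = None
    reads_seed: Optional[int] = None
    verbose: bool = False

    @property
    def total_cycles(self) -> int:
        return int(sum(self.cycle_schedule))

    def seed_for(self, stage: str) -> int:
        override = getattr(self, f"{stage}_seed", None)
        if override is not None:
            return int(override)
        return substream_seed(self.master_seed, stage)

    def resolve_condition(self) -> TreatmentCondition:
        if self.custom_condition is not None:
            return self.custom_condition
        if self.condition in CONDITIONS:
            return CONDITIONS[self.condition]
        raise ValueError(f"unknown condition {self.condition!r}")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["cycle_schedule"] = list(self.cycle_schedule)
        d["total_cycles"] = self.total_cycles
        if self.custom_condition is not None:
            d["custom_condition"] = asdict(self.custom_condition)
        return d


@dataclass
class PipelineResult:
    """All per-amplicon artifacts of one end-to-end run."""

    config: RunConfig
    treated: Dict[str, list]
    runs: Dict[str, list]
    reads: Dict[str, List[str]]
    methylation: Dict[str, MethylationReport]
    errors: Dict[str, Optional[ErrorReport]]
    align_stats: Dict[str, dict]

    def summary(self) -> dict:
        out: dict = {"total_cycles": self.config.total_cycles, "amplicons": {}}
        for name in self.reads:
            err = self.errors.get(name)
            meth = self.methylation.get(name)
            out["amplicons"][name] = {
                "n_reads": len(self.reads[name]),
                "align": self.align_stats.get(name, {}),
                "conversion_pct": err.conversion_pct if err else None,
                "overall_error_pct": err.overall_error_pct if err else None,
                "per_cycle_rate": err.per_cycle_rate if err else None,
                "global_methylation": (
                    meth.global_mean if meth is not None else None
                ),
                "ct": [r.ct for r in self.runs[name]],
            }
        return out


def _log(cfg: RunConfig, stage: str, msg: str) -> None:
    if cfg.verbose:
        print(f"[{stage}] {msg}", file=sys.stderr)


def run_end_to_end(
    config: RunConfig,
    templates: Sequence[MethylatedTemplate],
) -> PipelineResult:
    """Execute treatment -> nested PCR -> read generation -> analysis.

    Deterministic for a fixed config: running twice produces identical
    artifacts.  A template that fails to amplify (e.g. fully sulphonated DNA
    with a Taq-only reaction) yields zero reads and an analysis section that
    reports no aligned reads rather than an error.
    """
    cond = config.resolve_condition()
    pol1 = resolve_polymerase(config.polymerase)
    pol2 = resolve_polymerase(config.second_round_polymerase)
    c1, c2, c3 = config.cycle_schedule

    treated: Dict[str, list] = {}
    runs: Dict[str, list] = {}
    reads: Dict[str, List[str]] = {}
    methylation: Dict[str, MethylationReport] = {}
    errors: Dict[str, Optional[ErrorReport]] = {}
    align_stats: Dict[str, dict] = {}

    for template in templates:
        tseed = substream_seed(config.seed_for("treatment"), template.name)
        pool = treat_pool(template, cond, config.n_distinct_molecules, seed=tseed)
        per_count = config.n_input_copies / config.n_distinct_molecules
        treated[template.name] = pool
        _log(config, "treatment", f"{template.name}: {len(pool)} molecules ({cond.name})")

        pseed = substream_seed(config.seed_for("pcr"), template.name)
        prng = np.random.default_rng(pseed)
        stage_runs = []
        stage_pool = [(s, per_count) for s in pool]
        for stage_idx, (cycles, pol) in enumerate(
            [(c1, pol1), (c2, pol2), (c3, pol2)]
        ):
            if cycles == 0:
                continue
            run = run_pcr(
                stage_pool,
                pol,
                cycles=cycles,
                first_cycle_extension_min=(
                    config.first_cycle_extension_min if stage_idx == 0 else config.extension_min
                ),
                extension_min=config.extension_min,
                threshold=config.ct_threshold,
                max_reps=config.max_reps,
                rng=prng,
            )
            stage_runs.append(run)
            _log(
                config,
                "pcr",
                f"{template.name} stage {stage_idx + 1}: ct={run.ct} "
                f"final={run.copies_per_cycle[-1]:.3g}",
            )
            stage_pool = dilute(run, config.carryover_copies)
            if not stage_pool:
                break
        runs[template.name] = stage_runs

        rseed = substream_seed(config.seed_for("reads"), template.name)
        final_run = stage_runs[-1]
        amp_reads = generate_reads(
            final_run,
            n_reads=config.n_reads,
            read_len=min(config.read_len, max(final_run.amplicon_len, 1)),
            seq_error=config.seq_error,
            seed=rseed,
        ) if final_run.rep_seqs.shape[0] else []
        reads[template.name] = amp_reads
        _log(config, "reads", f"{template.name}: {len(amp_reads)} reads")

        ref = insilico_convert(template.seq, name=template.name)
        alignments, stats = align_reads(
            amp_reads, ref, min_identity=config.min_identity
        )
        align_stats[template.name] = stats
        pile = build_pileup(alignments, ref)
        methylation[template.name] = cpg_methylation(pile, min_depth=config.min_depth)
        errors[template.name] = (
            error_rates(pile, total_cycles=config.total_cycles)
            if stats["n_aligned"]
            else None
        )
        _log(config, "analysis", f"{template.name}: aligned {stats['n_aligned']}")

    result = PipelineResult(
        config=config,
        treated=treated,
        runs=runs,
        reads=reads,
        methylation=methylation,
        errors=errors,
        align_stats=align_stats,
    )
    if config.out_dir:
        _write_bundle(result, Path(config.out_dir))
    return result


def _write_bundle(result: PipelineResult, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    cfg = result.config
    for name, pool in result.treated.items():
        fileio.write_treated_fasta(out / f"{name}.treated.fa", pool)
        fileio.write_fragments_tsv(out / f"{name}.fragments.tsv", pool)
    for name, stage_runs in result.runs.items():
        fileio.write_json(
            out / f"{name}.pcr.json", [r.to_dict() for r in stage_runs]
        )
    for name, rds in result.reads.items():
        fileio.write_fastq(out / f"{name}.reads.fastq", rds, prefix=name)
    for name, meth in result.methylation.items():
        fileio.write_methylation_tsv(out / f"{name}.methylation.tsv", name, meth)
    for name, err in result.errors.items():
        if err is not None:
            fileio.write_error_tsv(out / f"{name}.errors.tsv", name, err)
    fileio.write_json(out / "summary.json", result.summary())
    fileio.write_json(
        out / "provenance.json",
        {
            "config": cfg.to_dict(),
            "version": __version__,
            "seeds": {
                stage: cfg.seed_for(stage) for stage in ("treatment", "pcr", "reads")
            },
        },
    )
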