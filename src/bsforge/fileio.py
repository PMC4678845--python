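"""Readers and writers for the pipeline's on-disk formats.

FASTA/FASTQ go through Bio.SeqIO; tabular sidecars (methylation annotations,
fragment intervals, report tables) are TSV via pandas.  Treated strands are
serialised as FASTA over the seven-letter state alphabet plus a BED-like
fragments TSV (0-based, half-open).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Dict, Iterable, List, Sequence, Tuple

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .analysis import ErrorReport, MethylationReport
from .chemistry import MethylatedTemplate, TreatedStrand, find_cpg_sites

__all__ = [
    "read_template_fasta",
    "write_template_fasta",
    "read_meth_tsv",
    "write_meth_tsv",
    "write_treated_fasta",
    "read_treated_fasta",
    "write_fragments_tsv",
    "write_fastq",
    "read_fastq",
    "write_methylation_tsv",
    "write_error_tsv",
    "write_json",
]


def read_template_fasta(path, meth_path=None) -> List[MethylatedTemplate]:
    """Load amplicon templates from FASTA, with an optional methylation TSV
    sidecar (columns: template, pos, state) giving per-cytosine annotations."""
    meth_by_template: Dict[str, Dict[int, float]] = {}
    if meth_path is not None:
        meth_by_template = read_meth_tsv(meth_path)
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        meth = meth_by_template.get(rec.id, {})
        out.append(
            MethylatedTemplate(
                name=rec.id,
                seq=seq,
                meth=meth,
                cpg_sites=tuple(find_cpg_sites(seq)),
            )
        )
    return out


def write_template_fasta(path, templates: Sequence[MethylatedTemplate]) -> None:
    records = [
        SeqRecord(Seq(t.seq), id=t.name, description="") for t in templates
    ]
    SeqIO.write(records, str(path), "fasta")


def read_meth_tsv(path) -> Dict[str, Dict[int, float]]:
    df = pd.read_csv(path, sep="\t")
    out: Dict[str, Dict[int, float]] = {}
    for _, row in df.iterrows():
        out.setdefault(str(row["template"]), {})[int(row["pos"])] = float(row["state"])
    return out


def write_meth_tsv(path, templates: Sequence[MethylatedTemplate]) -> None:
    rows = [
        {"template": t.name, "pos": p, "state": v}
        for t in templates
        for p, v in sorted(t.meth.items())
    ]
    pd.DataFrame(rows, columns=["template", "pos", "state"]).to_csv(
        path, sep="\t", index=False
    )


def write_treated_fasta(path, strands: Sequence[TreatedStrand]) -> None:
    """Treated strands as FASTA over {A,C,G,T,U,S,X}."""
    with open(path, "w") as fh:
        for i, s in enumerate(strands):
            fh.write(f">{s.source}|molecule_{i}\n{s.states}\n")


def read_treated_fasta(path) -> List[TreatedStrand]:
    out = []
    name, buf = None, []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith(">"):
                if name is not None:
                    out.append(TreatedStrand(states="".join(buf), source=name))
                name = line[1:].split("|")[0]
                buf = []
            elif line:
                buf.append(line)
    if name is not None:
        out.append(TreatedStrand(states="".join(buf), source=name))
    return out


def write_fragments_tsv(path, strands: Sequence[TreatedStrand]) -> None:
    rows = [
        {"molecule": i, "start": a, "end": b}
        for i, s in enumerate(strands)
        for a, b in s.fragments
    ]
    pd.DataFrame(rows, columns=["molecule", "start", "end"]).to_csv(
        path, sep="\t", index=False
    )


def write_fastq(path, reads: Sequence[str], prefix: str = "read", qual: str = "I") -> None:
    """Standard 4-line FASTQ records with constant Phred+33 quality."""
    with open(path, "w") as fh:
        for i, seq in enumerate(reads):
            fh.write(f"@{prefix}_{i:06d}\n{seq}\n+\n{qual * len(seq)}\n")


def read_fastq(path) -> List[str]:
    return [str(rec.seq) for rec in SeqIO.parse(str(path), "fastq")]


def write_methylation_tsv(path, amplicon: str, report: MethylationReport) -> None:
    df = report.table.copy()
    df.insert(0, "amplicon", amplicon)
    df.to_csv(path, sep="\t", index=False)


def write_error_tsv(path, amplicon: str, report: ErrorReport) -> None:
    row = {
        "amplicon": amplicon,
        "conversion_pct": report.conversion_pct,
        "overall_error_pct": report.overall_error_pct,
        "errA": report.per_base_error.get("A"),
        "errG": report.per_base_error.get("G"),
        "errT": report.per_base_error.get("T"),
        "per_cycle_rate": report.per_cycle_rate,
        "total_cycles": report.total_cycles,
    }
    pd.DataFrame([row]).to_csv(path, sep="\t", index=False)


def write_json(path, obj) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
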