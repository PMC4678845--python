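"""Bisulfite chemistry on methylated DNA templates.

Sodium bisulfite sulfonates unmethylated cytosine to 5,6-dihydrouridine-6-
sulfonate (state ``S``), which a subsequent desulphonation step resolves to
uracil (state ``U``); 5-methylcytosine is protected and stays ``C``.  Harsh
desulphonation regimes additionally damage the DNA (blocking lesions, state
``X``, and strand fragmentation).  This module simulates that chemistry on a
per-molecule basis and builds the synthetic benchmark templates used to
characterise polymerase read-through (a 20 nt mixed-run template T1, a 5'
dC8 homopolymer template T2, and its pre-made dU8 analogue T3).

All coordinates are 0-based, half-open.  Only the top strand is modelled:
bisulfite treatment makes the strands non-complementary and every analysis
downstream is amplicon/strand specific.

Per-position events are independent Bernoulli draws; for a fixed seed the
draw order is: one uniform per cytosine for methylation status, one per
cytosine for sulfonation, one per cytosine for desulphonation, then one per
position for lesions and one per phosphodiester bond for fragmentation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Tuple, Union

import numpy as np

__all__ = [
    "MethylatedTemplate",
    "TreatmentCondition",
    "TreatedStrand",
    "CONDITIONS",
    "find_cpg_sites",
    "apply_bisulfite",
    "treat_pool",
    "make_benchmark_template",
    "make_amplicon_template",
    "validate_benchmark",
]

_DNA = frozenset("ACGT")
_STATES = frozenset("ACGTUSX")


def find_cpg_sites(seq: str) -> List[int]:
    """0-based positions of the C in every CpG dinucleotide (top strand)."""
    return [i for i in range(len(seq) - 1) if seq[i] == "C" and seq[i + 1] == "G"]


def _normalise_meth(value) -> float:
    if isinstance(value, str):
        if value == "methylated":
            return 1.0
        if value == "unmethylated":
            return 0.0
        raise ValueError(f"unknown methylation state {value!r}")
    p = float(value)
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"methylation probability {p} outside [0, 1]")
    return p


@dataclass(frozen=True)
class MethylatedTemplate:
    """A DNA sequence with per-cytosine methylation annotations.

    ``meth`` maps a 0-based cytosine position to its methylation probability
    (the strings ``"methylated"``/``"unmethylated"`` are accepted and
    normalised to 1.0/0.0).  Cytosines absent from ``meth`` are unmethylated,
    matching the assumption behind the conversion-efficiency statistic that
    non-CpG cytosines carry no methylation.
    """

    name: str
    seq: str
    meth: Dict[int, float] = field(default_factory=dict)
    cpg_sites: Tuple[int, ...] = ()

    def __post_init__(self):
        bad = sorted(set(self.seq) - _DNA)
        if bad:
            raise ValueError(
                f"template {self.name!r}: non-ACGT characters {bad} in sequence"
            )
        norm = {int(p): _normalise_meth(v) for p, v in self.meth.items()}
        for p in norm:
            if not (0 <= p < len(self.seq)) or self.seq[p] != "C":
                raise ValueError(
                    f"template {self.name!r}: methylation key {p} does not index a C"
                )
        object.__setattr__(self, "meth", norm)
        cpg = tuple(int(p) for p in self.cpg_sites)
        for p in cpg:
            if p + 1 >= len(self.seq) or self.seq[p] != "C" or self.seq[p + 1] != "G":
                raise ValueError(f"template {self.name!r}: {p} is not a CpG cytosine")
        object.__setattr__(self, "cpg_sites", cpg)

    @classmethod
    def from_seq(
        cls,
        name: str,
        seq: str,
        cpg_methylation: float = 0.0,
        non_cpg_methylation: float = 0.0,
    ) -> "MethylatedTemplate":
        """Build a template, auto-detecting CpG sites.

        ``cpg_methylation`` is the methylation probability given to every CpG
        cytosine, ``non_cpg_methylation`` to every other cytosine (default 0:
        the generator defaults non-CpG cytosines to unmethylated).
        """
        cpg = find_cpg_sites(seq)
        cpg_set = set(cpg)
        meth = {
            i: (cpg_methylation if i in cpg_set else non_cpg_methylation)
            for i, b in enumerate(seq)
            if b == "C"
        }
        return cls(name=name, seq=seq, meth=meth, cpg_sites=tuple(cpg))

    @property
    def c_positions(self) -> List[int]:
        return [i for i, b in enumerate(self.seq) if b == "C"]


@dataclass(frozen=True)
class TreatmentCondition:
    """A bisulfite treatment / desulphonation regime.

    p_conv   -- probability a reactive (unmethylated) C is sulfonated to S
    p_desulf -- probability a sulfonated position is resolved S -> U
    p_lesion -- per-position probability of a blocking lesion (X)
    p_frag   -- per-phosphodiester probability of strand breakage
    """

    name: str
    p_conv: float
    p_desulf: float
    p_lesion: float = 0.0
    p_frag: float = 0.0

    def __post_init__(self):
        for attr in ("p_conv", "p_desulf", "p_lesion", "p_frag"):
            v = getattr(self, attr)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"condition {self.name!r}: {attr}={v} outside [0, 1]")
        if self.name == "WATER" and self.p_desulf != 0.0:
            raise ValueError("WATER condition must have p_desulf = 0")


#: Named desulphonation regimes.  Efficiencies are calibration conventions
#: reproducing the qualitative harshness ordering (BS1T >= BS1 > BS3 > BS2;
#: WATER performs no desulphonation at all); the heated regimes (BS1, BS1T)
#: also damage the DNA.
CONDITIONS: Dict[str, TreatmentCondition] = {
    "BS1": TreatmentCondition("BS1", 0.99, 0.99, p_lesion=0.001, p_frag=0.001),
    "BS1T": TreatmentCondition("BS1T", 0.99, 0.999, p_lesion=0.001, p_frag=0.001),
    "BS2": TreatmentCondition("BS2", 0.99, 0.50),
    "BS3": TreatmentCondition("BS3", 0.99, 0.95),
    "WATER": TreatmentCondition("WATER", 0.99, 0.0),
}


@dataclass(frozen=True)
class TreatedStrand:
    """Per-position chemical states of one treated molecule.

    ``states`` is a string over {A,C,G,T,U,S,X} of the same length as the
    source sequence; ``fragments`` lists the 0-based half-open intervals that
    survived fragmentation (a single full-length interval when intact).
    """

    states: str
    source: str
    fragments: Tuple[Tuple[int, int], ...] = ()

    def __post_init__(self):
        bad = sorted(set(self.states) - _STATES)
        if bad:
            raise ValueError(f"treated strand: invalid state characters {bad}")
        frags = tuple((int(a), int(b)) for a, b in self.fragments) or (
            (0, len(self.states)),
        )
        prev_end = 0
        for a, b in frags:
            if not (0 <= a < b <= len(self.states)) or a < prev_end:
                raise ValueError(f"invalid fragment intervals {frags}")
            prev_end = b
        object.__setattr__(self, "fragments", frags)

    @property
    def intact(self) -> bool:
        """True when a single fragment spans the whole molecule."""
        return self.fragments == ((0, len(self.states)),)

    def clean_copy_seq(self) -> str:
        """The sequence of a successful full-length polymerase copy.

        dA is inserted opposite U, S (read-through) and bypassed lesions, so
        on the top-strand representation those positions read as T; intact
        (methylated or unconverted) C stays C.
        """
        table = str.maketrans("USX", "TTT")
        return self.states.translate(table)


def apply_bisulfite(
    template: MethylatedTemplate,
    cond: TreatmentCondition,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> TreatedStrand:
    """Treat a single molecule of ``template`` under ``cond``.

    Each unmethylated C independently sulfonates to S with ``p_conv`` and each
    S resolves to U with ``p_desulf``; methylated Cs stay C.  Lesions (X) are
    applied after conversion to any position with ``p_lesion``; fragmentation
    breaks each phosphodiester with ``p_frag``.  Deterministic for a fixed
    seed.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    n = len(template.seq)
    states = np.array(list(template.seq))

    c_pos = np.array(template.c_positions, dtype=np.int64)
    if c_pos.size:
        meth_p = np.array([template.meth.get(int(p), 0.0) for p in c_pos])
        is_meth = rng.random(c_pos.size) < meth_p
        sulfonated = (~is_meth) & (rng.random(c_pos.size) < cond.p_conv)
        desulfonated = sulfonated & (rng.random(c_pos.size) < cond.p_desulf)
        states[c_pos[sulfonated & ~desulfonated]] = "S"
        states[c_pos[desulfonated]] = "U"

    if cond.p_lesion > 0 and n:
        lesions = rng.random(n) < cond.p_lesion
        states[lesions] = "X"

    fragments: List[Tuple[int, int]] = []
    if cond.p_frag > 0 and n > 1:
        breaks = np.flatnonzero(rng.random(n - 1) < cond.p_frag)
        start = 0
        for b in breaks:
            fragments.append((start, int(b) + 1))
            start = int(b) + 1
        fragments.append((start, n))
    else:
        fragments.append((0, n))

    return TreatedStrand(
        states="".join(states), source=template.name, fragments=tuple(fragments)
    )


def treat_pool(
    template: MethylatedTemplate,
    cond: TreatmentCondition,
    n_molecules: int,
    seed: int | None = None,
) -> List[TreatedStrand]:
    """Treat ``n_molecules`` independent molecules of the same template."""
    if n_molecules < 1:
        raise ValueError("n_molecules must be >= 1")
    rng = np.random.default_rng(seed)
    return [apply_bisulfite(template, cond, rng=rng) for _ in range(n_molecules)]


# ---------------------------------------------------------------------------
# Benchmark templates

_T1_RUNS = (3, 2, 1, 1, 1)  # one triplet, one duplet, three singletons


def _random_c_free(rng: np.random.Generator, length: int, no_leading_g: bool = False) -> str:
    """A C-free stretch over {A,G,T}; optionally not starting with G (so a
    preceding C does not become a CpG)."""
    bases = rng.choice(list("AGT"), size=length)
    if no_leading_g and length and bases[0] == "G":
        bases[0] = rng.choice(["A", "T"])
    return "".join(bases)


def make_benchmark_template(
    kind: str,
    length: int | None = None,
    n_c: int | None = None,
    primer_len: int | None = None,
    seed: int = 0,
) -> Union[MethylatedTemplate, TreatedStrand]:
    """Build one of the polymerase-characterisation templates.

    T1: 20 nt, 8 Cs (40%) arranged as three singletons, one dC2 duplet and one
    dC3 triplet, with a C-free 3' primer-binding region.
    T2: a 5' dC8 homopolymer followed by a C-free primer region.
    T3: T2 with the dC8 run replaced by dU8, returned as a pre-treated
    TreatedStrand (the synthetic uracil template needs no chemistry).
    custom: ``length`` and ``n_c`` cytosines at seeded random positions.
    """
    rng = np.random.default_rng(seed)
    kind = kind.upper() if kind.lower() != "custom" else "custom"
    if kind == "T1":
        runs = list(_T1_RUNS)
        rng.shuffle(runs)
        parts: List[str] = []
        for i, r in enumerate(runs):
            parts.append("C" * r)
            if i < len(runs) - 1:
                parts.append(str(rng.choice(["A", "T"])))  # separator, never G
        variable = "".join(parts)  # 8 Cs + 4 separators = 12 nt
        primer = _random_c_free(rng, 20 - len(variable), no_leading_g=True)
        seq = variable + primer
        return MethylatedTemplate.from_seq("T1", seq)
    if kind in ("T2", "T3"):
        plen = 12 if primer_len is None else primer_len
        primer = _random_c_free(rng, plen, no_leading_g=True)
        if kind == "T2":
            return MethylatedTemplate.from_seq("T2", "C" * 8 + primer)
        return TreatedStrand(states="U" * 8 + primer, source="T3")
    if kind == "custom":
        if length is None or n_c is None:
            raise ValueError("custom templates need length and n_c")
        if not 0 <= n_c <= length:
            raise ValueError(f"cannot place {n_c} Cs in {length} nt")
        seq = list(_random_c_free(rng, length))
        if n_c:
            pos = rng.choice(length, size=n_c, replace=False)
            for p in pos:
                seq[p] = "C"
        return MethylatedTemplate.from_seq("custom", "".join(seq))
    raise ValueError(f"unknown template kind {kind!r}")


def make_amplicon_template(
    name: str = "amplicon",
    length: int = 350,
    n_cpg: int = 10,
    c_fraction: float = 0.25,
    cpg_methylation: float = 0.8,
    seed: int = 0,
) -> MethylatedTemplate:
    """Synthesise an amplicon with an exact number of CpG sites.

    The background is drawn at the requested cytosine fraction with accidental
    CpGs removed, then ``n_cpg`` CG dinucleotides are placed evenly through
    the interior.  CpG cytosines receive ``cpg_methylation``; all other
    cytosines are unmethylated (the assumption the conversion statistic
    rests on).  Defaults emulate a high-C human promoter amplicon.
    """
    if length < 2 * n_cpg + 20:
        raise ValueError("amplicon too short for the requested CpG count")
    rng = np.random.default_rng(seed)
    other = (1.0 - c_fraction) / 3.0
    seq = list(rng.choice(list("ACGT"), size=length, p=[other, c_fraction, other, other]))
    for i in range(length - 1):  # strip accidental CpGs
        if seq[i] == "C" and seq[i + 1] == "G":
            seq[i + 1] = rng.choice(["A", "T"])
    if n_cpg:
        sites = np.linspace(10, length - 12, n_cpg).astype(int)
        for p in sites:
            seq[p], seq[p + 1] = "C", "G"
    template = MethylatedTemplate.from_seq(
        name, "".join(seq), cpg_methylation=cpg_methylation
    )
    if len(template.cpg_sites) != n_cpg:
        raise AssertionError("CpG placement failed")  # pragma: no cover
    return template


def _c_runs(seq: str) -> List[int]:
    runs, cur = [], 0
    for b in seq:
        if b == "C":
            cur += 1
        elif cur:
            runs.append(cur)
            cur = 0
    if cur:
        runs.append(cur)
    return runs


def validate_benchmark(template: MethylatedTemplate, primer_len: int = 8) -> dict:
    """Re-scan a benchmark template and report its composition.

    Returns C count, C fraction, the multiset of C run lengths and whether the
    3' ``primer_len`` bases are C-free.
    """
    seq = template.seq
    count = seq.count("C")
    return {
        "c_count": count,
        "c_fraction": count / len(seq) if seq else 0.0,
        "run_lengths": sorted(_c_runs(seq)),
        "primer_c_free": "C" not in seq[len(seq) - primer_len:],
    }
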