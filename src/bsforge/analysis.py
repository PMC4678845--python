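"""Amplicon bisulfite sequencing analysis.

The workflow mirrors the standard targeted bisulfite pipeline: the amplicon
reference is bisulfite-converted in silico (every C -> T), reads are aligned
bisulfite-aware (both read and reference collapsed C -> T for scoring, the
original read bases retained for calling), base counts are accumulated into a
pileup, and from the pileup come

* per-CpG methylation fractions (C / (C + T) at each CpG cytosine),
* the conversion efficiency statistic, computed over non-CpG cytosines only
  (non-CpG Cs are assumed unmethylated, so any C observation there reports
  incomplete conversion),
* substitution error rates with the bisulfite exclusion rules: C -> T events
  at original-C positions are never counted as errors (they are
  indistinguishable from conversion), and the per-nucleotide breakdown is
  reported only for original G, A and T positions.

Cumulative error divided by the total number of PCR cycles gives the
per-cycle fidelity estimate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, NamedTuple, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .chemistry import find_cpg_sites

__all__ = [
    "ConvertedReference",
    "Alignment",
    "Pileup",
    "MethylationReport",
    "ErrorReport",
    "CContent",
    "LocusSummary",
    "insilico_convert",
    "align_bisulfite",
    "align_reads",
    "build_pileup",
    "cpg_methylation",
    "conversion_rate",
    "error_rates",
    "c_content",
    "locus_success_summary",
    "locus_union_summary",
]

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
_BASES = "ACGT"

MATCH, MISMATCH, GAP = 1, -2, -3
DEFAULT_BAND = 16

_COLLAPSE = str.maketrans("C", "T")


def _collapse(seq: str) -> str:
    """Three-letter collapse: C -> T (the bisulfite-aware scoring alphabet)."""
    return seq.translate(_COLLAPSE)


@dataclass(frozen=True)
class ConvertedReference:
    """An amplicon reference and its in-silico bisulfite-converted image."""

    name: str
    original: str
    converted: str
    cpg_sites: Tuple[int, ...]

    def __post_init__(self):
        if len(self.original) != len(self.converted):
            raise ValueError("original/converted length mismatch")


def insilico_convert(amplicon: str, name: str = "ref") -> ConvertedReference:
    """Bisulfite-convert a reference in silico (every C -> T).

    CpG positions are recorded from the original so methylation can still be
    called there; ambiguity codes are rejected with a position report.
    """
    bad = [(i, b) for i, b in enumerate(amplicon) if b not in _BASE_INDEX]
    if bad:
        raise ValueError(f"non-ACGT characters at positions {bad[:10]}")
    return ConvertedReference(
        name=name,
        original=amplicon,
        converted=_collapse(amplicon),
        cpg_sites=tuple(find_cpg_sites(amplicon)),
    )


@dataclass
class Alignment:
    """Placement of one read on a converted reference.

    ``pairs`` lists (read_index, ref_index) for aligned (non-gap) columns;
    ``offset`` is the reference index of the first aligned read base.
    """

    read: str
    offset: int
    pairs: List[Tuple[int, int]]
    score: int
    collapsed_identity: float


def _ungapped_candidates(read_c: str, ref_c: str, top: int = 3) -> List[int]:
    """Best ungapped offsets by collapsed match count (seed diagonals)."""
    n, L = len(read_c), len(ref_c)
    if n > L:
        return [0]
    scores = []
    read_arr = np.frombuffer(read_c.encode(), dtype=np.uint8)
    ref_arr = np.frombuffer(ref_c.encode(), dtype=np.uint8)
    for off in range(L - n + 1):
        scores.append(int((read_arr == ref_arr[off : off + n]).sum()))
    order = np.argsort(scores, kind="stable")[::-1]
    return [int(o) for o in order[:top]]


def align_bisulfite(
    read: str,
    ref: ConvertedReference,
    band: int = DEFAULT_BAND,
) -> Alignment:
    """Banded bisulfite-aware alignment of one read.

    Global in the read, local in the reference; scoring on the C->T-collapsed
    strings (match +1, mismatch -2, linear gap -3) within a band of width
    ``band`` around the best-seeded diagonals.  Ties are broken toward the
    leftmost reference placement.  Original read bases are preserved in the
    returned pairing for base calling.
    """
    if not read:
        raise ValueError("empty read")
    if len(read) > len(ref.converted):
        raise ValueError("read longer than reference")
    read_c = _collapse(read)
    ref_c = ref.converted  # already C-free
    best: Optional[Alignment] = None
    for diag in _ungapped_candidates(read_c, ref_c):
        aln = _banded_dp(read, read_c, ref_c, diag, band)
        if best is None or aln.score > best.score or (
            aln.score == best.score and aln.offset < best.offset
        ):
            best = aln
    assert best is not None
    return best


def _banded_dp(
    read: str, read_c: str, ref_c: str, diag: int, band: int
) -> Alignment:
    """Semi-global DP restricted to |j - (i + diag)| <= band."""
    n, L = len(read_c), len(ref_c)
    NEG = -(10**9)
    # H[i][j]: best score of read[:i] aligned ending at ref[:j]
    H = np.full((n + 1, L + 1), NEG, dtype=np.int64)
    lo0 = max(0, diag - band)
    hi0 = min(L, diag + band)
    H[0, lo0 : hi0 + 1] = 0  # free reference start within band entry window
    for i in range(1, n + 1):
        lo = max(0, i + diag - band)
        hi = min(L, i + diag + band)
        for j in range(lo, hi + 1):
            s = NEG
            if j > 0 and H[i - 1, j - 1] > NEG:
                sub = MATCH if read_c[i - 1] == ref_c[j - 1] else MISMATCH
                s = H[i - 1, j - 1] + sub
            if H[i - 1, j] > NEG:  # read base against gap
                s = max(s, H[i - 1, j] + GAP)
            if j > 0 and H[i, j - 1] > NEG:  # reference base skipped (deletion)
                s = max(s, H[i, j - 1] + GAP)
            H[i, j] = s
    lo = max(0, n + diag - band)
    hi = min(L, n + diag + band)
    row = H[n, lo : hi + 1]
    end_j = lo + int(np.argmax(row))  # argmax takes first -> leftmost end
    score = int(H[n, end_j])

    # traceback: prefer diagonal, then read-gap (up), then ref-skip (left)
    pairs: List[Tuple[int, int]] = []
    i, j = n, end_j
    matches = 0
    while i > 0:
        if (
            j > 0
            and H[i - 1, j - 1] > NEG
            and H[i, j]
            == H[i - 1, j - 1]
            + (MATCH if read_c[i - 1] == ref_c[j - 1] else MISMATCH)
        ):
            pairs.append((i - 1, j - 1))
            if read_c[i - 1] == ref_c[j - 1]:
                matches += 1
            i, j = i - 1, j - 1
        elif H[i - 1, j] > NEG and H[i, j] == H[i - 1, j] + GAP:
            i -= 1
        else:
            j -= 1
    pairs.reverse()
    offset = pairs[0][1] if pairs else j
    identity = matches / len(read) if read else 0.0
    return Alignment(
        read=read, offset=offset, pairs=pairs, score=score,
        collapsed_identity=identity,
    )


def align_reads(
    reads: Sequence[str],
    ref: ConvertedReference,
    min_identity: float = 0.9,
    band: int = DEFAULT_BAND,
) -> Tuple[List[Alignment], Dict[str, int]]:
    """Align a batch of 5'-anchored amplicon reads with a quality filter.

    Reads whose collapsed identity at offset 0 is already near-perfect take a
    vectorised ungapped fast path (the generator anchors reads at the amplicon
    5' end); the rest go through the banded DP.  Reads below ``min_identity``
    collapsed identity are counted and dropped, not silently ignored.
    """
    stats = {"n_reads": len(reads), "n_aligned": 0, "n_filtered": 0}
    out: List[Alignment] = []
    ref_c = ref.converted
    for read in reads:
        n = len(read)
        if n <= len(ref_c):
            read_c = _collapse(read)
            mism = sum(a != b for a, b in zip(read_c, ref_c[:n]))
            identity = 1.0 - mism / n
            if identity >= max(min_identity, 0.97):
                out.append(
                    Alignment(
                        read=read,
                        offset=0,
                        pairs=[(i, i) for i in range(n)],
                        score=(n - mism) * MATCH + mism * MISMATCH,
                        collapsed_identity=identity,
                    )
                )
                stats["n_aligned"] += 1
                continue
        aln = align_bisulfite(read, ref, band=band)
        if aln.collapsed_identity >= min_identity:
            out.append(aln)
            stats["n_aligned"] += 1
        else:
            stats["n_filtered"] += 1
    return out, stats


@dataclass
class Pileup:
    """Per-reference-position base counts from aligned reads.

    ``counts`` is (L, 4) over A/C/G/T of the reads' original (uncollapsed)
    bases; each position also carries the original (untreated) reference base
    and CpG membership.
    """

    ref: ConvertedReference
    counts: np.ndarray

    def __post_init__(self):
        if self.counts.shape != (len(self.ref.original), 4):
            raise ValueError("counts shape mismatch")

    @property
    def depth(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def original(self) -> np.ndarray:
        return np.array(list(self.ref.original))

    @property
    def is_cpg(self) -> np.ndarray:
        mask = np.zeros(len(self.ref.original), dtype=bool)
        mask[list(self.ref.cpg_sites)] = True
        return mask

    def merge(self, other: "Pileup") -> "Pileup":
        if other.ref.original != self.ref.original:
            raise ValueError("pileups built against different references")
        return Pileup(ref=self.ref, counts=self.counts + other.counts)


def build_pileup(alignments: Iterable[Alignment], ref: ConvertedReference) -> Pileup:
    """Accumulate original read bases into per-position counts.

    Gap columns contribute nothing; depth equals the column sum exactly.
    """
    L = len(ref.original)
    counts = np.zeros((L, 4), dtype=np.int64)
    fast_rows: List[np.ndarray] = []
    for aln in alignments:
        read_codes = np.frombuffer(aln.read.encode(), dtype=np.uint8)
        n = len(aln.read)
        if aln.offset == 0 and len(aln.pairs) == n and aln.pairs[-1] == (n - 1, n - 1):
            fast_rows.append(read_codes)
            continue
        for ri, fj in aln.pairs:
            if not 0 <= fj < L:
                raise ValueError("alignment out of reference bounds")
            counts[fj, _BASE_INDEX[aln.read[ri]]] += 1
    # vectorised path for offset-0 full-length ungapped alignments
    code_of = np.zeros(256, dtype=np.int64)
    for b, i in _BASE_INDEX.items():
        code_of[ord(b)] = i
    for row in fast_rows:
        idx = code_of[row]
        counts[np.arange(len(row)), idx] += 1
    return Pileup(ref=ref, counts=counts)


@dataclass
class MethylationReport:
    """Per-CpG methylation fractions and the global weighted mean.

    ``table`` columns: cpg_index (1-based from the amplicon 5' end), pos0,
    meth_count (C), unmeth_count (T), other (A/G, excluded from the fraction),
    fraction, low_depth flag.  Low-depth sites are flagged, never dropped.
    """

    table: pd.DataFrame
    global_mean: float
    min_depth: int

    @property
    def n_sites(self) -> int:
        return len(self.table)


def cpg_methylation(pileup: Pileup, min_depth: int = 10) -> MethylationReport:
    """Call per-CpG methylation from a pileup.

    At each CpG cytosine the methylated count is the C observations and the
    unmethylated count the T observations; A/G observations are reported as
    "other" and excluded from the fraction denominator.  The global mean is
    the (C+T)-weighted mean over sites.
    """
    rows = []
    for k, pos in enumerate(pileup.ref.cpg_sites, start=1):
        c = int(pileup.counts[pos, _BASE_INDEX["C"]])
        t = int(pileup.counts[pos, _BASE_INDEX["T"]])
        other = int(pileup.counts[pos].sum() - c - t)
        denom = c + t
        rows.append(
            {
                "cpg_index": k,
                "pos0": pos,
                "meth_count": c,
                "unmeth_count": t,
                "other": other,
                "fraction": (c / denom) if denom else np.nan,
                "low_depth": denom < min_depth,
            }
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "cpg_index",
            "pos0",
            "meth_count",
            "unmeth_count",
            "other",
            "fraction",
            "low_depth",
        ],
    )
    total = table["meth_count"].sum() + table["unmeth_count"].sum()
    global_mean = float(table["meth_count"].sum() / total) if total else np.nan
    return MethylationReport(table=table, global_mean=global_mean, min_depth=min_depth)


def conversion_rate(pileup: Pileup) -> Optional[float]:
    """Bisulfite conversion efficiency in percent.

    100 * T / (T + C) aggregated over all non-CpG original-C positions; CpG
    positions contribute nothing.  Returns None (explicitly undefined, not 0)
    when no eligible observation exists.
    """
    mask = (pileup.original == "C") & ~pileup.is_cpg
    t = int(pileup.counts[mask, _BASE_INDEX["T"]].sum())
    c = int(pileup.counts[mask, _BASE_INDEX["C"]].sum())
    if t + c == 0:
        return None
    return 100.0 * t / (t + c)


@dataclass
class ErrorReport:
    """Conversion and substitution-error statistics of one amplicon.

    All percentages are on [0, 100]; ``per_cycle_rate`` is the overall error
    *fraction* divided by ``total_cycles`` (so per_cycle_rate * total_cycles
    reproduces the cumulative fraction exactly, before any display rounding).
    """

    conversion_pct: Optional[float]
    overall_error_pct: float
    per_base_error: Dict[str, float]
    per_cycle_rate: float
    total_cycles: int
    n_observations: int


def error_rates(pileup: Pileup, total_cycles: int) -> ErrorReport:
    """Substitution error rates with the bisulfite exclusion rules.

    At original-C positions both C and T observations are excluded entirely
    (conversion and methylation make them uninterpretable as errors); A/G
    observations there still count as errors.  The per-nucleotide breakdown is
    computed only at original G, A and T positions — original Ts only, since
    conversion cannot create a T at a genomic T by construction.
    """
    if total_cycles < 1:
        raise ValueError("total_cycles must be >= 1")
    original = pileup.original
    counts = pileup.counts
    depth = pileup.depth

    errors = 0
    observations = 0
    per_base: Dict[str, float] = {}
    for base in "GAT":
        mask = original == base
        obs = int(depth[mask].sum())
        err = int(obs - counts[mask, _BASE_INDEX[base]].sum())
        per_base[base] = 100.0 * err / obs if obs else 0.0
        errors += err
        observations += obs
    c_mask = original == "C"
    c_err = int(
        counts[c_mask, _BASE_INDEX["A"]].sum() + counts[c_mask, _BASE_INDEX["G"]].sum()
    )
    errors += c_err
    observations += c_err  # C/T observations at original-C positions excluded

    overall_pct = 100.0 * errors / observations if observations else 0.0
    return ErrorReport(
        conversion_pct=conversion_rate(pileup),
        overall_error_pct=overall_pct,
        per_base_error=per_base,
        per_cycle_rate=(overall_pct / 100.0) / total_cycles,
        total_cycles=total_cycles,
        n_observations=observations,
    )


class CContent(NamedTuple):
    count: int
    pct: float

    @property
    def pct_rounded(self) -> float:
        return round(self.pct, 1)


def c_content(seq: str, window: Optional[Tuple[int, int]] = None) -> CContent:
    """Cytosine count and percentage of a sequence (or 0-based half-open
    window).  The raw percentage is returned; display rounding is 1 decimal."""
    if not seq:
        raise ValueError("empty sequence")
    if window is not None:
        a, b = window
        seq = seq[a:b]
        if not seq:
            raise ValueError("empty window")
    count = seq.count("C")
    return CContent(count=count, pct=100.0 * count / len(seq))


class LocusSummary(NamedTuple):
    successes: int
    total: int
    fraction: float
    percent: float  # rounded to 1 decimal


def locus_success_summary(outcomes: Sequence[bool]) -> LocusSummary:
    """Fraction and percent of loci successfully amplified."""
    if not len(outcomes):
        raise ValueError("need at least one outcome")
    s = int(sum(bool(o) for o in outcomes))
    n = len(outcomes)
    return LocusSummary(s, n, s / n, round(100.0 * s / n, 1))


def locus_union_summary(per_blend: Dict[str, Sequence[bool]]) -> LocusSummary:
    """Union success across blends: a locus counts if any blend amplified it."""
    if not per_blend:
        raise ValueError("need at least one blend")
    lengths = {len(v) for v in per_blend.values()}
    if len(lengths) != 1:
        raise ValueError("blends report different locus counts")
    union = [any(v[i] for v in per_blend.values()) for i in range(lengths.pop())]
    return locus_success_summary(union)
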