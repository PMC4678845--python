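"""Polymerase models: primer extension, PCR/qPCR and read generation.

Two enzyme archetypes are parameterised: a Taq-like polymerase, which stalls
at template uracil (especially in homopolymeric runs) and cannot pass the
sulfonate intermediate dhU6S or blocking lesions, and a 5D4-like engineered
polymerase, which reads through uracil essentially freely and bypasses dhU6S
and lesions at useful rates.  Both insert dA opposite U and dhU6S, so on the
top-strand representation a bypassed position copies as T.  Blends of the two
enzymes model mixed reactions; the acting enzyme is drawn per molecule per
cycle by blend weight (distributive polymerases re-bind between events).

The PCR simulator tracks molecule counts exactly (binomial/deterministic
trajectories up to a plateau cap) while sequence-level diversity is carried by
a fixed-size representative pool resampled each cycle with its genealogy
(synthesis counts, accumulated error probability and substitution errors
travel with each lineage), so a 70-cycle amplification to 1e9+ molecules runs
in seconds and still yields reads with a realistic per-lineage error
distribution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np

from .chemistry import TreatedStrand

__all__ = [
    "PolymeraseProfile",
    "Blend",
    "ExtensionResult",
    "PcrRun",
    "TAQ",
    "P5D4",
    "BLENDS",
    "full_length_probability",
    "extend_primer",
    "run_pcr",
    "dilute",
    "generate_reads",
]

# base coding used for amplicon matrices
_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}
_BASES = np.array(list("ACGT"))
_ENCODE_TABLE = np.zeros(256, dtype=np.uint8)
for _b, _c in _CODE.items():
    _ENCODE_TABLE[ord(_b)] = _c

# seven-letter treated-state coding (A C G T U S X -> 0..6)
_STATE_ORDER = "ACGTUSX"
_STATE_TABLE = np.zeros(256, dtype=np.uint8)
for _i, _b in enumerate(_STATE_ORDER):
    _STATE_TABLE[ord(_b)] = _i
# clean-copy image of each state in 4-letter coding (U/S/X copy as T)
_CLEAN_IMAGE = np.array([0, 1, 2, 3, 3, 3, 3], dtype=np.uint8)


def encode_seq(seq: str) -> np.ndarray:
    return _ENCODE_TABLE[np.frombuffer(seq.encode(), dtype=np.uint8)].copy()


def decode_seq(codes: np.ndarray) -> str:
    return "".join(_BASES[codes])


def _encode_states(states: str) -> np.ndarray:
    return _STATE_TABLE[np.frombuffer(states.encode(), dtype=np.uint8)].copy()


@dataclass(frozen=True)
class PolymeraseProfile:
    """Per-template-state read-through behaviour of one enzyme.

    bypass               -- per-encounter read-through probability for U, S
                            (dhU6S) and X (lesion); canonical bases are 1.0.
    homopolymer_penalty  -- multiplier applied per additional consecutive U/S
                            beyond the first in a run.
    time_base, time_k    -- extension-time factor: bypass probabilities are
                            multiplied by time_base + time_k*ln(1+minutes)
                            and clamped to [0, 1].
    error_per_cycle      -- substitution probability per incorporated base per
                            copying event (uniform over the 3 alternatives).
    insert_opposite      -- base inserted opposite each non-canonical state on
                            read-through (dA opposite U and dhU6S).
    """

    name: str
    bypass: Dict[str, float]
    homopolymer_penalty: float
    error_per_cycle: float
    time_base: float = 1.0
    time_k: float = 0.25
    insert_opposite: Dict[str, str] = field(
        default_factory=lambda: {"U": "A", "S": "A", "X": "A"}
    )

    def __post_init__(self):
        for state in "USX":
            p = self.bypass.get(state)
            if p is None or not 0.0 <= p <= 1.0:
                raise ValueError(f"profile {self.name!r}: bypass[{state}] invalid")
        if not 0.0 < self.homopolymer_penalty <= 1.0:
            raise ValueError("homopolymer_penalty must be in (0, 1]")
        if not 0.0 <= self.error_per_cycle <= 1.0:
            raise ValueError("error_per_cycle must be in [0, 1]")
        if self.insert_opposite.get("U") != "A" or self.insert_opposite.get("S") != "A":
            raise ValueError("dA must be inserted opposite template U and dhU6S")

    def time_multiplier(self, time_min: float) -> float:
        return self.time_base + self.time_k * math.log1p(time_min)

    def effective_bypass(self, state: str, run_index: int, time_min: float) -> float:
        """Read-through probability at one encounter (clamped to [0, 1])."""
        p = (
            self.bypass[state]
            * self.homopolymer_penalty**run_index
            * self.time_multiplier(time_min)
        )
        return min(1.0, max(0.0, p))


#: Taq-like preset: stalls in dU runs, essentially blocked by dhU6S/lesions.
TAQ = PolymeraseProfile(
    name="TAQ",
    bypass={"U": 0.80, "S": 0.05, "X": 0.0},
    homopolymer_penalty=0.85,
    error_per_cycle=4e-5,
)

#: 5D4-like preset: near-free dU read-through, useful dhU6S/lesion bypass,
#: higher misincorporation.
P5D4 = PolymeraseProfile(
    name="P5D4",
    bypass={"U": 0.99, "S": 0.60, "X": 0.30},
    homopolymer_penalty=0.99,
    error_per_cycle=1.5e-4,
)


@dataclass(frozen=True)
class Blend:
    """A weighted mixture of polymerases acting in one reaction."""

    components: Tuple[Tuple[PolymeraseProfile, float], ...]
    name: str = "blend"

    def __post_init__(self):
        if not self.components:
            raise ValueError("blend needs at least one component")
        total = sum(w for _, w in self.components)
        if total <= 0 or any(w <= 0 for _, w in self.components):
            raise ValueError("blend weights must be positive")
        object.__setattr__(
            self,
            "components",
            tuple((p, w / total) for p, w in self.components),
        )

    @property
    def profiles(self) -> List[PolymeraseProfile]:
        return [p for p, _ in self.components]

    @property
    def weights(self) -> np.ndarray:
        return np.array([w for _, w in self.components])

    @property
    def mean_error_per_cycle(self) -> float:
        return float(sum(w * p.error_per_cycle for p, w in self.components))


def _as_blend(pol: Union[PolymeraseProfile, Blend]) -> Blend:
    if isinstance(pol, Blend):
        return pol
    return Blend(components=((pol, 1.0),), name=pol.name)


#: Taq/5D4 blend presets at the ratios characterised on gels and by qPCR.
BLENDS: Dict[str, Blend] = {
    "10/1": Blend(((TAQ, 10.0), (P5D4, 1.0)), name="TAQ/5D4 10/1"),
    "5/1": Blend(((TAQ, 5.0), (P5D4, 1.0)), name="TAQ/5D4 5/1"),
    "1/1": Blend(((TAQ, 1.0), (P5D4, 1.0)), name="TAQ/5D4 1/1"),
}


def _obstacles(states: str, primer_len: int = 0) -> List[Tuple[int, str, int]]:
    """(position, state, run_index) for each U/S/X encounter, in the order the
    polymerase meets them walking the template 3'->5' (string end to start).

    ``run_index`` counts consecutive U/S positions beyond the first of a run;
    lesions (X) carry no homopolymer penalty and break a U/S run.
    """
    start = len(states) - primer_len - 1
    out: List[Tuple[int, str, int]] = []
    run = 0
    prev_pos: Optional[int] = None
    for pos in range(start, -1, -1):
        s = states[pos]
        if s in "US":
            if prev_pos is not None and prev_pos == pos + 1:
                run += 1
            else:
                run = 0
            out.append((pos, s, run))
            prev_pos = pos
        elif s == "X":
            out.append((pos, s, 0))
            prev_pos = None
            run = 0
        else:
            prev_pos = None
            run = 0
    return out


def full_length_probability(
    strand: Union[TreatedStrand, str],
    profile: PolymeraseProfile,
    time_min: float,
    primer_len: int = 0,
) -> float:
    """Closed-form probability of a full-length copy (product over encounters)."""
    states = strand.states if isinstance(strand, TreatedStrand) else strand
    p = 1.0
    for _, state, run in _obstacles(states, primer_len):
        p *= profile.effective_bypass(state, run, time_min)
    return p


def pool_full_length_probabilities(
    states_mat: np.ndarray, profile: PolymeraseProfile, time_min: float
) -> np.ndarray:
    """Vectorised :func:`full_length_probability` over a (n, L) state matrix
    in the seven-letter coding; walks columns 3'->5' accumulating log bypass
    with the same homopolymer run indexing as the scalar path."""
    n, L = states_mat.shape
    m = profile.time_multiplier(time_min)
    bU, bS = profile.bypass["U"], profile.bypass["S"]
    effX = min(1.0, max(0.0, profile.bypass["X"] * m))
    pen = profile.homopolymer_penalty
    logp = np.zeros(n)
    blocked = np.zeros(n, dtype=bool)
    run = np.zeros(n, dtype=np.int64)
    tiny = 1e-300
    for j in range(L - 1, -1, -1):
        col = states_mat[:, j]
        is_u = col == 4
        is_s = col == 5
        is_x = col == 6
        is_us = is_u | is_s
        if is_us.any() or is_x.any():
            pen_pow = pen**run
            eff = np.ones(n)
            np.minimum(bU * pen_pow * m, 1.0, out=eff, where=is_u)
            np.minimum(bS * pen_pow * m, 1.0, out=eff, where=is_s)
            eff[is_x] = effX
            hit = is_us | is_x
            blocked |= hit & (eff <= 0.0)
            logp += np.where(hit, np.log(np.maximum(eff, tiny)), 0.0)
        run = np.where(is_us, run + 1, 0)
    p = np.exp(logp)
    p[blocked] = 0.0
    return p


def _systematic_choice(weights: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """Low-variance (systematic) categorical sampling of k indices."""
    cdf = np.cumsum(weights)
    cdf[-1] = 1.0
    u = (rng.random() + np.arange(k)) / k
    return np.searchsorted(cdf, u, side="right")


@dataclass
class ExtensionResult:
    """Outcome of a primer-extension assay over n molecules."""

    product_lengths: np.ndarray  # nt synthesised beyond the primer, one per molecule
    full_length: int
    n: int

    @property
    def full_length_fraction(self) -> float:
        return self.full_length / self.n


def extend_primer(
    strand: TreatedStrand,
    pol: Union[PolymeraseProfile, Blend],
    time_min: float,
    n: int,
    seed: int | None = None,
    primer_len: int = 0,
) -> ExtensionResult:
    """Simulate primer extension of ``n`` molecules on one treated template.

    Each molecule walks the template from the primer toward the 5' end and at
    every U/S/X encounter terminates with probability 1 - effective bypass;
    blends draw the acting enzyme per molecule by weight.  A common uniform is
    drawn per (molecule, encounter) so that equally seeded runs of two
    profiles are coupled (the pointwise better enzyme dominates exactly).
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if time_min <= 0:
        raise ValueError("time_min must be > 0")
    rng = np.random.default_rng(seed)
    blend = _as_blend(pol)
    obs = _obstacles(strand.states, primer_len)
    span = len(strand.states) - primer_len
    which = rng.choice(len(blend.profiles), size=n, p=blend.weights)
    if not obs:
        return ExtensionResult(np.full(n, span), full_length=n, n=n)

    eff = np.array(
        [
            [p.effective_bypass(state, run, time_min) for _, state, run in obs]
            for p in blend.profiles
        ]
    )  # (profiles, encounters)
    u = rng.random((n, len(obs)))
    survive = u < eff[which]
    failed_any = ~survive.all(axis=1)
    first_fail = np.where(failed_any, np.argmax(~survive, axis=1), -1)

    start = len(strand.states) - primer_len - 1
    positions = np.array([pos for pos, _, _ in obs])
    lengths = np.full(n, span, dtype=np.int64)
    if failed_any.any():
        # terminated before incorporating opposite the blocking position
        lengths[failed_any] = start - positions[first_fail[failed_any]]
    return ExtensionResult(lengths, full_length=int((~failed_any).sum()), n=n)


@dataclass
class PcrRun:
    """State and trajectory of a simulated PCR.

    ``copies_per_cycle`` holds the amplifiable molecule count after each cycle
    (treated templates plus clean copies); ``ct`` is the fractional cycle at
    which the count crosses the detection threshold (None if never).  The
    representative pool (``rep_seqs``, ``rep_synth``, ``rep_errp``) carries
    the sequence, lineage-synthesis-count and accumulated per-base error
    probability sample that reads are drawn from.
    """

    cycles: int
    copies_per_cycle: List[float]
    ct: Optional[float]
    first_cycle_extension_min: float
    amplicon_len: int
    n_clean: float
    n_templates: float
    rep_seqs: np.ndarray  # (R, L) uint8 base codes; R may be 0
    rep_synth: np.ndarray  # (R,) lineage synthesis counts
    rep_errp: np.ndarray  # (R,) accumulated per-base error probability

    @property
    def mean_synth(self) -> float:
        """Mean number of synthesis events in a sampled molecule's lineage."""
        return float(self.rep_synth.mean()) if self.rep_synth.size else 0.0

    def expected_error_fraction(self) -> float:
        """Analytic expectation of the cumulative per-base error fraction of a
        sampled amplicon molecule (before sequencing error)."""
        return float(self.rep_errp.mean()) if self.rep_errp.size else 0.0

    def to_dict(self) -> dict:
        return {
            "cycles": self.cycles,
            "copies_per_cycle": [float(x) for x in self.copies_per_cycle],
            "ct": self.ct,
            "first_cycle_extension_min": self.first_cycle_extension_min,
            "amplicon_len": self.amplicon_len,
            "n_clean": self.n_clean,
            "mean_synth": self.mean_synth,
            "expected_error_fraction": self.expected_error_fraction(),
        }


def _apply_copy_errors(
    seqs: np.ndarray, eps: np.ndarray, rng: np.random.Generator
) -> None:
    """In-place substitution errors on newly synthesised copies; ``eps`` is
    the per-base error probability per row, uniform over the 3 alternatives."""
    if seqs.size == 0:
        return
    L = seqs.shape[1]
    n_err = rng.binomial(L, eps)
    rows = np.flatnonzero(n_err)
    for r in rows:
        pos = rng.integers(0, L, size=n_err[r])
        seqs[r, pos] = (seqs[r, pos] + rng.integers(1, 4, size=n_err[r])) % 4


def _normalise_pool(pool: Sequence):
    strands: List[TreatedStrand] = []
    counts: List[float] = []
    synth0: List[int] = []
    errp0: List[float] = []
    for item in pool:
        if isinstance(item, TreatedStrand):
            strands.append(item)
            counts.append(1.0)
            synth0.append(0)
            errp0.append(0.0)
        else:
            item = tuple(item)
            strands.append(item[0])
            counts.append(float(item[1]))
            synth0.append(int(item[2]) if len(item) > 2 else 0)
            errp0.append(float(item[3]) if len(item) > 3 else 0.0)
    return strands, np.array(counts), np.array(synth0), np.array(errp0)


def run_pcr(
    strand_pool: Sequence,
    pol: Union[PolymeraseProfile, Blend],
    cycles: int,
    first_cycle_extension_min: float = 0.5,
    extension_min: float = 0.5,
    seed: int | None = None,
    threshold: float = 1e9,
    cap: float = 1e12,
    max_reps: int = 4000,
    rng: np.random.Generator | None = None,
) -> PcrRun:
    """PCR-amplify a pool of treated strands.

    ``strand_pool`` is a sequence of TreatedStrand or tuples
    ``(TreatedStrand, count[, prior_synth, prior_errp])`` (the tuple form is
    how :func:`dilute` chains nested PCRs).  Per cycle every treated template
    yields a clean full-length copy with its profile-and-time-dependent
    full-length probability (blend enzyme drawn per molecule), clean copies
    duplicate, and every new copy accrues substitution errors at the acting
    enzyme's per-cycle rate.  The count trajectory is capped at ``cap``
    (plateau: synthesis, and hence error accrual, stops); Ct is interpolated
    on a log2 scale against ``threshold``.  A zero-input pool yields a valid
    run with an absent Ct.
    """
    if cycles < 1:
        raise ValueError("cycles must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    blend = _as_blend(pol)
    strands, counts, synth0, errp0 = _normalise_pool(strand_pool)

    amplifiable = [i for i, s in enumerate(strands) if s.intact]
    L = len(strands[0].states) if strands else 0
    if amplifiable:
        states_mat = np.stack([_encode_states(strands[i].states) for i in amplifiable])
        clean_images = _CLEAN_IMAGE[states_mat]
        t_counts = counts[amplifiable]
        t_synth = synth0[amplifiable]
        t_errp = errp0[amplifiable]
    else:
        states_mat = np.zeros((0, L), dtype=np.uint8)
        clean_images = np.zeros((0, L), dtype=np.uint8)
        t_counts = np.zeros(0)
        t_synth = np.zeros(0, dtype=np.int64)
        t_errp = np.zeros(0)
    n_templates = float(t_counts.sum())

    def pbar(time_min: float) -> np.ndarray:
        """Per-template mean full-length probability under the blend."""
        if not amplifiable:
            return np.zeros(0)
        return sum(
            w * pool_full_length_probabilities(states_mat, p, time_min)
            for p, w in blend.components
        )

    p_first = pbar(first_cycle_extension_min)
    p_later = pbar(extension_min)

    comp_eps = np.array([p.error_per_cycle for p in blend.profiles])
    weights = blend.weights

    def draw_eps(k: int) -> np.ndarray:
        which = rng.choice(len(comp_eps), size=k, p=weights)
        return comp_eps[which]

    rep_seqs = np.zeros((0, L), dtype=np.uint8)
    rep_synth = np.zeros(0, dtype=np.int64)
    rep_errp = np.zeros(0)
    n_clean = 0.0
    trajectory: List[float] = []

    for c in range(1, cycles + 1):
        p_i = p_first if c == 1 else p_later
        if len(amplifiable):
            born = rng.binomial(np.round(t_counts).astype(np.int64), p_i)
        else:
            born = np.zeros(0, dtype=np.int64)
        B = float(born.sum())
        at_cap = n_clean >= cap
        n_new_copies = 0.0 if at_cap else n_clean  # efficiency 1 on clean DNA
        n_next = min(cap, n_clean + n_new_copies + B)

        if n_next > 0 and (B > 0 or rep_seqs.shape[0] > 0):
            # Each representative slot tracks one uniformly random lineage of
            # the product pool: it is reassigned to a newly-born founder with
            # the founders' share of the pool, and otherwise independently
            # follows a synthesis event with the new-copy share.  Slots never
            # copy from each other, so the sample carries no coalescent drift
            # beyond the true founder sampling.
            R_next = int(min(max_reps, round(n_next)))
            total = n_clean + n_new_copies + B
            f_born = B / total
            f_new = (
                n_new_copies / (n_clean + n_new_copies)
                if (n_clean + n_new_copies) > 0
                else 0.0
            )
            if rep_seqs.shape[0] == 0:
                f_born = 1.0
            if B == 0:
                R_next = rep_seqs.shape[0]  # no new founders: keep sample size
            if rep_seqs.shape[0] < R_next:
                pad = R_next - rep_seqs.shape[0]
                rep_seqs = np.vstack([rep_seqs, np.zeros((pad, L), dtype=np.uint8)])
                rep_synth = np.concatenate([rep_synth, np.zeros(pad, dtype=np.int64)])
                rep_errp = np.concatenate([rep_errp, np.zeros(pad)])
                is_born = np.ones(R_next, dtype=bool)
                is_born[: R_next - pad] = rng.random(R_next - pad) < f_born
            else:
                is_born = rng.random(R_next) < f_born

            k_born = int(is_born.sum())
            if k_born and B > 0:
                ti = _systematic_choice(born / B, k_born, rng)
                eps = draw_eps(k_born)
                rep_seqs[is_born] = clean_images[ti]
                rep_synth[is_born] = t_synth[ti] + 1
                rep_errp[is_born] = 1.0 - (1.0 - t_errp[ti]) * (1.0 - eps)
                fresh = rep_seqs[is_born]
                _apply_copy_errors(fresh, eps, rng)
                rep_seqs[is_born] = fresh

            walk = (~is_born) & (rng.random(R_next) < f_new)
            k_walk = int(walk.sum())
            if k_walk:
                eps = draw_eps(k_walk)
                rep_synth[walk] += 1
                rep_errp[walk] = 1.0 - (1.0 - rep_errp[walk]) * (1.0 - eps)
                sub = rep_seqs[walk]
                _apply_copy_errors(sub, eps, rng)
                rep_seqs[walk] = sub

        n_clean = n_next
        trajectory.append(n_templates + n_clean)

    ct = _threshold_cycle([n_templates] + trajectory, threshold)
    return PcrRun(
        cycles=cycles,
        copies_per_cycle=trajectory,
        ct=ct,
        first_cycle_extension_min=first_cycle_extension_min,
        amplicon_len=L,
        n_clean=n_clean,
        n_templates=n_templates,
        rep_seqs=rep_seqs,
        rep_synth=rep_synth,
        rep_errp=rep_errp,
    )


def _threshold_cycle(totals: List[float], threshold: float) -> Optional[float]:
    """Fractional cycle at which ``totals`` (index 0 = cycle 0) crosses
    ``threshold``, interpolated in log2 space."""
    for c in range(1, len(totals)):
        if totals[c] >= threshold:
            prev = totals[c - 1]
            if prev <= 0 or totals[c] == prev:
                return float(c)
            frac = (math.log2(threshold) - math.log2(prev)) / (
                math.log2(totals[c]) - math.log2(prev)
            )
            return c - 1 + max(0.0, min(1.0, frac))
    return None


def dilute(run: PcrRun, carryover_copies: float) -> List:
    """Model transferring an aliquot of a finished PCR into a fresh reaction.

    The representative pool is kept (it is already an unbiased sample of the
    product, with its accumulated errors and lineage statistics) and the
    molecule count reset to ``carryover_copies``; returns a strand pool usable
    as input to :func:`run_pcr`.
    """
    R = run.rep_seqs.shape[0]
    if R == 0:
        return []
    per = carryover_copies / R
    return [
        (
            TreatedStrand(states=decode_seq(run.rep_seqs[i]), source="carryover"),
            per,
            int(run.rep_synth[i]),
            float(run.rep_errp[i]),
        )
        for i in range(R)
    ]


def generate_reads(
    run: PcrRun,
    n_reads: int,
    read_len: int,
    seq_error: float,
    seed: int | None = None,
) -> List[str]:
    """Sample fixed-length 5'-anchored reads from the final amplicon pool.

    Reads are drawn uniformly from the representative molecules, truncated to
    ``read_len`` from the amplicon 5' end, and given flat substitution
    sequencing errors at ``seq_error``.  Returns read sequences (an empty list
    when the run produced no amplicons).
    """
    if n_reads < 1:
        raise ValueError("n_reads must be >= 1")
    if run.rep_seqs.shape[0] == 0:
        return []
    if read_len > run.amplicon_len:
        raise ValueError(
            f"read_len {read_len} exceeds amplicon length {run.amplicon_len}"
        )
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, run.rep_seqs.shape[0], size=n_reads)
    mat = run.rep_seqs[idx, :read_len].copy()
    if seq_error > 0:
        mask = rng.random(mat.shape) < seq_error
        k = int(mask.sum())
        if k:
            mat[mask] = (mat[mask] + rng.integers(1, 4, size=k)) % 4
    return [decode_seq(row) for row in mat]
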