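"""Junction-anchored primer pair enumeration with nearest-neighbor thermodynamics.

Melting temperatures come from the unified nearest-neighbor model
(Allawi & SantaLucia 1997 dinucleotide parameters) with the single-salt
entropy correction ``dS += 0.368 (N-1) ln[Na+eq]`` and a duplex-concentration
term, matching the standard short-oligo treatment.  Dimer and hairpin checks
use an ungapped complementarity alignment (+1 match / -1 mismatch, maximised
over all offsets) — a deterministic, brute-force-verifiable contract rather
than full duplex folding.

Candidate enumeration is exhaustive over the junction-anchored window: in
``span`` mode exactly one primer of each pair crosses the junction with at
least ``junction_overlap_5p``/``junction_overlap_3p`` bases on either side;
in ``flank`` mode the junction lies strictly between the two 3' ends.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field, replace

from .transcript_model import reverse_complement

__all__ = [
    "DesignParams",
    "PrimerCandidate",
    "PrimerPair",
    "DesignResult",
    "melting_temperature",
    "gc_fraction",
    "interaction_score",
    "hairpin_score",
    "pair_penalty",
    "generate_pairs",
]

# Allawi & SantaLucia (1997) unified parameters: dH kcal/mol, dS cal/(mol K),
# keyed by the 5'->3' top-strand dinucleotide of the Watson-Crick duplex.
_NN = {
    "AA": (-7.9, -22.2), "AT": (-7.2, -20.4), "TA": (-7.2, -21.3),
    "CA": (-8.5, -22.7), "GT": (-8.4, -22.4), "CT": (-7.8, -21.0),
    "GA": (-8.2, -22.2), "CG": (-10.6, -27.2), "GC": (-9.8, -24.4),
    "GG": (-8.0, -19.9),
}
# fill the 10 -> 16 map: XY has the same duplex as revcomp(XY)
for _d in list(_NN):
    _NN.setdefault(reverse_complement(_d), _NN[_d])

_INIT_AT = (2.3, 4.1)   # terminal A·T penalty
_INIT_GC = (0.1, -2.8)  # terminal G·C initiation
_SYM_DS = -1.4          # self-complementary symmetry correction
_R = 1.987              # gas constant, cal/(mol K)

_COMP = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass(frozen=True)
class DesignParams:
    """Primer/amplicon constraints and thermodynamic conditions.

    Lengths in nt, temperatures in Celsius, GC as fractions, concentrations:
    ``monovalent_mM``/``divalent_mM``/``dntp_mM`` in mmol/L, ``oligo_nM`` the
    per-strand primer concentration in nmol/L.
    """

    primer_len: tuple[int, int, int] = (18, 20, 25)  # min, opt, max
    tm: tuple[float, float, float] = (59.0, 60.0, 62.0)
    gc: tuple[float, float] = (0.35, 0.65)
    min_amplicon: int = 70
    max_amplicon: int = 200
    junction_overlap_3p: int = 4
    junction_overlap_5p: int = 4
    mode: str = "span"
    max_pair_tm_diff: float = 2.0
    interaction_limit: int = 8      # reject any dimer/hairpin score >= this
    anchored_limit: int = 5         # reject 3'-anchored dimer score >= this
    max_candidates: int = 50
    monovalent_mM: float = 50.0
    divalent_mM: float = 0.0
    dntp_mM: float = 0.0
    oligo_nM: float = 500.0
    # penalty weights: degrees per nt of length deviation, per unit GC deviation
    w_len: float = 0.25
    w_gc: float = 5.0

    def __post_init__(self) -> None:
        for lo, opt, hi in (self.primer_len, self.tm):
            if not lo <= opt <= hi:
                raise ValueError("min <= opt <= max violated in DesignParams")
        if self.gc[0] > self.gc[1]:
            raise ValueError("gc window inverted")
        if self.min_amplicon <= 2 * self.primer_len[0]:
            raise ValueError("min_amplicon must exceed twice the minimal primer")
        if self.mode not in ("span", "flank"):
            raise ValueError(f"unknown mode {self.mode!r}")

    @property
    def gc_opt(self) -> float:
        return (self.gc[0] + self.gc[1]) / 2.0


def gc_fraction(seq: str) -> float:
    """(#G + #C) / length."""
    if not seq:
        raise ValueError("empty sequence")
    return (seq.count("G") + seq.count("C")) / len(seq)


def melting_temperature(seq: str, params: DesignParams | None = None) -> float:
    """Nearest-neighbor duplex melting temperature in Celsius.

    Assumes the primer and its perfect complement at equal concentration
    ``oligo_nM`` (CT/4 ~ oligo/2 in the duplex term); self-complementary
    sequences get the symmetry entropy correction and the full strand
    concentration.
    """
    params = params or DesignParams()
    if len(seq) < 2:
        raise ValueError(f"sequence too short for the NN model: {seq!r}")
    if any(base not in "ACGT" for base in seq):
        raise ValueError(f"sequence {seq!r} has letters outside A/C/G/T")
    dh = 0.0
    ds = 0.0
    for end in (seq[0], seq[-1]):
        inc = _INIT_AT if end in "AT" else _INIT_GC
        dh += inc[0]
        ds += inc[1]
    for i in range(len(seq) - 1):
        nn = _NN[seq[i : i + 2]]
        dh += nn[0]
        ds += nn[1]
    selfcomp = seq == reverse_complement(seq)
    if selfcomp:
        ds += _SYM_DS
    # von Ahsen monovalent-equivalent, then SantaLucia (1998) entropy term
    mon = params.monovalent_mM
    if params.divalent_mM > 0:
        mg_free = max(params.divalent_mM - params.dntp_mM, 0.0)
        mon += 120.0 * math.sqrt(mg_free)
    ds += 0.368 * (len(seq) - 1) * math.log(mon / 1000.0)
    duplex = params.oligo_nM * 1e-9 * (1.0 if selfcomp else 0.5)
    return 1000.0 * dh / (ds + _R * math.log(duplex)) - 273.15


def _alignment_scores(a: str, b_rev: str, pairs_ok) -> tuple[int, int]:
    """Best (overall, a-3'-anchored) ungapped alignment of a vs reversed b."""
    n, m = len(a), len(b_rev)
    best = 0
    best_anchored = 0
    # offset: index in b_rev aligned with a[0]; overlap >= 1
    for offset in range(-(n - 1), m):
        score = 0
        last_pair_has_a3 = False
        lo = max(0, -offset)
        hi = min(n, m - offset)
        if lo >= hi:
            continue
        for i in range(lo, hi):
            score += 1 if pairs_ok(a[i], b_rev[i + offset]) else -1
        best = max(best, score)
        if hi == n:  # a's 3' terminal base is inside the overlap
            best_anchored = max(best_anchored, score)
    return best, best_anchored


def interaction_score(a: str, b: str | None = None) -> tuple[int, int]:
    """Dimer complementarity of two primers (or a self-dimer when b is None).

    Returns ``(overall, anchored_3p)``: the maximum ungapped alignment score
    of ``a`` against ``reversed(b)`` under Watson-Crick pairing (+1 match,
    -1 mismatch, floor 0), and the same maximum restricted to alignments that
    cover ``a``'s 3' terminus.
    """
    if not a or (b is not None and not b):
        raise ValueError("empty primer sequence")
    b = a if b is None else b
    comp = lambda x, y: _COMP.get(x) == y
    return _alignment_scores(a, b[::-1], comp)


def hairpin_score(seq: str) -> int:
    """Best self-folding score with a minimum loop of 3 nt.

    For every fold diagonal ``i + j = k`` the positions ``i < j`` with
    ``j - i - 1 >= 3`` are scored +1 when s[i] pairs s[j], else -1; the
    maximum over diagonals (floored at 0) is returned.
    """
    if not seq:
        raise ValueError("empty sequence")
    n = len(seq)
    best = 0
    for k in range(n * 2 - 1):
        score = 0
        i_max = (k - 4) // 2  # enforces j - i - 1 >= 3 with j = k - i
        for i in range(max(0, k - n + 1), i_max + 1):
            j = k - i
            if j >= n:
                continue
            score += 1 if _COMP.get(seq[i]) == seq[j] else -1
        best = max(best, score)
    return best


@dataclass(frozen=True)
class PrimerCandidate:
    sequence: str          # 5'->3'
    role: str              # forward | reverse
    template_start: int    # leftmost cDNA offset of the binding window
    tm: float
    gc: float
    hairpin_score: int
    homodimer_score: int
    spans_junction: bool = False
    overlap_5p: int = 0    # bases before the junction boundary (primer 5' side)
    overlap_3p: int = 0    # bases past the junction boundary (primer 3' side)

    @property
    def length(self) -> int:
        return len(self.sequence)

    @property
    def template_end(self) -> int:
        return self.template_start + len(self.sequence)


@dataclass(frozen=True)
class PrimerPair:
    forward: PrimerCandidate
    reverse: PrimerCandidate
    amplicon_start: int
    amplicon_end: int
    heterodimer_score: int
    heterodimer_3p_score: int
    pair_penalty: float
    pair_id: str = ""

    @property
    def amplicon_len(self) -> int:
        return self.amplicon_end - self.amplicon_start

    def with_id(self, pair_id: str) -> "PrimerPair":
        return replace(self, pair_id=pair_id)


@dataclass
class DesignResult:
    pairs: list[PrimerPair]
    rejections: Counter = field(default_factory=Counter)


def pair_penalty(fwd: PrimerCandidate, rev: PrimerCandidate,
                 params: DesignParams) -> float:
    """Deviation of a pair from the optimum, in Tm-equivalent degrees.

    ``|Tm_f - opt| + |Tm_r - opt| + |Tm_f - Tm_r|`` plus weighted length and
    GC deviations from their optima; a pair at the exact optima scores 0.
    """
    opt_tm = params.tm[1]
    opt_len = params.primer_len[1]
    pen = abs(fwd.tm - opt_tm) + abs(rev.tm - opt_tm) + abs(fwd.tm - rev.tm)
    pen += params.w_len * (abs(fwd.length - opt_len) + abs(rev.length - opt_len))
    pen += params.w_gc * (abs(fwd.gc - params.gc_opt) + abs(rev.gc - params.gc_opt))
    return pen


def _window_checks(seq: str, params: DesignParams, reject: Counter):
    """Single-primer filters; returns (tm, gc, hairpin, homodimer) or None."""
    if "N" in seq:
        reject["masked"] += 1
        return None
    gc = gc_fraction(seq)
    if not params.gc[0] <= gc <= params.gc[1]:
        reject["gc"] += 1
        return None
    tm = melting_temperature(seq, params)
    if tm < params.tm[0]:
        reject["tm_low"] += 1
        return None
    if tm > params.tm[2]:
        reject["tm_high"] += 1
        return None
    hp = hairpin_score(seq)
    if hp >= params.interaction_limit:
        reject["hairpin"] += 1
        return None
    homo, homo_3p = interaction_score(seq)
    if homo >= params.interaction_limit or homo_3p >= params.anchored_limit:
        reject["homodimer"] += 1
        return None
    return tm, gc, hp, homo


def _spanning_candidates(template: str, junction_pos: int, role: str,
                         params: DesignParams, reject: Counter
                         ) -> list[PrimerCandidate]:
    """All junction-crossing primers of one role meeting single-primer filters.

    The junction boundary sits between template[junction_pos] and
    template[junction_pos + 1].  A forward primer's 3' end is its rightmost
    template base, a reverse primer's its leftmost.
    """
    out = []
    lmin, _, lmax = params.primer_len
    for length in range(lmin, lmax + 1):
        for start in range(
            max(0, junction_pos - length + 2),
            min(junction_pos + 1, len(template) - length + 1),
        ):
            end = start + length  # half-open
            upstream = junction_pos - start + 1      # bases at/left of boundary
            downstream = end - 1 - junction_pos      # bases right of boundary
            if upstream < 1 or downstream < 1:
                continue
            if role == "forward":
                overlap_5p, overlap_3p = upstream, downstream
            else:
                overlap_5p, overlap_3p = downstream, upstream
            if (overlap_3p < params.junction_overlap_3p
                    or overlap_5p < params.junction_overlap_5p):
                reject["junction_overlap"] += 1
                continue
            window = template[start:end]
            seq = window if role == "forward" else reverse_complement(window)
            checked = _window_checks(seq, params, reject)
            if checked is None:
                continue
            tm, gc, hp, homo = checked
            out.append(PrimerCandidate(
                sequence=seq, role=role, template_start=start, tm=tm, gc=gc,
                hairpin_score=hp, homodimer_score=homo, spans_junction=True,
                overlap_5p=overlap_5p, overlap_3p=overlap_3p,
            ))
    return out


def _mate_candidates(template: str, lo: int, hi: int, role: str,
                     params: DesignParams, reject: Counter
                     ) -> list[PrimerCandidate]:
    """Non-spanning primers whose window lies inside template[lo:hi]."""
    out = []
    lmin, _, lmax = params.primer_len
    for length in range(lmin, lmax + 1):
        for start in range(max(0, lo), min(hi, len(template)) - length + 1):
            window = template[start : start + length]
            seq = window if role == "forward" else reverse_complement(window)
            checked = _window_checks(seq, params, reject)
            if checked is None:
                continue
            tm, gc, hp, homo = checked
            out.append(PrimerCandidate(
                sequence=seq, role=role, template_start=start, tm=tm, gc=gc,
                hairpin_score=hp, homodimer_score=homo,
            ))
    return out


def _combine(fwd_list, rev_list, params: DesignParams, reject: Counter
             ) -> list[tuple]:
    """Cheap pair filters; returns (penalty, fwd, rev) combos still unchecked
    for heterodimers (deferred: that check is quadratic in primer length)."""
    combos = []
    for fwd in fwd_list:
        for rev in rev_list:
            amp_len = rev.template_end - fwd.template_start
            if amp_len < params.min_amplicon or amp_len > params.max_amplicon:
                reject["amplicon_len"] += 1
                continue
            if rev.template_start < fwd.template_end:
                reject["primer_overlap"] += 1
                continue
            if abs(fwd.tm - rev.tm) > params.max_pair_tm_diff:
                reject["pair_tm_diff"] += 1
                continue
            combos.append((pair_penalty(fwd, rev, params), fwd, rev))
    return combos


def generate_pairs(template: str, junction_pos: int,
                   params: DesignParams | None = None) -> DesignResult:
    """Enumerate primer pairs anchored on one junction of a (masked) cDNA.

    ``junction_pos`` is the cDNA offset of the last base of the upstream exon.
    In ``span`` mode exactly one primer of each pair crosses the junction
    (with the configured minimum overlaps) and its mate sits entirely on the
    opposite side; in ``flank`` mode both primers sit off the junction with
    their 3' ends on opposite sides.  Output is ordered by ascending pair
    penalty (ties by coordinates) and truncated to ``max_candidates``; the
    rejection counter records why windows and combinations were discarded.
    """
    params = params or DesignParams()
    if not 0 <= junction_pos < len(template) - 1:
        raise ValueError(
            f"junction position {junction_pos} invalid for a "
            f"{len(template)} nt template"
        )
    if len(template) < params.min_amplicon:
        raise ValueError("template shorter than the minimum amplicon")
    reject: Counter = Counter()
    reach = params.max_amplicon  # mates can sit at most this far from the junction
    if params.mode == "span":
        span_fwd = _spanning_candidates(template, junction_pos, "forward",
                                        params, reject)
        span_rev = _spanning_candidates(template, junction_pos, "reverse",
                                        params, reject)
        plain_rev = _mate_candidates(template, junction_pos + 1,
                                     junction_pos + 1 + reach, "reverse",
                                     params, reject)
        plain_fwd = _mate_candidates(template, junction_pos + 1 - reach,
                                     junction_pos + 1, "forward",
                                     params, reject)
        combos = _combine(span_fwd, plain_rev, params, reject)
        combos += _combine(plain_fwd, span_rev, params, reject)
    else:
        plain_fwd = _mate_candidates(template, junction_pos + 1 - reach,
                                     junction_pos + 1, "forward",
                                     params, reject)
        plain_rev = _mate_candidates(template, junction_pos + 1,
                                     junction_pos + 1 + reach, "reverse",
                                     params, reject)
        # 3' ends strictly on opposite sides of the boundary
        plain_fwd = [c for c in plain_fwd if c.template_end - 1 <= junction_pos]
        plain_rev = [c for c in plain_rev if c.template_start > junction_pos]
        combos = _combine(plain_fwd, plain_rev, params, reject)
    # best-penalty first; the quadratic heterodimer check runs lazily until
    # the candidate cap is filled
    combos.sort(key=lambda c: (
        c[0], c[1].template_start, c[2].template_start, c[1].length, c[2].length,
    ))
    pairs = []
    for penalty, fwd, rev in combos:
        het, het_3p = interaction_score(fwd.sequence, rev.sequence)
        _, het_3p_rev = interaction_score(rev.sequence, fwd.sequence)
        het_3p = max(het_3p, het_3p_rev)
        if het >= params.interaction_limit or het_3p >= params.anchored_limit:
            reject["heterodimer"] += 1
            continue
        pairs.append(PrimerPair(
            forward=fwd, reverse=rev,
            amplicon_start=fwd.template_start,
            amplicon_end=rev.template_end,
            heterodimer_score=het, heterodimer_3p_score=het_3p,
            pair_penalty=penalty,
        ))
        if len(pairs) >= params.max_candidates:
            break
    return DesignResult(pairs=pairs, rejections=reject)
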