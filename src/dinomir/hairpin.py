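"""Candidate miRNA precursor prediction and evaluation.

Unannotated small-RNA reads that map to the transcriptome are tested for
residence inside a fold-back (hairpin) precursor.  Candidate windows are
cut around the mapped mature read (60 nt of flanking sequence upstream,
downstream, and both), folded with a maximum-pairing dynamic program
(a pseudo-energy Nussinov variant with stacking bonus), and accepted only
if the structure satisfies eleven stem-loop criteria (bulge sizes, stem
pairing, free energy, hairpin and loop lengths, mature-arm pairing and
stem residence).

The internal folder is *not* a thermodynamic model: it reports a
pseudo-energy of -0.5 kcal/mol per score unit.  Externally computed
structures (RNAfold / Vienna ``sequence / dot-bracket (energy)`` text)
can be supplied instead, bypassing the internal folder entirely.

Coordinates are 1-based inclusive in all public inputs and outputs.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

NEG = -1.0e18  # "impossible" marker in the pairing DP

#: default pseudo-energy scores per closed pair, by canonical pair
DEFAULT_PAIR_SCORES = {"AT": 2.0, "GC": 3.0, "GT": 1.0}
DEFAULT_STACK_BONUS = 1.0
MIN_LOOP = 3  # minimal unpaired loop length enforced by the folder

#: thresholds of the 11 acceptance criteria; value, comparison direction
CRITERIA_THRESHOLDS = {
    "c1": ("max_stem_bulge_nt", 12, "le"),
    "c2": ("stem_bp", 16, "ge"),
    "c3": ("free_energy", -15.0, "le"),
    "c4": ("hairpin_len", 50, "ge"),
    "c5": ("loop_len", 200, "le"),
    "c6": ("max_mature_bulge_nt", 4, "le"),
    "c7": ("mature_biased_errors", 4, "le"),
    "c8": ("mature_biased_bulges", 2, "le"),
    "c9": ("mature_errors", 2, "le"),
    "c10": ("mature_bp", 12, "ge"),
    "c11": ("pct_mature_in_stem", 80.0, "ge"),
}


def criterion_passes(key: str, value: float) -> bool:
    """Check a single criterion threshold against a measured value
    (e.g. ``criterion_passes("c3", -67.8)`` for a reported dG)."""
    _, thresh, direction = CRITERIA_THRESHOLDS[key]
    return value <= thresh if direction == "le" else value >= thresh


def _norm(seq: str) -> str:
    return seq.upper().replace("U", "T")


def _pair_key(a: str, b: str) -> str | None:
    """Canonical pair name for two bases (T-space), or None if not pairable."""
    p = a + b
    if p in ("AT", "TA"):
        return "AT"
    if p in ("GC", "CG"):
        return "GC"
    if p in ("GT", "TG"):
        return "GT"
    return None


@dataclass(frozen=True)
class SecondaryStructure:
    """A folded sequence: dot-bracket string plus (pseudo-)energy in kcal/mol."""

    sequence: str
    dot_bracket: str
    energy: float

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.dot_bracket):
            raise ValueError("sequence and dot-bracket lengths differ")
        pairs_from_dotbracket(self.dot_bracket)  # raises if unbalanced

    @property
    def pairs(self) -> dict[int, int]:
        return pairs_from_dotbracket(self.dot_bracket)

    @property
    def n_pairs(self) -> int:
        return self.dot_bracket.count("(")


def pairs_from_dotbracket(db: str) -> dict[int, int]:
    """Map of 0-based position -> partner for a balanced dot-bracket string."""
    stack: list[int] = []
    pairs: dict[int, int] = {}
    for i, ch in enumerate(db):
        if ch == "(":
            stack.append(i)
        elif ch == ")":
            if not stack:
                raise ValueError(f"unbalanced ')' at position {i}")
            j = stack.pop()
            pairs[j] = i
            pairs[i] = j
        elif ch != ".":
            raise ValueError(f"illegal character {ch!r} in dot-bracket")
    if stack:
        raise ValueError("unbalanced '(' in dot-bracket")
    return pairs


def fold(
    sequence: str,
    *,
    pair_scores: dict[str, float] | None = None,
    stack_bonus: float = DEFAULT_STACK_BONUS,
    min_loop: int = MIN_LOOP,
    length_bounds: tuple[int, int] | None = (50, 400),
) -> SecondaryStructure:
    """Fold a sequence with the internal maximum-pairing pseudo-energy model.

    The score of a structure is the sum of pair scores (AT/AU = 2,
    GC = 3, GT/GU = 1 by default) plus ``stack_bonus`` for every pair
    stacked directly on another.  Pseudo-energy = -score * 0.5 kcal/mol.
    Traceback is deterministic: on ties a paired base is preferred over
    an unpaired one, then the leftmost partner.

    ``length_bounds`` guards pipeline use (candidate precursors are
    50-400 nt); pass ``None`` to fold arbitrary-length test strings.
    """
    if length_bounds is not None:
        lo, hi = length_bounds
        if not lo <= len(sequence) <= hi:
            raise ValueError(
                f"sequence length {len(sequence)} outside foldable range [{lo}, {hi}]"
            )
    scores = dict(DEFAULT_PAIR_SCORES if pair_scores is None else pair_scores)
    s = _norm(sequence)
    n = len(s)

    # pscore[i, j]: score of closing pair (i, j), NEG if not pairable
    pscore = np.full((n, n), NEG)
    for i in range(n):
        for j in range(i + min_loop + 1, n):
            key = _pair_key(s[i], s[j])
            if key is not None and key in scores:
                pscore[i, j] = scores[key]

    # V[i, j]: best score of s[i..j] given (i, j) paired (closed coords)
    # W[i, j]: best score of s[i:j] (half-open), W[i, i] = 0
    V = np.full((n, n), NEG)
    W = np.zeros((n + 1, n + 1))
    for t in range(2, n + 1):  # half-open span length
        for i in range(0, n - t + 1):
            j = i + t  # half-open end
            jj = j - 1  # closed right index
            if pscore[i, jj] > NEG / 2:
                inner = W[i + 1, jj]
                if jj - 1 >= i + 1 and V[i + 1, jj - 1] > NEG / 2:
                    inner = max(inner, V[i + 1, jj - 1] + stack_bonus)
                V[i, jj] = pscore[i, jj] + inner
            best = W[i, j - 1]  # s[j-1] unpaired
            ks = np.arange(i, jj - min_loop)
            if ks.size:
                vals = W[i, ks] + V[ks, jj]
                best = max(best, float(vals.max()))
            W[i, j] = best

    db = ["."] * n
    _traceback(s, V, W, pscore, stack_bonus, min_loop, db, n)
    score = float(W[0, n])
    energy = 0.0 if score == 0.0 else -score * 0.5
    return SecondaryStructure(sequence=sequence, dot_bracket="".join(db), energy=energy)


def _traceback(s, V, W, pscore, stack_bonus, min_loop, db, n) -> None:
    eps = 1e-9
    stack: list[tuple[str, int, int]] = [("W", 0, n)]
    while stack:
        kind, i, j = stack.pop()
        if kind == "W":
            if j - i < 2:
                continue
            jj = j - 1
            target = W[i, j]
            # prefer pairing the last base, leftmost partner
            paired = False
            for k in range(i, jj - min_loop):
                if V[k, jj] > NEG / 2 and abs(W[i, k] + V[k, jj] - target) < eps:
                    stack.append(("W", i, k))
                    stack.append(("V", k, jj))
                    paired = True
                    break
            if not paired:
                stack.append(("W", i, j - 1))
        else:  # V: (i, j) closed pair
            db[i] = "("
            db[j] = ")"
            target = V[i, j] - pscore[i, j]
            # prefer the stacked continuation on ties
            if (
                j - 1 >= i + 1
                and V[i + 1, j - 1] > NEG / 2
                and abs(V[i + 1, j - 1] + stack_bonus - target) < eps
            ):
                stack.append(("V", i + 1, j - 1))
            else:
                stack.append(("W", i + 1, j))


# ---------------------------------------------------------------------------
# Vienna-format I/O


def write_vienna(records, path) -> None:
    """Write (name, SecondaryStructure) records as Vienna text."""
    with open(path, "w") as fh:
        for name, ss in records:
            fh.write(f">{name}\n{ss.sequence}\n{ss.dot_bracket} ({ss.energy:.2f})\n")


_VIENNA_ENERGY = re.compile(r"^([.()]+)\s*\(\s*(-?\d+(?:\.\d+)?)\s*\)\s*$")


def read_vienna(path) -> list[tuple[str, SecondaryStructure]]:
    """Parse Vienna records: ``>name`` / sequence / dot-bracket (energy)."""
    out = []
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    i = 0
    while i < len(lines):
        if not lines[i].startswith(">"):
            raise ValueError(f"expected header at line {i + 1}")
        name = lines[i][1:].strip()
        seq = lines[i + 1].strip()
        m = _VIENNA_ENERGY.match(lines[i + 2].strip())
        if m is None:
            raise ValueError(f"malformed structure line for record {name!r}")
        out.append(
            (name, SecondaryStructure(seq, m.group(1), float(m.group(2))))
        )
        i += 3
    return out


# ---------------------------------------------------------------------------
# Stem-loop decomposition and the 11-criterion engine


@dataclass(frozen=True)
class Criterion:
    name: str
    value: float | None  # None when undefined (no hairpin loop)
    threshold: float
    direction: str  # "le" or "ge"
    passed: bool


@dataclass(frozen=True)
class CriteriaReport:
    criteria: dict[str, Criterion]

    @property
    def overall(self) -> bool:
        return all(c.passed for c in self.criteria.values())

    def failed(self) -> list[str]:
        return [k for k, c in self.criteria.items() if not c.passed]


@dataclass
class StemLoop:
    """Decomposed hairpin: the helix chain around the innermost loop."""

    stem_pairs: list[tuple[int, int]]  # outermost -> innermost, 0-based
    loop: tuple[int, int]  # unpaired loop interval, 0-based inclusive
    events: list[dict]  # gap events between adjacent stem pairs

    @property
    def outer(self) -> tuple[int, int]:
        return self.stem_pairs[0]

    @property
    def arm5(self) -> tuple[int, int]:
        return (self.stem_pairs[0][0], self.stem_pairs[-1][0])

    @property
    def arm3(self) -> tuple[int, int]:
        return (self.stem_pairs[-1][1], self.stem_pairs[0][1])


def decompose(structure: SecondaryStructure) -> StemLoop | None:
    """Locate the principal hairpin: the innermost loop with the longest
    enclosing helix chain (ties: leftmost loop).  Returns None when the
    structure contains no hairpin loop (no pairs at all).
    """
    pairs = structure.pairs
    opens = sorted(p for p, q in pairs.items() if p < q)
    if not opens:
        return None

    # hairpin loops: closing pairs with no paired position strictly inside
    hairpins = []
    for p in opens:
        q = pairs[p]
        if not any(p < x < q for x in pairs):
            hairpins.append((p, q))

    best: StemLoop | None = None
    for (i, j) in hairpins:
        chain = [(i, j)]
        cur_i, cur_j = i, j
        while True:
            parent = None
            for p in opens:
                q = pairs[p]
                if p < cur_i and q > cur_j:
                    if parent is None or p > parent[0]:
                        parent = (p, q)
            if parent is None:
                break
            p, q = parent
            # stop at multiloop junctions: parent must enclose only this chain
            inside = [x for x in pairs if p < x < q and pairs[x] > x]
            if any(not (cur_i <= x and pairs[x] <= cur_j) for x in inside):
                break
            chain.append(parent)
            cur_i, cur_j = p, q
        chain.reverse()  # outermost first
        events = []
        for (a, b), (c, d) in zip(chain, chain[1:]):
            l5, l3 = c - a - 1, b - d - 1
            if l5 == 0 and l3 == 0:
                continue
            events.append(
                {
                    "run5": (a + 1, c - 1) if l5 else None,
                    "run3": (d + 1, b - 1) if l3 else None,
                    "l5": l5,
                    "l3": l3,
                    "errors": min(l5, l3),
                    "bulge": abs(l5 - l3),
                    "bulge_arm": 5 if l5 > l3 else (3 if l3 > l5 else 0),
                    "asymmetric": l5 != l3,
                }
            )
        sl = StemLoop(stem_pairs=chain, loop=(i + 1, j - 1), events=events)
        if best is None or len(chain) > len(best.stem_pairs) or (
            len(chain) == len(best.stem_pairs) and i < best.loop[0]
        ):
            best = sl
    return best


def _overlap(run: tuple[int, int] | None, lo: int, hi: int) -> int:
    if run is None:
        return 0
    return max(0, min(run[1], hi) - max(run[0], lo) + 1)


def evaluate(
    structure: SecondaryStructure,
    mature_interval: tuple[int, int],
    *,
    thresholds: dict | None = None,
    biased_mode: str = "asymmetric",
) -> CriteriaReport:
    """Apply the 11 stem-loop acceptance criteria.

    ``mature_interval`` is 1-based inclusive within the precursor.
    ``biased_mode`` selects which stem imperfections count as "biased":
    ``"asymmetric"`` (unpaired run sizes differ between the arms; the
    default) or ``"any"``.

    Gap events between adjacent stem pairs with unpaired run lengths
    (l5, l3) contribute min(l5, l3) "error" nucleotides (mismatch-like)
    and |l5 - l3| "bulge" nucleotides on the longer arm; a one-sided run
    is thus a pure bulge.  Mature-region counts consider events whose
    unpaired runs intersect the mature interval.
    """
    if biased_mode not in ("asymmetric", "any"):
        raise ValueError("biased_mode must be 'asymmetric' or 'any'")
    th = dict(CRITERIA_THRESHOLDS)
    if thresholds:
        for k, v in thresholds.items():
            name, _, d = th[k]
            th[k] = (name, v, d)

    m_lo, m_hi = mature_interval[0] - 1, mature_interval[1] - 1  # 0-based
    if not (0 <= m_lo <= m_hi < len(structure.sequence)):
        raise ValueError("mature interval outside the precursor")

    sl = decompose(structure)
    values: dict[str, float | None] = {}
    if sl is None:
        # no hairpin loop: stem metrics undefined -> automatic fail
        for key in th:
            values[key] = None
        values["c3"] = structure.energy
    else:
        a5_lo, a5_hi = sl.arm5
        a3_lo, a3_hi = sl.arm3
        p_out, q_out = sl.outer
        stem_positions = set(range(a5_lo, a5_hi + 1)) | set(range(a3_lo, a3_hi + 1))
        mature = set(range(m_lo, m_hi + 1))
        pairs = structure.pairs

        runs = [e["run5"] for e in sl.events if e["run5"]] + [
            e["run3"] for e in sl.events if e["run3"]
        ]
        values["c1"] = max((r[1] - r[0] + 1 for r in runs), default=0)
        values["c2"] = len(sl.stem_pairs)
        values["c3"] = structure.energy
        values["c4"] = q_out - p_out + 1
        values["c5"] = sl.loop[1] - sl.loop[0] + 1

        def mature_nt(e, which):
            return _overlap(e[which], m_lo, m_hi)

        in_mature = [
            e for e in sl.events if mature_nt(e, "run5") or mature_nt(e, "run3")
        ]
        values["c6"] = max(
            (
                mature_nt(e, "run5") + mature_nt(e, "run3")
                for e in in_mature
                if e["bulge"] > 0
            ),
            default=0,
        )
        biased = (
            in_mature
            if biased_mode == "any"
            else [e for e in in_mature if e["asymmetric"]]
        )
        values["c7"] = max((e["errors"] for e in biased), default=0)
        values["c8"] = sum(1 for e in biased if e["bulge"] > 0)
        values["c9"] = sum(e["errors"] for e in in_mature)
        values["c10"] = sum(1 for x in mature if x in pairs)
        values["c11"] = 100.0 * len(mature & stem_positions) / len(mature)

    criteria = {}
    for key, (name, thresh, direction) in th.items():
        v = values.get(key)
        if v is None:
            passed = False
        elif direction == "le":
            passed = v <= thresh
        else:
            passed = v >= thresh
        criteria[key] = Criterion(name, v, thresh, direction, passed)
    return CriteriaReport(criteria=criteria)


# ---------------------------------------------------------------------------
# Window extraction, stats, discovery


@dataclass(frozen=True)
class HairpinCandidate:
    """An accepted (or evaluated) precursor candidate."""

    contig: str
    precursor_interval: tuple[int, int]  # 1-based inclusive on contig
    mature_interval: tuple[int, int]  # 1-based inclusive on contig
    sequence: str
    mature_in_precursor: tuple[int, int]  # 1-based inclusive within precursor
    structure: SecondaryStructure
    report: CriteriaReport
    length: int = field(init=False)
    gc_percent: float = field(init=False)
    dg: float = field(init=False)

    def __post_init__(self) -> None:
        length, gc, dg = precursor_stats(self.sequence, self.structure)
        object.__setattr__(self, "length", length)
        object.__setattr__(self, "gc_percent", gc)
        object.__setattr__(self, "dg", dg)


def precursor_stats(sequence: str, structure: SecondaryStructure):
    """(length nt, GC% to 2 dp, dG kcal/mol) for a precursor."""
    s = _norm(sequence)
    length = len(s)
    gc = round(100.0 * (s.count("G") + s.count("C")) / length, 2) if length else 0.0
    return length, gc, structure.energy


def extract_windows(
    mature_start: int,
    mature_end: int,
    contig_seq: str,
    flank: int = 60,
) -> list[tuple[int, int]]:
    """Candidate precursor windows around a mapped mature locus.

    Returns up to three distinct (start, end) 1-based inclusive windows:
    upstream-flank only, downstream-flank only, and both flanks, each
    truncated at the contig boundaries.
    """
    n = len(contig_seq)
    if not (1 <= mature_start <= mature_end <= n):
        raise ValueError("mature interval outside contig")
    raw = [
        (mature_start - flank, mature_end),
        (mature_start, mature_end + flank),
        (mature_start - flank, mature_end + flank),
    ]
    seen: set[tuple[int, int]] = set()
    out = []
    for s, e in raw:
        w = (max(1, s), min(n, e))
        if w not in seen:
            seen.add(w)
            out.append(w)
    return out


def map_to_contig(read: str, transcriptome: dict[str, str]):
    """Locate a read in the transcriptome (forward strand, exact match).

    Returns (contig_id, start, end) 1-based inclusive, or None if the
    read maps nowhere or maps to more than one location.
    """
    r = _norm(read)
    hit = None
    for cid, seq in transcriptome.items():
        s = _norm(seq)
        start = s.find(r)
        while start != -1:
            if hit is not None:
                return None  # multi-mapper
            hit = (cid, start + 1, start + len(r))
            nxt = s.find(r, start + 1)
            if nxt != -1:
                return None
            break
    return hit


def discover(
    reads: dict[str, tuple[int, int]] | list[str],
    transcriptome: dict[str, str],
    *,
    flank: int = 60,
    thresholds: dict | None = None,
    biased_mode: str = "asymmetric",
    min_precursor: int = 50,
    max_precursor: int = 400,
) -> list[HairpinCandidate]:
    """Run precursor discovery for unannotated reads.

    ``reads`` maps sequence -> (count_a, count_b) (counts are carried
    through unchanged) or is a plain list of sequences.  For every read
    that maps uniquely to a contig, all flank windows are folded and
    evaluated; among windows passing all 11 criteria the lowest-energy
    (tie: shortest) precursor is kept.
    """
    if not isinstance(reads, dict):
        reads = {r: (0, 0) for r in reads}
    accepted: list[HairpinCandidate] = []
    for read in reads:
        locus = map_to_contig(read, transcriptome)
        if locus is None:
            continue
        cid, m_start, m_end = locus
        contig = transcriptome[cid]
        candidates = []
        for w_start, w_end in extract_windows(m_start, m_end, contig, flank=flank):
            seq = contig[w_start - 1 : w_end]
            if not (min_precursor <= len(seq) <= max_precursor):
                continue
            ss = fold(seq, length_bounds=(min_precursor, max_precursor))
            rel = (m_start - w_start + 1, m_end - w_start + 1)
            rep = evaluate(ss, rel, thresholds=thresholds, biased_mode=biased_mode)
            if rep.overall:
                candidates.append(
                    HairpinCandidate(
                        contig=cid,
                        precursor_interval=(w_start, w_end),
                        mature_interval=(m_start, m_end),
                        sequence=seq,
                        mature_in_precursor=rel,
                        structure=ss,
                        report=rep,
                    )
                )
        if candidates:
            candidates.sort(key=lambda c: (c.structure.energy, c.length))
            accepted.append(candidates[0])
    return accepted
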