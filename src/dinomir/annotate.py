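"""Annotation of unique clean reads.

Reads are partitioned into (in order) contaminant non-coding RNA
classes / repeats, known-miRNA hits, and the unannotated remainder that
feeds novel-precursor discovery.

Contaminant matching is exact substring containment (either strand)
against class-labelled reference sets, applied in a fixed precedence
order.  Known-miRNA matching follows the catalog convention of mature
variants: up to ``max_shift`` nt of end shift on each side and at most
``max_mismatch`` substitution over the aligned overlap, with a
deterministic best-hit rule and a variant suffix recording the
difference from the reference mature, e.g. ``_R+1`` (one extra base on
the right), ``_L-1`` (one base fewer on the left) or ``_1ss11GC``
(one substitution at detected position 11, reference G read as C).
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

log = logging.getLogger(__name__)

#: fixed contaminant class precedence
CONTAMINANT_ORDER = ("rRNA", "tRNA", "snoRNA", "snRNA", "otherRfam", "repeats")

_T = str.maketrans("Uu", "Tt")


def to_tspace(seq: str) -> str:
    """Uppercase, U -> T (internal alphabet)."""
    return seq.translate(_T).upper()


def to_uspace(seq: str) -> str:
    """T -> U for human-facing RNA reports."""
    return seq.upper().replace("T", "U")


def revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


@dataclass(frozen=True)
class CatalogEntry:
    """One known mature miRNA, miRBase-style ``<species>-<name>``."""

    name: str
    sequence: str  # stored in T-space
    precursor: str | None = None

    @property
    def species(self) -> str:
        return self.name.split("-", 1)[0] if "-" in self.name else ""


@dataclass
class ReferenceCatalog:
    """Contaminant reference sets plus the known-miRNA catalog."""

    contaminants: dict[str, list[str]] = field(default_factory=dict)
    known: list[CatalogEntry] = field(default_factory=list)
    species_priority: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.contaminants = {
            cls: [to_tspace(s) for s in seqs]
            for cls, seqs in self.contaminants.items()
        }
        self.known = [
            CatalogEntry(e.name, to_tspace(e.sequence), e.precursor)
            for e in self.known
        ]

    def priority_rank(self, species: str) -> int:
        try:
            return self.species_priority.index(species)
        except ValueError:
            return len(self.species_priority)


def load_catalog_fasta(path) -> list[CatalogEntry]:
    """Load a known-miRNA FASTA with miRBase-style headers."""
    return [
        CatalogEntry(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")
    ]


def load_contaminant_fastas(paths: dict[str, str]) -> dict[str, list[str]]:
    """Load per-class contaminant FASTAs (class name -> path)."""
    return {
        cls: [str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")]
        for cls, path in paths.items()
    }


# ---------------------------------------------------------------------------
# Contaminant classification


def classify_contaminants(reads, catalog: ReferenceCatalog):
    """Assign reads to contaminant classes by substring containment.

    ``reads`` is an iterable of sequences (or a mapping whose keys are
    sequences).  A read belongs to the first class, in the fixed order
    rRNA -> tRNA -> snoRNA -> snRNA -> otherRfam -> repeats, holding it
    as an exact substring on either strand.  Returns a mapping
    read -> class for the contaminated reads only.
    """
    assignment: dict[str, str] = {}
    for read in reads:
        r = to_tspace(read)
        rc = revcomp(r)
        for cls in CONTAMINANT_ORDER:
            refs = catalog.contaminants.get(cls, [])
            if any(r in ref or rc in ref for ref in refs):
                assignment[read] = cls
                break
    return assignment


def contaminant_report(
    assignment: dict[str, str],
    counts: dict[str, list[int]],
    raw_totals: list[int],
    raw_uniques: list[int],
    libraries: list[str],
) -> pd.DataFrame:
    """Per-class accounting: total/unique reads and percent of raw total."""
    rows = []
    for cls in CONTAMINANT_ORDER:
        members = [r for r, c in assignment.items() if c == cls]
        for li, lib in enumerate(libraries):
            tot = sum(counts[r][li] for r in members if r in counts)
            uniq = sum(1 for r in members if r in counts and counts[r][li] > 0)
            rows.append(
                {
                    "category": cls,
                    "library": lib,
                    "total": tot,
                    "unique": uniq,
                    "pct_total_of_raw": round(100.0 * tot / raw_totals[li], 2)
                    if raw_totals[li]
                    else 0.0,
                    "pct_unique_of_raw": round(100.0 * uniq / raw_uniques[li], 2)
                    if raw_uniques[li]
                    else 0.0,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Known-miRNA matching


@dataclass(frozen=True)
class KnownHit:
    """A unique read matched to a catalog mature miRNA."""

    read: str
    entry: CatalogEntry
    n_substitutions: int
    left_shift: int  # detected minus reference, left end
    right_shift: int  # detected minus reference, right end
    substitution: tuple[int, str, str] | None  # (1-based pos, ref, read) U-space
    counts: tuple[int, ...] = ()

    @property
    def variant_suffix(self) -> str:
        parts = []
        if self.left_shift:
            parts.append(f"_L{self.left_shift:+d}")
        if self.right_shift:
            parts.append(f"_R{self.right_shift:+d}")
        if self.substitution is not None:
            pos, ref_b, read_b = self.substitution
            parts.append(f"_1ss{pos}{ref_b}{read_b}")
        return "".join(parts)

    @property
    def reported_name(self) -> str:
        return self.entry.name + self.variant_suffix

    @property
    def family(self) -> str:
        return assign_family(self.entry.name)


def _align(read: str, ref: str, left_shift: int):
    """Hamming comparison of read vs ref at a fixed left shift.

    ``left_shift`` > 0 means the read has extra bases on the left.
    Returns (n_subs, substitution) over the overlap, or None when the
    overlap is empty.  ``substitution`` is (1-based read pos, ref base,
    read base) in U-space for the single mismatch, if any.
    """
    n, m = len(read), len(ref)
    start = max(0, left_shift)  # first overlapping read index
    end = min(n, m + left_shift)  # one past last overlapping read index
    if end <= start:
        return None
    subs = []
    for i in range(start, end):
        rb = ref[i - left_shift]
        if read[i] != rb:
            subs.append((i + 1, to_uspace(rb), to_uspace(read[i])))
    return len(subs), (subs[0] if len(subs) == 1 else None)


def match_known(
    reads,
    catalog: ReferenceCatalog,
    max_mismatch: int = 1,
    max_shift: int = 2,
) -> list[KnownHit]:
    """Match unique reads against the known-miRNA catalog.

    ``reads`` is an iterable of sequences or a mapping
    sequence -> per-library counts.  For every read each catalog mature
    is tried at every end-shift combination within ``max_shift``;
    acceptances require at most ``max_mismatch`` substitutions over the
    overlap.  The best hit is chosen by (fewest substitutions, smallest
    total absolute shift, highest species priority, lexicographic name).
    """
    if not catalog.known:
        log.warning("known-miRNA catalog is empty; no hits possible")
        return []
    count_map = reads if isinstance(reads, dict) else {r: () for r in reads}
    hits: list[KnownHit] = []
    for read in count_map:
        r = to_tspace(read)
        best = None
        best_key = None
        for entry in catalog.known:
            for left in range(-max_shift, max_shift + 1):
                right = len(r) - len(entry.sequence) - left
                if abs(right) > max_shift:
                    continue
                res = _align(r, entry.sequence, left)
                if res is None:
                    continue
                n_subs, sub = res
                if n_subs > max_mismatch:
                    continue
                key = (
                    n_subs,
                    abs(left) + abs(right),
                    catalog.priority_rank(entry.species),
                    entry.name,
                )
                if best_key is None or key < best_key:
                    best_key = key
                    best = KnownHit(
                        read=read,
                        entry=entry,
                        n_substitutions=n_subs,
                        left_shift=left,
                        right_shift=right,
                        substitution=sub,
                        counts=tuple(count_map[read]) if count_map[read] else (),
                    )
        if best is not None:
            hits.append(best)
    return hits


def matching_species(
    read: str, catalog: ReferenceCatalog, max_mismatch: int = 1, max_shift: int = 2
) -> set[str]:
    """All catalog species with at least one entry accepting the read
    (used for cross-species occurrence counting)."""
    r = to_tspace(read)
    species = set()
    for entry in catalog.known:
        if entry.species in species:
            continue
        for left in range(-max_shift, max_shift + 1):
            right = len(r) - len(entry.sequence) - left
            if abs(right) > max_shift:
                continue
            res = _align(r, entry.sequence, left)
            if res is not None and res[0] <= max_mismatch:
                species.add(entry.species)
                break
    return species


_FAMILY_RE = re.compile(r"(?:^|-)mir-?(\d+)", re.IGNORECASE)


def assign_family(name: str) -> str:
    """Family = "miR" + the numeric core of a catalog name.

    ``zma-miR169f-5p`` -> ``miR169``; unparseable names -> ``unknown``.
    """
    m = _FAMILY_RE.search(name)
    if m is None:
        log.info("cannot parse family from %r", name)
        return "unknown"
    return f"miR{int(m.group(1))}"


# ---------------------------------------------------------------------------
# Full partition


@dataclass
class AnnotationResult:
    """The three-way partition of unique clean reads."""

    contaminants: dict[str, str]  # read -> class
    known_hits: list[KnownHit]
    remainder: dict[str, list[int]]  # read -> per-library counts
    report: pd.DataFrame | None = None


def annotate_reads(
    clean,
    catalog: ReferenceCatalog,
    max_mismatch: int = 1,
    max_shift: int = 2,
) -> AnnotationResult:
    """Partition a CleanReadSet into contaminants, known hits, remainder."""
    counts = clean.counts
    contam = classify_contaminants(counts, catalog)
    rest = {r: c for r, c in counts.items() if r not in contam}
    hits = match_known(rest, catalog, max_mismatch=max_mismatch, max_shift=max_shift)
    hit_reads = {h.read for h in hits}
    remainder = {r: c for r, c in rest.items() if r not in hit_reads}
    acct = clean.accounting
    raw = acct[acct["category"] == "Raw reads"]
    report = contaminant_report(
        contam,
        counts,
        raw_totals=list(raw["total"]),
        raw_uniques=list(raw["unique"]),
        libraries=clean.libraries,
    )
    return AnnotationResult(
        contaminants=contam, known_hits=hits, remainder=remainder, report=report
    )


def hits_to_frame(hits: list[KnownHit], libraries: list[str]) -> pd.DataFrame:
    rows = []
    for h in sorted(hits, key=lambda h: (h.reported_name, h.read)):
        row = {
            "read": to_uspace(h.read),
            "miRNA": h.reported_name,
            "family": h.family,
            "n_substitutions": h.n_substitutions,
            "left_shift": h.left_shift,
            "right_shift": h.right_shift,
        }
        for i, lib in enumerate(libraries):
            row[f"count_{lib}"] = h.counts[i] if i < len(h.counts) else 0
        rows.append(row)
    return pd.DataFrame(rows)
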