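"""Raw-read cleaning and collapsing to unique sequences.

Small-RNA reads carry the 3' sequencing adapter; cleaning removes it,
discards reads whose insert falls outside the 18-25 nt analysis window,
flags junk (ambiguous bases, poly-A), and collapses the survivors to
unique sequences with per-library counts.  Every raw read is assigned to
exactly one terminal category so that the accounting table is a strict
partition of the raw total:

1. "3ADT&length filter" -- no adapter found (and raw length outside the
   gel-cut window) or trimmed insert outside 18-25 nt;
2. "Junk reads"         -- any N, or a poly-A run covering >= 80% of the read;
3. "Clean reads"        -- everything else, collapsed to unique sequences.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd
from Bio import SeqIO

#: fixed category order of the accounting table
CATEGORIES = ("Raw reads", "3ADT&length filter", "Junk reads", "Clean reads")


@dataclass(frozen=True)
class FilterRules:
    """Cleaning parameters.

    ``raw_window`` is the library gel-cut size range: reads in which no
    adapter is detected are kept only when their raw length already lies
    in this window (and then must also pass the analysis window).
    """

    adapter: str
    min_overlap: int = 6
    length_window: tuple[int, int] = (18, 25)
    raw_window: tuple[int, int] = (15, 40)
    polya_fraction: float = 0.8

    def __post_init__(self) -> None:
        if not self.adapter:
            raise ValueError("adapter sequence must be non-empty")
        if not 1 <= self.min_overlap <= len(self.adapter):
            raise ValueError("require adapter length >= min_overlap >= 1")


def trim_adapter(seq: str, adapter: str, min_overlap: int = 6):
    """Strip the 3' adapter from a read.

    Returns ``(insert, True)`` using the leftmost full adapter
    occurrence, or the longest exact read-suffix / adapter-prefix
    overlap of at least ``min_overlap`` nt; ``(seq, False)`` when no
    adapter evidence is found.
    """
    if not adapter:
        raise ValueError("adapter sequence must be non-empty")
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    seq = seq.upper()
    adapter = adapter.upper()
    idx = seq.find(adapter)
    if idx != -1:
        return seq[:idx], True
    for k in range(min(len(seq), len(adapter) - 1), min_overlap - 1, -1):
        if seq[-k:] == adapter[:k]:
            return seq[:-k], True
    return seq, False


def _longest_run(seq: str, base: str) -> int:
    best = cur = 0
    for ch in seq:
        cur = cur + 1 if ch == base else 0
        best = max(best, cur)
    return best


def is_junk(seq: str, polya_fraction: float = 0.8) -> bool:
    """Junk: any ambiguous base, or a poly-A run covering >= the given
    fraction of the read."""
    if "N" in seq:
        return True
    return len(seq) > 0 and _longest_run(seq, "A") >= polya_fraction * len(seq)


def classify_read(seq: str, rules: FilterRules):
    """Assign one raw read to its terminal category.

    Returns ``(category, insert)``; ``insert`` is None for reads removed
    by the adapter/length filter.
    """
    seq = seq.upper().replace("U", "T")
    insert, found = trim_adapter(seq, rules.adapter, rules.min_overlap)
    if not found:
        lo, hi = rules.raw_window
        if not lo <= len(seq) <= hi:
            return "3ADT&length filter", None
        insert = seq
    lo, hi = rules.length_window
    if not lo <= len(insert) <= hi:
        return "3ADT&length filter", None
    if is_junk(insert, rules.polya_fraction):
        return "Junk reads", insert
    return "Clean reads", insert


@dataclass
class CleanReadSet:
    """Unique clean sequences with per-library counts plus accounting."""

    libraries: list[str]
    counts: dict[str, list[int]] = field(default_factory=dict)
    accounting: pd.DataFrame | None = None

    @property
    def clean_totals(self) -> list[int]:
        totals = [0] * len(self.libraries)
        for per_lib in self.counts.values():
            for i, c in enumerate(per_lib):
                totals[i] += c
        return totals

    @property
    def n_unique(self) -> int:
        return len(self.counts)

    def library_index(self, name: str) -> int:
        return self.libraries.index(name)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame.from_dict(
            self.counts, orient="index", columns=[f"count_{l}" for l in self.libraries]
        )
        df.index.name = "sequence"
        return df.sort_index()

    def write_fasta(self, path) -> None:
        """Collapsed FASTA: ``>uid_count_<lib>=<n>;...`` headers."""
        with open(path, "w") as fh:
            for uid, (seq, per_lib) in enumerate(sorted(self.counts.items()), 1):
                parts = ";".join(
                    f"count_{l}={c}" for l, c in zip(self.libraries, per_lib)
                )
                fh.write(f">u{uid}_{parts}\n{seq}\n")

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t")


def classify_and_filter(
    library_reads: dict[str, list[str]], rules: FilterRules
) -> CleanReadSet:
    """Clean raw reads from one or more libraries and collapse them.

    ``library_reads`` maps library name -> iterable of raw read
    sequences.  The accounting table partitions the raw total of each
    library over the fixed categories, with both total and unique
    (distinct-sequence) tallies.
    """
    libs = list(library_reads)
    counts: dict[str, list[int]] = {}
    total = {c: [0] * len(libs) for c in CATEGORIES}
    uniq_sets: dict[str, list[set]] = {c: [set() for _ in libs] for c in CATEGORIES}

    for li, lib in enumerate(libs):
        for raw in library_reads[lib]:
            raw = str(raw).upper().replace("U", "T")
            total["Raw reads"][li] += 1
            uniq_sets["Raw reads"][li].add(raw)
            cat, insert = classify_read(raw, rules)
            total[cat][li] += 1
            uniq_sets[cat][li].add(insert if insert is not None else raw)
            if cat == "Clean reads":
                counts.setdefault(insert, [0] * len(libs))[li] += 1

    rows = []
    for cat in CATEGORIES:
        for li, lib in enumerate(libs):
            rows.append(
                {
                    "category": cat,
                    "library": lib,
                    "total": total[cat][li],
                    "unique": len(uniq_sets[cat][li]),
                }
            )
    acct = pd.DataFrame(rows)
    return CleanReadSet(libraries=libs, counts=counts, accounting=acct)


def read_fastq(path) -> list[str]:
    """Read sequences from a FASTQ file (Phred+33; qualities ignored)."""
    return [str(rec.seq) for rec in SeqIO.parse(str(path), "fastq")]
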