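"""Synthetic two-library small-RNA experiment with a truth manifest.

The generator emulates the statistical structure of a two-growth-phase
(lag vs logarithmic) small-RNA sequencing experiment at desk scale: a
toy transcriptome whose contigs host planted miRNA hairpin precursors,
contaminant rRNA/tRNA/snoRNA/snRNA/repeat fragments, poly-A and
ambiguous-base junk, and out-of-window fragments that exist solely to
exercise the length filter.  Reads are the mature (or fragment)
sequence plus the 3' adapter, truncated to the platform read length.

Per-miRNA between-library abundance ratios (lag/log), including
presence/absence sentinels, are part of the stated world; sampling is
either *deterministic* (exactly the expected counts, for exact
assertions) or *multinomial* (seeded, at a chosen depth, for power and
calibration checks).  A fixed seed makes all outputs byte-identical.

Planted precursors are built as mature + 5'-arm padding + terminal loop
+ (partially) complementary 3' arm, and are verified at generation time
to pass all eleven hairpin acceptance criteria.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import hairpin
from .annotate import CatalogEntry, ReferenceCatalog

#: 3' sequencing adapter (TruSeq small-RNA style)
DEFAULT_ADAPTER = "TGGAATTCTCGGGTGCCAAGG"

ONLY_A = "only-A"
ONLY_B = "only-B"

_BASES = np.array(list("ACGT"))
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


class GenerationError(RuntimeError):
    """Raised when the generator cannot satisfy its own constraints."""


@dataclass
class SimConfig:
    """Stated world of the synthetic experiment.

    ``fold_change_spec`` lists (mirna_name, ratio) with ratio the
    expected lag/log count ratio, or the sentinels "only-A" (lag only)
    / "only-B" (log only).  ``flank_design`` is the fraction of 3'-arm
    positions complementary to the 5' arm (1.0 = perfect stem).
    """

    seed: int = 0
    n_contigs: int = 8
    contig_len: int = 400
    n_planted_mirnas: int = 10
    mature_len_range: tuple[int, int] = (20, 24)
    flank_design: float = 1.0
    stem_pad: int = 5  # extra stem pairs beyond the mature arm
    loop_len: int = 8
    n_contaminants: dict[str, int] = field(
        default_factory=lambda: {
            "rRNA": 4,
            "tRNA": 3,
            "snoRNA": 2,
            "snRNA": 2,
            "repeats": 2,
        }
    )
    contaminant_count: int = 20  # expected reads per contaminant fragment/library
    adapter_seq: str = DEFAULT_ADAPTER
    read_length: int = 36
    depth_per_library: int = 20000  # multinomial mode only
    base_count: int = 200  # expected reads per miRNA/library unless spec'd
    fold_change_spec: list[tuple[str, float | str]] = field(default_factory=list)
    junk_fraction: float = 0.02
    n_out_of_window: int = 20  # fragments outside 18-25 nt, per library
    known_fraction: float = 0.6  # share of planted miRNAs copied to the catalog

    def validate(self) -> None:
        lo, hi = self.mature_len_range
        if not (18 <= lo <= hi <= 25):
            raise ValueError("mature_len_range must lie within [18, 25]")
        if not 0.0 <= self.flank_design <= 1.0:
            raise ValueError("flank_design must be in [0, 1]")
        if not 0.0 <= self.junk_fraction <= 1.0:
            raise ValueError("junk_fraction must be in [0, 1]")
        for name, ratio in self.fold_change_spec:
            if isinstance(ratio, str):
                if ratio not in (ONLY_A, ONLY_B):
                    raise ValueError(f"unknown ratio sentinel {ratio!r} for {name}")
            elif not ratio > 0:
                raise ValueError(f"ratio for {name} must be strictly positive")
        max_prec = 2 * (hi + self.stem_pad) + self.loop_len
        if self.n_planted_mirnas > 0 and self.contig_len < max_prec + 20:
            raise ValueError(
                f"contig_len={self.contig_len} too short to host a precursor "
                f"(need >= {max_prec + 20} nt)"
            )


@dataclass
class PlantedMiRNA:
    name: str
    contig: str
    precursor_interval: tuple[int, int]  # 1-based inclusive on contig
    mature_interval: tuple[int, int]
    mature: str
    strand: str = "+"
    known: bool = True
    expected: tuple[float, float] = (0.0, 0.0)  # (lag, log)


@dataclass
class PlantedContaminant:
    cls: str  # rRNA/tRNA/snoRNA/snRNA/repeats/junk_polyA/junk_N/out_of_window
    sequence: str
    expected: tuple[float, float] = (0.0, 0.0)


@dataclass
class TruthManifest:
    mirnas: list[PlantedMiRNA] = field(default_factory=list)
    contaminants: list[PlantedContaminant] = field(default_factory=list)

    def expected_totals(self, include_junk: bool = True) -> tuple[float, float]:
        ea = sum(m.expected[0] for m in self.mirnas)
        eb = sum(m.expected[1] for m in self.mirnas)
        for c in self.contaminants:
            if not include_junk and c.cls.startswith("junk"):
                continue
            ea += c.expected[0]
            eb += c.expected[1]
        return ea, eb

    def to_json(self) -> str:
        return json.dumps(
            {
                "mirnas": [dataclasses.asdict(m) for m in self.mirnas],
                "contaminants": [dataclasses.asdict(c) for c in self.contaminants],
            },
            indent=1,
        )

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(
                "kind\tname\tcontig\tprecursor_start\tprecursor_end\t"
                "mature_start\tmature_end\tstrand\tsequence\tknown\t"
                "expected_lag\texpected_log\n"
            )
            for m in self.mirnas:
                fh.write(
                    f"miRNA\t{m.name}\t{m.contig}\t{m.precursor_interval[0]}\t"
                    f"{m.precursor_interval[1]}\t{m.mature_interval[0]}\t"
                    f"{m.mature_interval[1]}\t{m.strand}\t{m.mature}\t"
                    f"{int(m.known)}\t{m.expected[0]:g}\t{m.expected[1]:g}\n"
                )
            for c in self.contaminants:
                fh.write(
                    f"{c.cls}\t.\t.\t.\t.\t.\t.\t.\t{c.sequence}\t0\t"
                    f"{c.expected[0]:g}\t{c.expected[1]:g}\n"
                )


@dataclass
class Reference:
    transcriptome: dict[str, str]
    contaminant_refs: dict[str, list[str]]
    catalog: ReferenceCatalog
    manifest: TruthManifest


def _rand_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(_BASES, size=n))


def _design_precursor(rng: np.random.Generator, mature: str, cfg: SimConfig) -> str:
    """mature + pad + loop + (partially complementary) reversed arm."""
    arm5 = mature + _rand_seq(rng, cfg.stem_pad)
    loop = _rand_seq(rng, cfg.loop_len)
    arm3 = []
    for b in reversed(arm5):
        if rng.random() < cfg.flank_design:
            arm3.append(_COMP[b])
        else:
            choices = [x for x in "ACGT" if x != _COMP[b]]
            arm3.append(choices[rng.integers(len(choices))])
    return arm5 + loop + "".join(arm3)


def _precursor_ok(prec: str, mature_len: int) -> bool:
    ss = hairpin.fold(prec, length_bounds=None)
    rep = hairpin.evaluate(ss, (1, mature_len))
    return rep.overall


def generate_reference(config: SimConfig, max_retries: int = 50) -> Reference:
    """Build the toy transcriptome, contaminant references, known-miRNA
    catalog and truth manifest.

    Every planted precursor is verified to pass all 11 hairpin criteria
    (retrying the design on failure); planted mature sequences are
    unique across the catalog and map uniquely into the transcriptome.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    contigs = {
        f"contig_{i + 1}": list(_rand_seq(rng, config.contig_len))
        for i in range(config.n_contigs)
    }
    manifest = TruthManifest()
    catalog_entries: list[CatalogEntry] = []
    matures: set[str] = set()

    # deterministic slot layout: non-overlapping regions across contigs
    lo, hi = config.mature_len_range
    max_prec = 2 * (hi + config.stem_pad) + config.loop_len
    slot_len = max_prec + 10
    slots = []
    for cid in contigs:
        n_slots = config.contig_len // slot_len
        for s in range(n_slots):
            slots.append((cid, s * slot_len))
    if config.n_planted_mirnas > len(slots):
        raise ValueError(
            f"cannot place {config.n_planted_mirnas} precursors: only "
            f"{len(slots)} slots of {slot_len} nt available; increase "
            "n_contigs or contig_len"
        )

    n_known = round(config.known_fraction * config.n_planted_mirnas)
    spec = dict(config.fold_change_spec)
    for i in range(config.n_planted_mirnas):
        name = f"aca-miR{101 + i}-5p"
        for attempt in range(max_retries + 1):
            mlen = int(rng.integers(lo, hi + 1))
            mature = _rand_seq(rng, mlen)
            if mature in matures:
                if attempt == max_retries:
                    raise GenerationError(
                        f"duplicate mature sequence persists for {name}"
                    )
                continue
            prec = _design_precursor(rng, mature, config)
            if _precursor_ok(prec, mlen):
                break
            if attempt == max_retries:
                raise GenerationError(
                    f"could not design a criteria-passing precursor for {name} "
                    f"(flank_design={config.flank_design})"
                )
        matures.add(mature)
        cid, offset = slots[i]
        start = offset + int(rng.integers(0, slot_len - len(prec) + 1))
        contigs[cid][start : start + len(prec)] = list(prec)

        known = i < n_known
        if known:
            catalog_entries.append(CatalogEntry(name, mature))
        ratio = spec.get(name, 1.0)
        b = float(config.base_count)
        if ratio == ONLY_A:
            exp = (b, 0.0)
        elif ratio == ONLY_B:
            exp = (0.0, b)
        else:
            exp = (round(b * float(ratio)), b)
        manifest.mirnas.append(
            PlantedMiRNA(
                name=name,
                contig=cid,
                precursor_interval=(start + 1, start + len(prec)),
                mature_interval=(start + 1, start + mlen),
                mature=mature,
                known=known,
                expected=exp,
            )
        )
    unknown_spec = set(spec) - {m.name for m in manifest.mirnas}
    if unknown_spec:
        raise ValueError(f"fold_change_spec names not planted: {sorted(unknown_spec)}")

    transcriptome = {cid: "".join(seq) for cid, seq in contigs.items()}
    for m in manifest.mirnas:  # planted matures must map uniquely
        occ = sum(t.count(m.mature) for t in transcriptome.values())
        if occ != 1:
            raise GenerationError(f"mature of {m.name} occurs {occ} times")

    contaminant_refs: dict[str, list[str]] = {}
    for cls, n in config.n_contaminants.items():
        refs = []
        for _ in range(n):
            ref = _rand_seq(rng, int(rng.integers(60, 121)))
            refs.append(ref)
            flen = int(rng.integers(18, 26))
            fstart = int(rng.integers(0, len(ref) - flen + 1))
            frag = ref[fstart : fstart + flen]
            attempt = 0
            while (
                frag in matures
                or any(frag in t for t in transcriptome.values())
                or "N" in frag
            ):
                attempt += 1
                if attempt > max_retries:
                    raise GenerationError(f"cannot draw a clean {cls} fragment")
                fstart = int(rng.integers(0, len(ref) - flen + 1))
                frag = ref[fstart : fstart + flen]
            manifest.contaminants.append(
                PlantedContaminant(
                    cls=cls,
                    sequence=frag,
                    expected=(
                        float(config.contaminant_count),
                        float(config.contaminant_count),
                    ),
                )
            )
        contaminant_refs[cls] = refs

    # out-of-window fragments (exercise the length filter only)
    for _ in range(config.n_out_of_window):
        if rng.random() < 0.5:
            flen = int(rng.integers(15, 18))
        else:
            flen = int(rng.integers(26, 31))
        manifest.contaminants.append(
            PlantedContaminant(
                cls="out_of_window", sequence=_rand_seq(rng, flen), expected=(1.0, 1.0)
            )
        )

    # junk: one poly-A and one ambiguous-base template per library share
    ea, eb = manifest.expected_totals(include_junk=True)
    n_junk_a = round(config.junk_fraction * ea)
    n_junk_b = round(config.junk_fraction * eb)
    njseq = list(_rand_seq(rng, 22))
    njseq[10] = "N"
    for seq, frac in (("A" * 22, 0.5), ("".join(njseq), 0.5)):
        manifest.contaminants.append(
            PlantedContaminant(
                cls="junk_polyA" if set(seq) == {"A"} else "junk_N",
                sequence=seq,
                expected=(round(n_junk_a * frac), round(n_junk_b * frac)),
            )
        )

    catalog = ReferenceCatalog(
        contaminants=contaminant_refs,
        known=catalog_entries,
        species_priority=["aca"],
    )
    return Reference(
        transcriptome=transcriptome,
        contaminant_refs=contaminant_refs,
        catalog=catalog,
        manifest=manifest,
    )


def _make_read(insert: str, cfg: SimConfig) -> str:
    read = insert + cfg.adapter_seq
    if len(read) < cfg.read_length:
        read += "A" * (cfg.read_length - len(read))
    return read[: cfg.read_length]


def generate_libraries(
    reference: Reference,
    config: SimConfig,
    mode: str = "deterministic",
):
    """Emit the two read libraries as lists of (name, sequence).

    ``mode="deterministic"`` emits exactly the expected counts of every
    manifest entry; ``mode="multinomial"`` draws ``depth_per_library``
    reads per library from the expected-count distribution (seeded from
    ``config.seed``).  A depth of zero yields empty libraries.
    """
    if mode not in ("deterministic", "multinomial"):
        raise ValueError("mode must be 'deterministic' or 'multinomial'")
    man = reference.manifest
    entries: list[tuple[str, tuple[float, float]]] = [
        (m.mature, m.expected) for m in man.mirnas
    ] + [(c.sequence, c.expected) for c in man.contaminants]

    libs: list[list[tuple[str, str]]] = [[], []]
    if mode == "deterministic":
        counts = [
            [int(round(e[li])) for _, e in entries] for li in range(2)
        ]
    else:
        rng = np.random.default_rng(config.seed + 1)
        # split total depth across libraries in proportion to expected
        # totals, so between-library count ratios are kept in expectation
        e_mat = np.array([[exp[li] for _, exp in entries] for li in range(2)], float)
        tots = e_mat.sum(axis=1)
        counts = []
        for li in range(2):
            if tots[li] == 0 or config.depth_per_library == 0:
                counts.append([0] * len(entries))
                continue
            depth = int(round(2 * config.depth_per_library * tots[li] / tots.sum()))
            counts.append(list(rng.multinomial(depth, e_mat[li] / tots[li])))
    for li, lib_name in enumerate(("A", "B")):
        serial = 0
        for (insert, _), c in zip(entries, counts[li]):
            read = _make_read(insert, config)
            for _ in range(int(c)):
                serial += 1
                libs[li].append((f"{lib_name}_{serial:07d}", read))
    return libs[0], libs[1]


# ---------------------------------------------------------------------------
# File emission


def write_fastq(reads, path) -> None:
    """Phred+33 FASTQ with constant quality 'I'."""
    with open(path, "w") as fh:
        for name, seq in reads:
            fh.write(f"@{name}\n{seq}\n+\n{'I' * len(seq)}\n")


def write_fasta(records, path) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n{seq}\n")


def simulate_to_dir(
    config: SimConfig, outdir, mode: str = "deterministic"
) -> Reference:
    """Run the full simulation and write all artifacts to ``outdir``.

    Files: transcriptome.fasta, contaminants_<class>.fasta,
    known_mirnas.fasta, library_A.fastq, library_B.fastq,
    manifest.tsv, manifest.json.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ref = generate_reference(config)
    reads_a, reads_b = generate_libraries(ref, config, mode=mode)
    write_fasta(ref.transcriptome.items(), outdir / "transcriptome.fasta")
    for cls, refs in ref.contaminant_refs.items():
        write_fasta(
            ((f"{cls}_{i + 1}", s) for i, s in enumerate(refs)),
            outdir / f"contaminants_{cls}.fasta",
        )
    write_fasta(
        ((e.name, e.sequence) for e in ref.catalog.known),
        outdir / "known_mirnas.fasta",
    )
    write_fastq(reads_a, outdir / "library_A.fastq")
    write_fastq(reads_b, outdir / "library_B.fastq")
    ref.manifest.write_tsv(outdir / "manifest.tsv")
    (outdir / "manifest.json").write_text(ref.manifest.to_json())
    return ref
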