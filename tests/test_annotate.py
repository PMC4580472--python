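"""Contaminant classification, known-miRNA matching and family naming."""

import numpy as np
import pytest

from dinomir.annotate import (
    CatalogEntry,
    ReferenceCatalog,
    annotate_reads,
    assign_family,
    classify_contaminants,
    match_known,
    matching_species,
    revcomp,
)

COMP = {"A": "T", "T": "A", "G": "C", "C": "G"}


def make_catalog(**kw):
    defaults = dict(contaminants={}, known=[], species_priority=[])
    defaults.update(kw)
    return ReferenceCatalog(**defaults)


class TestContaminants:
    def test_planted_fragment_assigned(self):
        ref = "CGATCGTAGCTAGCTAGCTAGGCTAGCTAGGATCGAT"
        cat = make_catalog(contaminants={"rRNA": [ref]})
        frag = ref[5:27]
        assert classify_contaminants([frag], cat) == {frag: "rRNA"}

    def test_reverse_strand_match(self):
        ref = "CGATCGTAGCTAGCTAGCTAGGCTAGCTAGGATCGAT"
        cat = make_catalog(contaminants={"tRNA": [ref]})
        frag = revcomp(ref[5:27])
        assert classify_contaminants([frag], cat)[frag] == "tRNA"

    def test_precedence_rrna_over_repeats(self):
        seq = "GCTAGCTAGCTAGGCTAGCTAG"
        cat = make_catalog(
            contaminants={"repeats": ["AAA" + seq], "rRNA": ["CCC" + seq]}
        )
        assert classify_contaminants([seq], cat)[seq] == "rRNA"

    def test_unmatched_left_out(self):
        cat = make_catalog(contaminants={"rRNA": ["CCCCCCCCCCCCCCCCCCCCCCCC"]})
        assert classify_contaminants(["GTGTGTGTGTGTGTGTGTGT"], cat) == {}


MATURE = "TGGAGCTCCCTTCATTCCAAT"  # 21 nt


class TestMatchKnown:
    def cat(self, *entries):
        return make_catalog(
            known=[CatalogEntry(n, s) for n, s in entries],
            species_priority=["cre", "osa", "tae"],
        )

    def test_exact_match_no_suffix(self):
        (hit,) = match_known([MATURE], self.cat(("osa-miR530", MATURE)))
        assert hit.variant_suffix == ""
        assert hit.reported_name == "osa-miR530"

    def test_extra_base_right(self):
        (hit,) = match_known([MATURE + "A"], self.cat(("osa-miR530", MATURE)))
        assert hit.variant_suffix == "_R+1"

    def test_missing_base_left_plus_substitution(self):
        detected = list(MATURE[1:])
        ref = list(MATURE)
        ref[11] = "G"  # detected pos 11 (1-based) aligns to ref pos 12
        detected[10] = "C"
        (hit,) = match_known(
            ["".join(detected)], self.cat(("bdi-miR7732-3p", "".join(ref)))
        )
        assert hit.variant_suffix == "_L-1_1ss11GC"
        assert hit.reported_name == "bdi-miR7732-3p_L-1_1ss11GC"

    def test_two_mismatches_rejected(self):
        detected = list(MATURE)
        detected[3] = COMP[detected[3]]
        detected[10] = COMP[detected[10]]
        assert match_known(["".join(detected)], self.cat(("osa-miR530", MATURE))) == []

    def test_species_priority_breaks_ties(self):
        cat = self.cat(("tae-miR9999", MATURE), ("cre-miR9999", MATURE))
        (hit,) = match_known([MATURE], cat)
        assert hit.entry.name == "cre-miR9999"

    def test_priority_monotonicity(self):
        entries = [("aaa-miR1", MATURE), ("bbb-miR1", MATURE)]
        low = make_catalog(
            known=[CatalogEntry(*e) for e in entries], species_priority=["aaa", "bbb"]
        )
        high = make_catalog(
            known=[CatalogEntry(*e) for e in entries], species_priority=["bbb", "aaa"]
        )
        n_low = sum(h.entry.species == "bbb" for h in match_known([MATURE], low))
        n_high = sum(h.entry.species == "bbb" for h in match_known([MATURE], high))
        assert n_high >= n_low

    def test_empty_catalog_warns_empty(self):
        assert match_known([MATURE], make_catalog()) == []


def brute_force_best(read, catalog, max_mismatch=1, max_shift=2):
    """Exhaustive scan over all shift/substitution combinations,
    independent of the implementation's alignment bookkeeping."""
    best = None
    for entry in catalog.known:
        ref = entry.sequence
        for left in range(-max_shift, max_shift + 1):
            for right in range(-max_shift, max_shift + 1):
                if len(read) != len(ref) + left + right:
                    continue
                lo = max(0, left)
                hi = min(len(read), len(ref) + left)
                if hi <= lo:
                    continue
                subs = sum(
                    1 for i in range(lo, hi) if read[i] != ref[i - left]
                )
                if subs > max_mismatch:
                    continue
                key = (
                    subs,
                    abs(left) + abs(right),
                    catalog.priority_rank(entry.species),
                    entry.name,
                )
                if best is None or key < best[0]:
                    best = (key, entry.name, left, right)
    return best


class TestBruteForceOracle:
    def test_fifty_random_pairs(self):
        rng = np.random.default_rng(2024)
        species = ["cre", "osa", "tae", "zma", "stu"]
        for trial in range(50):
            entries = []
            for k in range(int(rng.integers(3, 12))):
                sp = species[int(rng.integers(len(species)))]
                seq = "".join(rng.choice(list("ACGT"), size=int(rng.integers(20, 25))))
                entries.append(CatalogEntry(f"{sp}-miR{100 + k}", seq))
            cat = make_catalog(known=entries, species_priority=species)
            if rng.random() < 0.7:  # perturb a catalog entry
                base = entries[int(rng.integers(len(entries)))].sequence
                read = list(base)
                if rng.random() < 0.5:
                    read[int(rng.integers(len(read)))] = "ACGT"[int(rng.integers(4))]
                shift = int(rng.integers(-2, 3))
                read = read[shift:] if shift > 0 else ["A"] * (-shift) + read
                read = "".join(read)
            else:
                read = "".join(rng.choice(list("ACGT"), size=int(rng.integers(18, 26))))
            hits = match_known([read], cat)
            expected = brute_force_best(read, cat)
            if expected is None:
                assert hits == []
            else:
                assert hits, (trial, read)
                h = hits[0]
                assert (h.entry.name, h.left_shift, h.right_shift) == expected[1:]
                assert h.n_substitutions == expected[0][0]


class TestFamily:
    @pytest.mark.parametrize(
        "name,family",
        [
            ("tae-miR159a", "miR159"),
            ("osa-miR168a-5p", "miR168"),
            ("zma-miR169f-5p", "miR169"),
            ("rgl-miR5139", "miR5139"),
            ("xxx-foo", "unknown"),
        ],
    )
    def test_family_from_name(self, name, family):
        assert assign_family(name) == family


class TestPartition:
    def test_every_clean_read_lands_once(self, reference, libraries, config):
        from dinomir.preprocess import FilterRules, classify_and_filter

        reads_a, reads_b = libraries
        clean = classify_and_filter(
            {"A": [s for _, s in reads_a], "B": [s for _, s in reads_b]},
            FilterRules(adapter=config.adapter_seq),
        )
        ann = annotate_reads(clean, reference.catalog)
        hit_reads = {h.read for h in ann.known_hits}
        contam = set(ann.contaminants)
        rest = set(ann.remainder)
        assert contam | hit_reads | rest == set(clean.counts)
        assert not (contam & hit_reads) and not (contam & rest)
        assert not (hit_reads & rest)

    def test_contaminant_totals_match_manifest(self, reference, libraries, config):
        from dinomir.preprocess import FilterRules, classify_and_filter

        reads_a, reads_b = libraries
        clean = classify_and_filter(
            {"A": [s for _, s in reads_a], "B": [s for _, s in reads_b]},
            FilterRules(adapter=config.adapter_seq),
        )
        ann = annotate_reads(clean, reference.catalog)
        man_by_class = {}
        for c in reference.manifest.contaminants:
            if c.cls in ("junk_polyA", "junk_N", "out_of_window"):
                continue
            man_by_class.setdefault(c.cls, [0, 0])
            man_by_class[c.cls][0] += c.expected[0]
            man_by_class[c.cls][1] += c.expected[1]
        got = {}
        for read, cls in ann.contaminants.items():
            got.setdefault(cls, [0, 0])
            got[cls][0] += clean.counts[read][0]
            got[cls][1] += clean.counts[read][1]
        assert {k: list(map(int, v)) for k, v in got.items()} == {
            k: list(map(int, v)) for k, v in man_by_class.items()
        }


class TestOccurrenceHelper:
    def test_matching_species_collects_all(self):
        cat = make_catalog(
            known=[
                CatalogEntry("osa-miR1", MATURE),
                CatalogEntry("tae-miR1", MATURE),
                CatalogEntry("zma-miR2", "G" * 22),
            ],
            species_priority=["osa", "tae", "zma"],
        )
        assert matching_species(MATURE, cat) == {"osa", "tae"}
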