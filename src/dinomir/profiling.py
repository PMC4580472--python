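"""Descriptive profiles of the cleaned small-RNA population.

Covers the standard summaries of a two-library small-RNA study:
per-length read proportions, 5'-first-nucleotide composition by length,
miRNA family sizes and abundances, presence/absence (Venn) sets between
the libraries, and cross-species occurrence of identified miRNAs over
the reference catalog.
"""

from __future__ import annotations

from collections import Counter

import pandas as pd

from .annotate import KnownHit, ReferenceCatalog, matching_species, to_uspace

LENGTH_RANGE = range(18, 26)
BASES = ("A", "C", "G", "U")


def length_distribution(clean) -> pd.DataFrame:
    """Per-length proportion of clean reads in each library.

    Rows: lengths 18-25; columns: one proportion column per library.
    Each column sums to 1 over the observed lengths.
    """
    totals = clean.clean_totals
    if sum(totals) == 0:
        raise ValueError("empty clean read set")
    per_len = {length: [0] * len(clean.libraries) for length in LENGTH_RANGE}
    for seq, per_lib in clean.counts.items():
        row = per_len.setdefault(len(seq), [0] * len(clean.libraries))
        for i, c in enumerate(per_lib):
            row[i] += c
    df = pd.DataFrame(
        {
            "length": sorted(per_len),
            **{
                lib: [
                    per_len[length][i] / totals[i] if totals[i] else 0.0
                    for length in sorted(per_len)
                ]
                for i, lib in enumerate(clean.libraries)
            },
        }
    )
    return df


def first_nt_bias(hits: list[KnownHit]) -> pd.DataFrame:
    """Fraction of distinct identified miRNAs starting with each base,
    per mature length (RNA alphabet; rows with no miRNAs are omitted)."""
    if not hits:
        raise ValueError("no known-miRNA hits to profile")
    seen: dict[int, Counter] = {}
    done = set()
    for h in hits:
        if h.reported_name in done:
            continue
        done.add(h.reported_name)
        seq = to_uspace(h.read)
        seen.setdefault(len(seq), Counter())[seq[0]] += 1
    rows = []
    for length in sorted(seen):
        total = sum(seen[length].values())
        row = {"length": length}
        for b in BASES:
            row[b] = seen[length][b] / total
        rows.append(row)
    return pd.DataFrame(rows)


def family_summary(hits: list[KnownHit], la: int, lb: int) -> pd.DataFrame:
    """Per-family member counts and summed per-million abundance.

    A member is a distinct catalog mature name (variants of the same
    name collapse); abundance sums normalized counts over members.
    """
    members: dict[str, set[str]] = {}
    abundance: dict[str, list[float]] = {}
    for h in hits:
        fam = h.family
        members.setdefault(fam, set()).add(h.entry.name)
        acc = abundance.setdefault(fam, [0.0, 0.0])
        if h.counts:
            acc[0] += 1e6 * h.counts[0] / la
            acc[1] += 1e6 * h.counts[1] / lb
    rows = [
        {
            "family": fam,
            "members": len(mem),
            "abundance_lag": round(abundance[fam][0], 4),
            "abundance_log": round(abundance[fam][1], 4),
        }
        for fam, mem in members.items()
    ]
    return pd.DataFrame(rows).sort_values("family").reset_index(drop=True)


def co_expression(hits: list[KnownHit]) -> dict[str, set[str]]:
    """Presence/absence partition of identified miRNAs between libraries.

    Returns the three sets keyed "A_only", "B_only", "both" (by reported
    name, count > 0 per library).
    """
    in_a: set[str] = set()
    in_b: set[str] = set()
    for h in hits:
        if h.counts and h.counts[0] > 0:
            in_a.add(h.reported_name)
        if h.counts and len(h.counts) > 1 and h.counts[1] > 0:
            in_b.add(h.reported_name)
    return {
        "A_only": in_a - in_b,
        "B_only": in_b - in_a,
        "both": in_a & in_b,
    }


def occurrence(
    hits: list[KnownHit],
    catalog: ReferenceCatalog,
    max_mismatch: int = 1,
    max_shift: int = 2,
) -> pd.DataFrame:
    """Cross-species occurrence: for how many identified miRNAs does each
    catalog species carry a matching entry."""
    counter: Counter = Counter()
    for h in hits:
        for sp in matching_species(h.read, catalog, max_mismatch, max_shift):
            counter[sp] += 1
    df = pd.DataFrame(
        {"species": list(counter), "n_mirnas": [counter[s] for s in counter]}
    )
    return df.sort_values(
        ["n_mirnas", "species"], ascending=[False, True]
    ).reset_index(drop=True)


def plot_length_distribution(dist: pd.DataFrame, path) -> bool:
    """Grouped bar plot of the length distribution; returns False when
    no plotting backend is available."""
    try:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
    except ImportError:
        return False
    libs = [c for c in dist.columns if c != "length"]
    x = dist["length"].to_numpy()
    fig, ax = plt.subplots(figsize=(6, 3.5))
    width = 0.8 / len(libs)
    for i, lib in enumerate(libs):
        ax.bar(x + (i - (len(libs) - 1) / 2) * width, dist[lib], width, label=lib)
    ax.set_xlabel("read length (nt)")
    ax.set_ylabel("proportion of clean reads")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return True
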