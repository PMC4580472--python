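"""Two-library differential expression of miRNA counts.

Counts are normalized to reads per million of each library's clean
total; the effect size is log2(lag / logarithmic) of the normalized
abundances, with +inf / -inf sentinels when one library lacks the
miRNA entirely.  Significance comes from the 2x2 table
[[a, La - a], [b, Lb - b]]: a two-sided Fisher exact test and a 1-df
chi-square without continuity correction are both computed; the call
uses the chi-square p when all expected cells are >= 5 (the printed
convention) and the Fisher p otherwise.  A miRNA is differentially
expressed when |log2FC| > 1 and p < 0.05, and "significant" when
additionally p < 0.01.  Bonferroni-adjusted p values are reported; by
default the raw p gates the call (``use_adjusted`` switches this).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd
from scipy import stats


def normalize(count: float, library_size: float) -> float:
    """Reads-per-million normalization: 1e6 * count / library_size."""
    if library_size <= 0:
        raise ValueError("library_size must be positive")
    if count < 0:
        raise ValueError("count must be non-negative")
    return 1e6 * count / library_size


def fold_change(na: float, nb: float) -> float:
    """log2(na / nb) with infinity sentinels for presence/absence.

    na, nb are normalized abundances (lag, logarithmic).  Both zero is
    undefined and raises.
    """
    if na < 0 or nb < 0:
        raise ValueError("normalized abundances must be non-negative")
    if na == 0 and nb == 0:
        raise ValueError("fold change undefined when both abundances are zero")
    if na == 0:
        return -math.inf
    if nb == 0:
        return math.inf
    return math.log2(na / nb)


def test(a: int, b: int, la: int, lb: int) -> tuple[float, float]:
    """(Fisher two-sided p, chi-square 1-df p) for the 2x2 count table.

    Table: [[a, La - a], [b, Lb - b]].  The chi-square uses no
    continuity correction; a degenerate table (a == b == 0, or any zero
    margin) yields p = 1 for both.
    """
    if a < 0 or b < 0 or la < a or lb < b:
        raise ValueError("need 0 <= a <= La and 0 <= b <= Lb")
    table = [[a, la - a], [b, lb - b]]
    if a + b == 0 or (la - a) + (lb - b) == 0:
        return 1.0, 1.0
    _, p_fisher = stats.fisher_exact(table, alternative="two-sided")
    chi2, p_chi, _, _ = stats.chi2_contingency(table, correction=False)
    return float(p_fisher), float(p_chi)


def expected_cells_ok(a: int, b: int, la: int, lb: int, min_expected: float = 5.0):
    """True when all expected cell counts of the 2x2 table are >= 5."""
    n = la + lb
    row1, row2 = a + b, (la - a) + (lb - b)
    expected = [row1 * la / n, row1 * lb / n, row2 * la / n, row2 * lb / n]
    return min(expected) >= min_expected


@dataclass(frozen=True)
class DERecord:
    """Per-miRNA differential-expression result."""

    mirna: str
    a: int  # raw count, lag phase
    b: int  # raw count, logarithmic phase
    la: int  # clean totals (library sizes)
    lb: int
    na: float  # per-million
    nb: float
    log2fc: float  # +-inf capable
    p_fisher: float
    p_chisq: float
    p: float  # the gating p (chi-square when valid, else Fisher)
    p_adj: float  # Bonferroni
    call: str  # "up" | "down" | "ns"
    significant_01: bool


def classify(
    log2fc: float,
    p: float,
    fc_thresh: float = 1.0,
    p_thresh: float = 0.05,
    strict_thresh: float = 0.01,
) -> tuple[str, bool]:
    """DE call from effect size and p value.

    Returns (call, significant) where call is "up"/"down"/"ns" by the
    sign of log2FC (infinite values exceed any finite threshold) and
    significant additionally requires p < ``strict_thresh``.
    """
    de = abs(log2fc) > fc_thresh and p < p_thresh
    if not de:
        return "ns", False
    call = "up" if log2fc > 0 else "down"
    return call, p < strict_thresh


def differential_expression(
    counts: dict[str, tuple[int, int]],
    la: int,
    lb: int,
    fc_thresh: float = 1.0,
    p_thresh: float = 0.05,
    strict_thresh: float = 0.01,
    use_adjusted: bool = False,
) -> list[DERecord]:
    """Full DE analysis over a name -> (count_lag, count_log) table.

    Records with zero counts in both libraries are dropped (undefined
    fold change).  Bonferroni multiplicity = number of miRNAs tested.
    """
    tested = {m: ab for m, ab in counts.items() if ab[0] + ab[1] > 0}
    m_tests = len(tested)
    records = []
    for mirna, (a, b) in sorted(tested.items()):
        na, nb = normalize(a, la), normalize(b, lb)
        lfc = fold_change(na, nb)
        p_fisher, p_chi = test(a, b, la, lb)
        p = p_chi if expected_cells_ok(a, b, la, lb) else p_fisher
        p_adj = min(1.0, p * m_tests)
        gate = p_adj if use_adjusted else p
        call, sig = classify(lfc, gate, fc_thresh, p_thresh, strict_thresh)
        records.append(
            DERecord(
                mirna=mirna,
                a=a,
                b=b,
                la=la,
                lb=lb,
                na=na,
                nb=nb,
                log2fc=lfc,
                p_fisher=p_fisher,
                p_chisq=p_chi,
                p=p,
                p_adj=p_adj,
                call=call,
                significant_01=sig,
            )
        )
    return records


def _fmt_fc(x: float) -> str:
    if math.isinf(x):
        return "+inf" if x > 0 else "-inf"
    return f"{x:.2f}"


def to_frame(records: list[DERecord]) -> pd.DataFrame:
    """DE table with the conventional columns (log2FC serialized with
    "+inf"/"-inf" sentinels)."""
    return pd.DataFrame(
        {
            "miRNA": [r.mirna for r in records],
            "count_lag": [r.a for r in records],
            "count_log": [r.b for r in records],
            "norm_lag": [round(r.na, 4) for r in records],
            "norm_log": [round(r.nb, 4) for r in records],
            "log2fc": [_fmt_fc(r.log2fc) for r in records],
            "p_fisher": [r.p_fisher for r in records],
            "p_chisq": [r.p_chisq for r in records],
            "p": [r.p for r in records],
            "p_adj": [r.p_adj for r in records],
            "call": [r.call for r in records],
            "significant_01": [r.significant_01 for r in records],
        }
    )
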