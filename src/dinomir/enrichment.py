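"""Term enrichment of predicted miRNA target genes.

Given a background of N annotated genes, n of them targets of
differentially expressed miRNAs, a term annotating M genes of which m
are targets, the enrichment p value is the hypergeometric upper tail

    P = 1 - sum_{i=0}^{m-1} C(M, i) C(N-M, n-i) / C(N, n)
      = P(X >= m),  X ~ Hypergeom(N, M, n)

evaluated in exact rational arithmetic; the one-sided Fisher exact test
on the table [[m, n-m], [M-m, N-M-(n-m)]] is identical by construction
and reported alongside.  Terms with p < 0.05 are flagged enriched; no
multiple-testing correction is applied by default (an optional
Benjamini-Hochberg q value can be requested).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from fractions import Fraction
from math import comb

import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)


def _check(n_bg: int, n_tgt: int, m_term: int, m_hit: int) -> None:
    if not (
        max(0, n_tgt + m_term - n_bg) <= m_hit <= min(n_tgt, m_term)
        and n_tgt <= n_bg
        and m_term <= n_bg
    ):
        raise ValueError(
            f"invalid enrichment counts N={n_bg}, n={n_tgt}, M={m_term}, m={m_hit}"
        )


def hypergeom_p(n_bg: int, n_tgt: int, m_term: int, m_hit: int) -> float:
    """Upper-tail hypergeometric P(X >= m), exact rational evaluation.

    Arguments follow the conventional letters: N (background), n
    (targets), M (term-annotated), m (term-annotated targets).
    """
    _check(n_bg, n_tgt, m_term, m_hit)
    if m_hit == 0:
        return 1.0
    total = comb(n_bg, n_tgt)
    acc = Fraction(0)
    for i in range(m_hit):
        acc += Fraction(comb(m_term, i) * comb(n_bg - m_term, n_tgt - i), total)
    return float(1 - acc)


def fisher_p(n_bg: int, n_tgt: int, m_term: int, m_hit: int) -> float:
    """One-sided (enrichment-tail) Fisher exact p.

    Table [[m, n-m], [M-m, N-M-(n-m)]]; equals the hypergeometric upper
    tail.  Computed with scipy as an independent code path.
    """
    _check(n_bg, n_tgt, m_term, m_hit)
    table = [
        [m_hit, n_tgt - m_hit],
        [m_term - m_hit, (n_bg - m_term) - (n_tgt - m_hit)],
    ]
    _, p = stats.fisher_exact(table, alternative="greater")
    return float(p)


@dataclass(frozen=True)
class EnrichmentResult:
    term: str
    label: str
    n_bg: int
    n_tgt: int
    m_term: int
    m_hit: int
    p_hypergeom: float
    p_fisher: float
    enriched: bool
    q_bh: float | None = None


def enrich(
    targets: set[str],
    annotation: dict[str, set[str]],
    background: set[str] | None = None,
    labels: dict[str, str] | None = None,
    alpha: float = 0.05,
    bh_correction: bool = False,
) -> list[EnrichmentResult]:
    """Per-term enrichment over an annotation map.

    ``annotation`` maps gene -> set of term ids; the background defaults
    to all annotated genes.  Target genes absent from the background are
    excluded from n (and logged).  Results are sorted by (p, term id).
    """
    if not annotation:
        raise ValueError("annotation map is empty")
    background = set(annotation) if background is None else set(background)
    dropped = targets - background
    if dropped:
        log.info("%d target genes outside the background excluded", len(dropped))
    tgt = targets & background
    n_bg, n_tgt = len(background), len(tgt)

    term_genes: dict[str, set[str]] = {}
    for gene, terms in annotation.items():
        if gene not in background:
            continue
        for t in terms:
            term_genes.setdefault(t, set()).add(gene)

    results = []
    for term, genes in term_genes.items():
        m_term = len(genes)
        m_hit = len(genes & tgt)
        p_h = hypergeom_p(n_bg, n_tgt, m_term, m_hit)
        p_f = fisher_p(n_bg, n_tgt, m_term, m_hit)
        results.append(
            EnrichmentResult(
                term=term,
                label=(labels or {}).get(term, term),
                n_bg=n_bg,
                n_tgt=n_tgt,
                m_term=m_term,
                m_hit=m_hit,
                p_hypergeom=p_h,
                p_fisher=p_f,
                enriched=p_h < alpha,
            )
        )
    results.sort(key=lambda r: (r.p_hypergeom, r.term))
    if bh_correction:
        m = len(results)
        qs = [r.p_hypergeom * m / (i + 1) for i, r in enumerate(results)]
        for i in range(m - 2, -1, -1):  # enforce monotonicity
            qs[i] = min(qs[i], qs[i + 1])
        results = [
            EnrichmentResult(
                **{**r.__dict__, "q_bh": min(1.0, q)}
            )
            for r, q in zip(results, qs)
        ]
    return results


def read_annotation_tsv(path) -> dict[str, set[str]]:
    """Two-column TSV (gene, term) -> gene -> set of terms."""
    df = pd.read_csv(path, sep="\t", header=None, names=["gene", "term"], dtype=str)
    out: dict[str, set[str]] = {}
    for gene, term in zip(df["gene"], df["term"]):
        out.setdefault(gene, set()).add(term)
    return out


def read_target_list(path) -> set[str]:
    """One-column TSV of target gene ids."""
    with open(path) as fh:
        return {ln.strip() for ln in fh if ln.strip()}


def to_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    cols = {
        "term": [r.term for r in results],
        "label": [r.label for r in results],
        "N": [r.n_bg for r in results],
        "n": [r.n_tgt for r in results],
        "M": [r.m_term for r in results],
        "m": [r.m_hit for r in results],
        "p_hypergeom": [r.p_hypergeom for r in results],
        "p_fisher": [r.p_fisher for r in results],
        "enriched": [r.enriched for r in results],
    }
    if results and results[0].q_bh is not None:
        cols["q_bh"] = [r.q_bh for r in results]
    return pd.DataFrame(cols)
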