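"""Report arithmetic and the published reference tables.

The percentage routine used in every accounting table lives here, plus
loaders for three reference tables from the original two-growth-phase
*Alexandrium catenella* small-RNA study, shipped as package data:

* library accounting (raw / filter / junk / contaminant / clean counts),
* the 15 reported novel miRNA precursors (length, GC%, dG),
* the 12 reported differentially expressed known miRNAs.

These serve as demonstration inputs and as fixtures for validating the
report arithmetic; the pipeline itself never depends on them.
"""

from __future__ import annotations

import math
from importlib import resources

import pandas as pd


def percentage(part: float, total: float, digits: int = 2) -> float:
    """100 * part / total, rounded to ``digits`` decimal places."""
    if total == 0:
        raise ZeroDivisionError("percentage of a zero total")
    return round(100.0 * part / total, digits)


def _data_path(name: str):
    return resources.files("dinomir").joinpath("data", name)


def published_library_stats() -> pd.DataFrame:
    """Library accounting of the reference study (reads per category,
    total and unique, for the lag and logarithmic phase libraries)."""
    with resources.as_file(_data_path("acatenella_library_stats.tsv")) as p:
        return pd.read_csv(p, sep="\t")


def published_novel_mirnas() -> pd.DataFrame:
    """The 15 reported novel miRNA precursors with mature sequence,
    precursor length, GC% and folding dG (kcal/mol)."""
    with resources.as_file(_data_path("acatenella_novel_mirnas.tsv")) as p:
        return pd.read_csv(p, sep="\t")


def published_de_mirnas() -> pd.DataFrame:
    """The 12 reported differentially expressed miRNAs: log2 fold change
    (lag / logarithmic; +-inf for presence/absence), chi-square p, call."""
    with resources.as_file(_data_path("acatenella_de_mirnas.tsv")) as p:
        df = pd.read_csv(p, sep="\t")
    df["log2fc"] = [
        math.inf if str(x) == "+inf" else (-math.inf if str(x) == "-inf" else float(x))
        for x in df["log2fc"]
    ]
    return df


def accounting_table(clean_accounting: pd.DataFrame, contaminant_report) -> pd.DataFrame:
    """Combined per-category accounting table for a pipeline run.

    Stacks the preprocessing categories with the contaminant classes, in
    the conventional row order, one block per library.
    """
    pre = clean_accounting.copy()
    if contaminant_report is None or contaminant_report.empty:
        return pre
    cont = contaminant_report[["category", "library", "total", "unique"]]
    return pd.concat([pre, cont], ignore_index=True)
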