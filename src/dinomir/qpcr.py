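"""Relative expression by the comparative-threshold (2^-ddCt) method.

Ct values of the target miRNA are normalized against a reference gene
(here the 5.8S rRNA) within each sample, then against a calibrator
sample:

    dCt(sample)  = mean Ct(target) - mean Ct(reference)
    ddCt         = dCt(sample) - dCt(calibrator)
    expression   = 2^-ddCt

The standard error is propagated from the replicate Ct standard
deviations; a two-sided paired t-test on per-replicate dCt values
against the calibrator gives significance tiers at 0.05 and 0.01.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class CtTable:
    """Long-format Ct measurements.

    ``data`` columns: sample, gene, replicate, ct.  ``reference`` is the
    normalizer gene; ``calibrator`` the baseline sample.
    """

    data: pd.DataFrame
    reference: str
    calibrator: str

    def __post_init__(self) -> None:
        required = {"sample", "gene", "replicate", "ct"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"Ct table missing columns: {sorted(missing)}")
        if (self.data["ct"] <= 0).any():
            raise ValueError("Ct values must be positive")
        for sample in self.data["sample"].unique():
            sub = self.data[self.data["sample"] == sample]
            if not (sub["gene"] == self.reference).any():
                raise ValueError(f"sample {sample!r} has no reference-gene rows")

    @classmethod
    def from_csv(cls, path, reference: str, calibrator: str) -> "CtTable":
        return cls(pd.read_csv(path), reference=reference, calibrator=calibrator)

    def _ct(self, sample: str, gene: str) -> np.ndarray:
        sub = self.data[(self.data["sample"] == sample) & (self.data["gene"] == gene)]
        if sub.empty:
            raise ValueError(f"no Ct rows for gene {gene!r} in sample {sample!r}")
        return sub["ct"].to_numpy(float)


@dataclass(frozen=True)
class RelativeExpression:
    sample: str
    gene: str
    ddct: float
    expression: float  # 2^-ddCt
    se: float  # propagated standard error on the expression scale
    p_value: float | None  # paired t vs calibrator dCt; None for calibrator
    significance: str  # "", "*" (p<0.05) or "**" (p<0.01)


def ddct(table: CtTable, gene: str, sample: str) -> RelativeExpression:
    """Relative expression of ``gene`` in ``sample`` vs the calibrator."""
    ct_t = table._ct(sample, gene)
    ct_r = table._ct(sample, table.reference)
    ct_tc = table._ct(table.calibrator, gene)
    ct_rc = table._ct(table.calibrator, table.reference)

    dct = ct_t.mean() - ct_r.mean()
    dct_cal = ct_tc.mean() - ct_rc.mean()
    dd = dct - dct_cal
    expr = 2.0 ** (-dd)

    # SE of ddCt from the four replicate groups, then delta-method to 2^-x
    var = sum(
        a.var(ddof=1) / a.size if a.size > 1 else 0.0
        for a in (ct_t, ct_r, ct_tc, ct_rc)
    )
    se_dd = math.sqrt(var)
    se_expr = expr * math.log(2) * se_dd

    p = None
    sig = ""
    if sample != table.calibrator:
        d_s = _replicate_dct(table, gene, sample)
        d_c = _replicate_dct(table, gene, table.calibrator)
        k = min(len(d_s), len(d_c))
        if k >= 2:
            _, p = stats.ttest_rel(d_s[:k], d_c[:k])
            p = float(p)
            sig = "**" if p < 0.01 else ("*" if p < 0.05 else "")
    else:
        expr = 1.0  # exact by definition
    return RelativeExpression(
        sample=sample, gene=gene, ddct=dd, expression=expr, se=se_expr,
        p_value=p, significance=sig,
    )


def _replicate_dct(table: CtTable, gene: str, sample: str) -> np.ndarray:
    """Per-replicate dCt values (target minus reference, paired on the
    replicate label; biological replicates are the test unit)."""
    sub = table.data[table.data["sample"] == sample]
    t = sub[sub["gene"] == gene].set_index("replicate")["ct"]
    r = sub[sub["gene"] == table.reference].set_index("replicate")["ct"]
    common = t.index.intersection(r.index)
    return (t.loc[common].to_numpy(float) - r.loc[common].to_numpy(float))


def relative_expression_table(table: CtTable, gene: str) -> pd.DataFrame:
    """2^-ddCt of one target gene across all samples."""
    rows = []
    for sample in table.data["sample"].unique():
        if not ((table.data["sample"] == sample) & (table.data["gene"] == gene)).any():
            continue
        r = ddct(table, gene, sample)
        rows.append(
            {
                "sample": r.sample,
                "gene": r.gene,
                "ddct": round(r.ddct, 4),
                "expression": round(r.expression, 4),
                "se": round(r.se, 4),
                "p_value": r.p_value,
                "significance": r.significance,
            }
        )
    return pd.DataFrame(rows)
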