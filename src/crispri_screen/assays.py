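"""Low-throughput follow-up quantifications: growth curves and qPCR.

``curve_auc`` / ``relative_growth`` summarize plate-reader OD curves the
way single-strain validation assays are scored: the mean of the first ten
OD readings sets the baseline, the area under the curve is the plain sum
of baseline-subtracted readings, and relative growth compares a treatment
curve with the same-plate reference.  ``ddct`` computes qPCR log2 fold
changes as the negative delta-delta-Ct with error propagation across
replicate wells.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

BASELINE_READINGS = 10


@dataclass
class GrowthCurve:
    """One well's OD time course."""

    times: np.ndarray  # minutes
    ods: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.ods = np.asarray(self.ods, dtype=float)
        if len(self.times) != len(self.ods):
            raise ValueError("times and ODs differ in length")
        if len(self.ods) < BASELINE_READINGS:
            raise ValueError(f"need >= {BASELINE_READINGS} readings to set a baseline")
        if (np.diff(self.times) <= 0).any():
            raise ValueError("time points must be strictly increasing")


def curve_auc(curve: GrowthCurve, trapezoid: bool = False) -> float:
    """Baseline-subtracted area under a growth curve.

    The mean of the first ten readings is subtracted from every reading;
    the AUC is the sum of the result.  ``trapezoid=True`` integrates over
    time instead (units OD*min); the plain sum is the default scoring.
    """
    baseline = curve.ods[:BASELINE_READINGS].mean()
    adj = curve.ods - baseline
    if trapezoid:
        return float(np.trapezoid(adj, curve.times))
    return float(adj.sum())


def relative_growth(condition: GrowthCurve, control: GrowthCurve, **auc_kwargs) -> float:
    """(AUC_condition - AUC_control) / AUC_control; 0 = control-like,
    -1 = complete growth inhibition."""
    auc_ctrl = curve_auc(control, **auc_kwargs)
    if auc_ctrl == 0:
        raise ZeroDivisionError("control AUC is zero")
    return (curve_auc(condition, **auc_kwargs) - auc_ctrl) / auc_ctrl


def curves_from_table(table: pd.DataFrame) -> dict:
    """Build GrowthCurves from a long-format plate table (well, time, od)."""
    out = {}
    meta_cols = [c for c in table.columns if c not in ("well", "time", "od")]
    for well, sub in table.groupby("well"):
        sub = sub.sort_values("time")
        meta = {c: sub[c].iloc[0] for c in meta_cols}
        out[well] = GrowthCurve(sub["time"].to_numpy(), sub["od"].to_numpy(), meta)
    return out


def ddct(
    ct: pd.DataFrame,
    gene: str,
    control_gene: str,
    test_condition: str,
    reference_condition: str,
) -> tuple[float, float]:
    """Negative delta-delta-Ct log2 fold change with propagated stdev.

    ``ct`` is long-format with columns gene, condition, ct (one row per
    replicate well).  DDCt = (Ct_gene - Ct_control)_test -
    (Ct_gene - Ct_control)_reference, computed on replicate-mean Ct
    values; the returned log2 fold change is -DDCt, and the stdev is
    sqrt(sd(Ct_gene)^2 + sd(Ct_control)^2) over the test-condition
    replicates.
    """

    def cell(g, cond):
        vals = ct.loc[(ct["gene"] == g) & (ct["condition"] == cond), "ct"]
        if len(vals) == 0:
            raise KeyError(f"no Ct values for gene {g!r} in condition {cond!r}")
        return vals

    d_test = cell(gene, test_condition).mean() - cell(control_gene, test_condition).mean()
    d_ref = cell(gene, reference_condition).mean() - cell(control_gene, reference_condition).mean()
    sd_gene = cell(gene, test_condition).std(ddof=1)
    sd_ctrl = cell(control_gene, test_condition).std(ddof=1)
    sd_gene = 0.0 if math.isnan(sd_gene) else sd_gene
    sd_ctrl = 0.0 if math.isnan(sd_ctrl) else sd_ctrl
    return float(-(d_test - d_ref)), float(math.sqrt(sd_gene**2 + sd_ctrl**2))
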