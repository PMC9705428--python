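"""Wet-lab assay quantification formulas.

qPCR standard curves (Ct vs log10 input), chromatin-conformation (3C) ligation
frequencies derived from a standard curve as ``10^((Ct - intercept)/slope)``
normalized to a loading-control amplicon, delta-delta-Ct fold changes with a
reference gene, and dual-luciferase firefly/renilla normalization.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "StandardCurve",
    "fit_standard_curve",
    "quantify_3c",
    "fold_change_ddct",
    "luciferase_relative_activity",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class StandardCurve:
    """Fitted qPCR dilution series: ct = slope * log10(input) + intercept."""

    slope: float
    intercept: float
    r2_fit: float

    @property
    def efficiency(self) -> float:
        """Amplification efficiency implied by the slope (2 means perfect doubling)."""
        return 10.0 ** (-1.0 / self.slope)


def fit_standard_curve(dilution_log10, ct) -> StandardCurve:
    """Least-squares line through (log10 dilution, Ct) points."""
    x = np.asarray(dilution_log10, dtype=float)
    y = np.asarray(ct, dtype=float)
    if len(np.unique(x)) < 2:
        raise ValueError("fit_standard_curve: need >= 2 distinct dilution values")
    res = stats.linregress(x, y)
    if res.slope == 0:
        raise ValueError("fit_standard_curve: zero slope, curve uninformative")
    return StandardCurve(float(res.slope), float(res.intercept), float(res.rvalue**2))


def quantify_3c(ct: float, curve: StandardCurve, reference_value: float = 1.0) -> float:
    """Crosslinking frequency: 10^((Ct - intercept)/slope), over a loading control.

    ``reference_value`` is the same formula evaluated on the loading-control
    amplicon (e.g. ERCC3); pass 1.0 for the raw value.
    """
    if reference_value <= 0:
        raise ValueError("quantify_3c: reference_value must be > 0")
    raw = 10.0 ** ((ct - curve.intercept) / curve.slope)
    return raw / reference_value


def fold_change_ddct(
    ct_table: pd.DataFrame,
    target: str,
    reference: str,
    control_condition: str,
) -> pd.DataFrame:
    """Delta-delta-Ct fold changes: 2^-(dCt_condition - dCt_control).

    ``ct_table`` needs columns ``target`` (the assayed gene label),
    ``condition`` and ``ct``; replicate Cts are averaged on the Ct scale
    first. dCt = Ct_target - Ct_reference per condition; the control
    condition's fold is exactly 1 by construction.
    """
    means = ct_table.groupby(["condition", "target"])["ct"].mean()
    conditions = sorted(ct_table["condition"].unique())
    if control_condition not in conditions:
        raise ValueError(f"control condition {control_condition!r} absent from table")
    dct = {}
    for cond in conditions:
        try:
            dct[cond] = means[(cond, target)] - means[(cond, reference)]
        except KeyError as exc:
            raise ValueError(
                f"condition {cond!r}: missing Ct for target or reference gene"
            ) from exc
    rows = [
        (cond, dct[cond], dct[cond] - dct[control_condition],
         2.0 ** -(dct[cond] - dct[control_condition]))
        for cond in conditions
    ]
    return pd.DataFrame(rows, columns=["condition", "dct", "ddct", "fold"]).set_index("condition")


def luciferase_relative_activity(
    wells: pd.DataFrame, baseline_construct: str
) -> pd.DataFrame:
    """Dual-luciferase activity relative to a baseline (promoter-only) construct.

    ``wells`` needs columns ``construct``, ``firefly``, ``renilla``; each well's
    ratio is firefly/renilla, wells with renilla <= 0 are excluded (logged).
    Per construct the mean ratio, SD and well count are reported, with
    activity expressed relative to the baseline construct's mean.
    """
    bad = wells["renilla"] <= 0
    if bad.any():
        logger.warning("luciferase: excluding %d wells with nonpositive renilla", int(bad.sum()))
    ok = wells[~bad].copy()
    if baseline_construct not in set(ok["construct"]):
        raise ValueError(f"baseline construct {baseline_construct!r} absent (or all wells invalid)")
    ok["ratio"] = ok["firefly"] / ok["renilla"]
    g = ok.groupby("construct")["ratio"]
    out = pd.DataFrame({"mean_ratio": g.mean(), "sd_ratio": g.std(ddof=1), "n_wells": g.size()})
    out["relative_activity"] = out["mean_ratio"] / out.loc[baseline_construct, "mean_ratio"]
    return out
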