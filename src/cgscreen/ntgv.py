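"""Liquid-culture validation statistics.

The Net Treated Growth Value (NTGV) normalises a strain's endpoint OD600
under drug for both its own untreated growth and the wild-type response:

    NTGV = (OD_strain,treated / OD_wt,treated)
         / (OD_strain,untreated / OD_wt,untreated)

Strains with NTGV <= 0.7 are called sensitive and NTGV >= 1.2 resistant.
The simpler fraction-of-control statistic is the plain treated/untreated
OD ratio for a single strain, with no wild-type normalisation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synth import WT_STRAIN

NTGV_SENSITIVE_CUT = 0.7
NTGV_RESISTANT_CUT = 1.2


@dataclass
class NTGVResult:
    strain_id: str
    condition: float
    ntgv: float | None
    classification: str
    reason: str = ""


def classify_ntgv(
    value: float,
    sensitive_cut: float = NTGV_SENSITIVE_CUT,
    resistant_cut: float = NTGV_RESISTANT_CUT,
) -> str:
    # both thresholds inclusive
    if value <= sensitive_cut:
        return "sensitive"
    if value >= resistant_cut:
        return "resistant"
    return "unaffected"


def ntgv(
    strain_treated,
    strain_untreated,
    wt_treated,
    wt_untreated,
    strain_id: str = "",
    condition: float = float("nan"),
    sensitive_cut: float = NTGV_SENSITIVE_CUT,
    resistant_cut: float = NTGV_RESISTANT_CUT,
    per_replicate_ratios: bool = False,
) -> NTGVResult:
    """Compute one NTGV from replicate OD vectors (or scalars).

    Replicate ODs are averaged on the OD scale before the double ratio is
    formed (default); ``per_replicate_ratios=True`` instead forms the
    ratio per replicate and averages the ratios.
    """
    arrs = [np.atleast_1d(np.asarray(x, dtype=float)) for x in
            (strain_treated, strain_untreated, wt_treated, wt_untreated)]
    st, su, wt, wu = arrs
    if su.mean() <= 0 or wt.mean() <= 0 or wu.mean() <= 0:
        return NTGVResult(strain_id, condition, None, "unevaluable", "zero denominator")
    if per_replicate_ratios:
        n = min(map(len, arrs))
        vals = (st[:n] / wt[:n]) / (su[:n] / wu[:n])
        value = float(vals.mean())
    else:
        value = float((st.mean() / wt.mean()) / (su.mean() / wu.mean()))
    return NTGVResult(strain_id, condition, value, classify_ntgv(value, sensitive_cut, resistant_cut))


def ntgv_table(
    od: pd.DataFrame,
    wt_strain: str = WT_STRAIN,
    sensitive_cut: float = NTGV_SENSITIVE_CUT,
    resistant_cut: float = NTGV_RESISTANT_CUT,
    per_replicate_ratios: bool = False,
) -> pd.DataFrame:
    """NTGV per (strain, treated condition) from a long-format OD table.

    Expects columns strain_id, condition (0 = untreated), replicate,
    od600, batch; the wild-type reference is batch-matched.
    """
    rows = []
    for batch, grp in od.groupby("batch"):
        wt = grp[grp["strain_id"] == wt_strain]
        if wt.empty:
            raise ValueError(f"batch {batch!r} lacks wild-type reference rows")
        wt_by_cond = {c: g["od600"].to_numpy() for c, g in wt.groupby("condition")}
        for strain, sgrp in grp[grp["strain_id"] != wt_strain].groupby("strain_id"):
            by_cond = {c: g["od600"].to_numpy() for c, g in sgrp.groupby("condition")}
            for cond in sorted(c for c in by_cond if c > 0):
                if 0.0 not in by_cond or cond not in wt_by_cond or 0.0 not in wt_by_cond:
                    res = NTGVResult(strain, cond, None, "unevaluable", "missing reference")
                else:
                    res = ntgv(
                        by_cond[cond], by_cond[0.0], wt_by_cond[cond], wt_by_cond[0.0],
                        strain_id=strain, condition=cond,
                        sensitive_cut=sensitive_cut, resistant_cut=resistant_cut,
                        per_replicate_ratios=per_replicate_ratios,
                    )
                rows.append(
                    {
                        "strain_id": res.strain_id,
                        "batch": batch,
                        "condition": res.condition,
                        "ntgv": res.ntgv,
                        "classification": res.classification,
                        "reason": res.reason,
                    }
                )
    return pd.DataFrame(rows)


def fraction_of_control(treated, untreated) -> tuple[float, float]:
    """Mean +/- sample SD of per-replicate treated/untreated OD ratios.

    This is the endpoint statistic reported for single-strain liquid
    growth assays; unlike NTGV it carries no wild-type normalisation.
    """
    t = np.atleast_1d(np.asarray(treated, dtype=float))
    u = np.atleast_1d(np.asarray(untreated, dtype=float))
    if np.any(u <= 0):
        raise ValueError("untreated OD must be > 0")
    ratios = t / u
    sd = float(ratios.std(ddof=1)) if ratios.size > 1 else 0.0
    return float(ratios.mean()), sd


def format_mean_sd(mean: float, sd: float, digits: int = 2) -> str:
    """Render the conventional 'mean ± SD' string, e.g. '0.26 ± 0.18'."""
    return f"{mean:.{digits}f} ± {sd:.{digits}f}"
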