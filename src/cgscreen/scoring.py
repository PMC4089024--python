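"""Ordinal scoring and classification of spotted-growth screens.

Each spot is compared with the strain's own untreated growth and the
wild-type control via the relative growth ratio

    r = (strain_treated / strain_untreated) / (wt_treated / wt_untreated)

so that r = 1 means the strain responds to the drug exactly like
wild-type.  The ratio is graded onto the screen's ordinal scale
(3 = strong sensitivity ... 0 = wild-type-like ... -2 = strong
resistance), spot scores are summed across concentrations and biological
replicates into a final score, and strains are classified sensitive
(final score >= 3), resistant (final score <= -2) or unaffected.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .synth import PlateLayout, WT_STRAIN, SENS_CONTROL_STRAIN

UNSCOREABLE = None

#: default ratio bins mapping r -> ordinal score; upper bound is inclusive
#: on the sensitive side.  (upper_r, score) pairs in ascending r order,
#: the final open interval scoring -2.
DEFAULT_BINS: tuple[tuple[float, int], ...] = (
    (0.10, 3),
    (0.35, 2),
    (0.60, 1),
    (1.30, 0),   # 0.60 < r < 1.30 : wild-type-like (exclusive upper edge)
    (1.75, -1),  # 1.30 <= r < 1.75
)
SENSITIVE_CUT = 3
RESISTANT_CUT = -2

CLASS_NO_DATA = "no-data"


class BinConfigError(ValueError):
    """Raised for non-monotone ratio-bin configurations."""


def relative_growth_ratio(
    strain_treated: float,
    strain_untreated: float,
    wt_treated: float,
    wt_untreated: float,
) -> float | None:
    """Growth of a strain under drug relative to wild-type, double ratio.

    Returns None (unscoreable) rather than raising when a denominator is
    non-positive — a strain that failed to grow without drug, or a failed
    wild-type control, must not abort a whole screen.
    """
    if strain_untreated is None or not strain_untreated > 0:
        return UNSCOREABLE
    if wt_treated is None or wt_untreated is None or not (wt_treated > 0 and wt_untreated > 0):
        return UNSCOREABLE
    if strain_treated is None or strain_treated < 0 or math.isnan(strain_treated):
        return UNSCOREABLE
    return (strain_treated / strain_untreated) / (wt_treated / wt_untreated)


def _validate_bins(bins: tuple[tuple[float, int], ...]) -> None:
    uppers = [b for b, _ in bins]
    scores = [s for _, s in bins]
    if any(b2 <= b1 for b1, b2 in zip(uppers, uppers[1:])):
        raise BinConfigError("bin upper bounds must be strictly increasing")
    if any(s2 >= s1 for s1, s2 in zip(scores, scores[1:])):
        raise BinConfigError("bin scores must be strictly decreasing with r")


def grade_spot(r: float | None, bins: tuple[tuple[float, int], ...] = DEFAULT_BINS) -> int | None:
    """Map a relative growth ratio to an ordinal spot score.

    The sensitive-side boundaries are inclusive (r <= bound) so a ratio
    sitting exactly on an edge takes the stronger sensitivity grade,
    except the wild-type bin whose upper edge belongs to the resistant
    side (1.30 grades -1).  Unscoreable spots (r is None) stay None and
    are excluded from aggregation.
    """
    if r is UNSCOREABLE or r is None or (isinstance(r, float) and math.isnan(r)):
        return None
    if r < 0:
        return None
    _validate_bins(bins)
    for i, (upper, score) in enumerate(bins):
        if score > 0 or score == 0:
            inclusive = score != 0  # sensitive-side edges inclusive
        else:
            inclusive = False
        if (r <= upper) if inclusive else (r < upper):
            return score
    return bins[-1][1] - 1 if bins[-1][1] <= 0 else -2


@dataclass
class ScreenScore:
    """Aggregate result for one strain."""

    strain_id: str
    final_score: int
    n_spots_scored: int
    classification: str


def aggregate_and_classify(
    strain_id: str,
    spot_scores: list[int | None],
    sensitive_cut: int = SENSITIVE_CUT,
    resistant_cut: int = RESISTANT_CUT,
    n_design_spots: int | None = None,
) -> ScreenScore:
    """Sum spot scores into a final score and classify the strain.

    Unscoreable spots (None) contribute nothing — they are dropped, not
    zeroed.  If fewer than half of the designed spots were scored the
    strain is reported as "no-data" rather than risk classifying from a
    single surviving replicate.
    """
    scored = [s for s in spot_scores if s is not None]
    n = len(scored)
    if n == 0:
        return ScreenScore(strain_id, 0, 0, CLASS_NO_DATA)
    if n_design_spots is not None and n < math.ceil(n_design_spots / 2):
        return ScreenScore(strain_id, int(sum(scored)), n, CLASS_NO_DATA)
    final = int(sum(scored))
    if final >= sensitive_cut:
        cls = "sensitive"
    elif final <= resistant_cut:
        cls = "resistant"
    else:
        cls = "unaffected"
    return ScreenScore(strain_id, final, n, cls)


@dataclass
class PlateQCReport:
    """Pass/fail record of control-well behaviour per plate and replicate."""

    passed: list[tuple[str, int]] = field(default_factory=list)
    failed: list[tuple[str, int, str]] = field(default_factory=list)
    unevaluable: list[tuple[str, int, str]] = field(default_factory=list)

    def plate_rep_ok(self, plate_id: str, replicate: int) -> bool:
        return (plate_id, replicate) in set(self.passed)

    def to_frame(self) -> pd.DataFrame:
        rows = (
            [{"plate_id": p, "replicate": r, "status": "pass", "reason": ""} for p, r in self.passed]
            + [{"plate_id": p, "replicate": r, "status": "fail", "reason": why} for p, r, why in self.failed]
            + [
                {"plate_id": p, "replicate": r, "status": "unevaluable", "reason": why}
                for p, r, why in self.unevaluable
            ]
        )
        return pd.DataFrame(rows, columns=["plate_id", "replicate", "status", "reason"])


def _growth_lookup(growth: pd.DataFrame) -> dict:
    return {
        (s, p, c, r): g
        for s, p, c, r, g in zip(
            growth["strain_id"],
            growth["plate_id"],
            growth["concentration"],
            growth["replicate"],
            growth["growth"],
        )
    }


def _batch_wt_reference(growth: pd.DataFrame, wt_strain: str) -> dict:
    """Mean wild-type control growth per (concentration, replicate).

    Pooling the per-plate wild-type controls across plates of the same
    batch gives an essentially noise-free reference; a single noisy
    control well then cannot distort every ratio on its plate.
    """
    wt = growth[growth["strain_id"] == wt_strain]
    return (
        wt.groupby(["concentration", "replicate"])["growth"].mean().to_dict()
    )


def plate_qc(
    growth: pd.DataFrame,
    layouts: list[PlateLayout],
    wt_strain: str = WT_STRAIN,
    sens_control: str = SENS_CONTROL_STRAIN,
    bins: tuple[tuple[float, int], ...] = DEFAULT_BINS,
) -> PlateQCReport:
    """Check every plate's control wells.

    A plate/replicate passes iff the wild-type control grades 0 or better
    (no apparent inhibition) at the lowest concentration and the
    sensitive spt3Δ control grades >= 1 at the highest concentration.
    Plates lacking either control well are unevaluable.
    """
    report = PlateQCReport()
    concs = sorted(c for c in growth["concentration"].unique() if c > 0)
    if not concs:
        raise ValueError("growth table has no treated concentrations")
    low_c, high_c = concs[0], concs[-1]
    wt_ref = _batch_wt_reference(growth, wt_strain)
    lut = _growth_lookup(growth)
    reps = sorted(growth["replicate"].unique())

    for layout in layouts:
        has_wt = wt_strain in layout.wells.values()
        has_sc = sens_control in layout.wells.values()
        for rep in reps:
            if not (has_wt and has_sc):
                report.unevaluable.append((layout.plate_id, rep, "missing control well"))
                continue
            pid = layout.plate_id
            wt_r = relative_growth_ratio(
                lut.get((wt_strain, pid, low_c, rep)),
                lut.get((wt_strain, pid, 0.0, rep)),
                wt_ref.get((low_c, rep)),
                wt_ref.get((0.0, rep)),
            )
            sc_r = relative_growth_ratio(
                lut.get((sens_control, pid, high_c, rep)),
                lut.get((sens_control, pid, 0.0, rep)),
                wt_ref.get((high_c, rep)),
                wt_ref.get((0.0, rep)),
            )
            wt_g, sc_g = grade_spot(wt_r, bins), grade_spot(sc_r, bins)
            if wt_g is None or sc_g is None:
                report.unevaluable.append((pid, rep, "control spot unscoreable"))
            elif wt_g > 0:
                report.failed.append((pid, rep, f"wild-type inhibited at {low_c} uM (grade {wt_g})"))
            elif sc_g < 1:
                report.failed.append((pid, rep, f"spt3 control not sensitive at {high_c} uM (grade {sc_g})"))
            else:
                report.passed.append((pid, rep))
    return report


def score_screen(
    growth: pd.DataFrame,
    layouts: list[PlateLayout] | None = None,
    wt_strain: str = WT_STRAIN,
    bins: tuple[tuple[float, int], ...] = DEFAULT_BINS,
    sensitive_cut: int = SENSITIVE_CUT,
    resistant_cut: int = RESISTANT_CUT,
    wt_reference: str = "batch",
    apply_qc: bool = True,
) -> tuple[pd.DataFrame, PlateQCReport | None]:
    """Score a whole screen from the long-format growth table.

    Returns a per-strain results table (strain_id, final_score, n_spots,
    classification) and the plate QC report (None when layouts are not
    supplied, in which case QC is skipped).

    wt_reference: "batch" normalises against the mean wild-type control
    across plates of the same concentration x replicate; "plate" uses the
    same-plate control only (with batch fallback if it failed).
    """
    _validate_bins(bins)
    if wt_reference not in ("batch", "plate"):
        raise ValueError("wt_reference must be 'batch' or 'plate'")

    qc = None
    bad = set()
    if layouts is not None and apply_qc:
        qc = plate_qc(growth, layouts, wt_strain=wt_strain, bins=bins)
        bad = {(p, r) for p, r, _ in qc.failed} | {(p, r) for p, r, _ in qc.unevaluable}

    wt_ref = _batch_wt_reference(growth, wt_strain)
    wt_plate = {
        (p, c, r): g
        for (s, p, c, r), g in _growth_lookup(
            growth[growth["strain_id"] == wt_strain]
        ).items()
    }

    concs = sorted(c for c in growth["concentration"].unique() if c > 0)
    reps = sorted(growth["replicate"].unique())
    n_design = len(concs) * len(reps)

    lib = growth[growth["strain_id"] != wt_strain]
    untreated = {
        (s, p, r): g
        for (s, p, c, r), g in _growth_lookup(lib[lib["concentration"] == 0]).items()
    }

    spot_scores: dict[str, list[int | None]] = {}
    treated = lib[lib["concentration"] > 0]
    for s, p, c, r, g in zip(
        treated["strain_id"],
        treated["plate_id"],
        treated["concentration"],
        treated["replicate"],
        treated["growth"],
    ):
        if (p, r) in bad:
            continue
        if wt_reference == "plate":
            wt_t = wt_plate.get((p, c, r), wt_ref.get((c, r)))
            wt_u = wt_plate.get((p, 0.0, r), wt_ref.get((0.0, r)))
        else:
            wt_t, wt_u = wt_ref.get((c, r)), wt_ref.get((0.0, r))
        ratio = relative_growth_ratio(g, untreated.get((s, p, r)), wt_t, wt_u)
        spot_scores.setdefault(s, []).append(grade_spot(ratio, bins))

    results = []
    for s in lib["strain_id"].unique():
        res = aggregate_and_classify(
            s,
            spot_scores.get(s, []),
            sensitive_cut=sensitive_cut,
            resistant_cut=resistant_cut,
            n_design_spots=n_design,
        )
        results.append((res.strain_id, res.final_score, res.n_spots_scored, res.classification))
    table = pd.DataFrame(
        results, columns=["strain_id", "final_score", "n_spots", "classification"]
    )
    return table, qc


def confusion_metrics(truth: pd.DataFrame, results: pd.DataFrame) -> dict[str, float]:
    """Class-recovery metrics of a scored screen against ground truth.

    sensitivity: recall of the true-sensitive class; specificity:
    fraction of true-unaffected strains classified unaffected;
    resistant_recall: recall of the true-resistant class.  Computed by
    direct confusion-matrix counting on the merged tables.
    """
    merged = truth.merge(results, on="strain_id", how="inner")
    out = {}
    for name, true_cls, pred_cls in [
        ("sensitivity", "sensitive", "sensitive"),
        ("specificity", "unaffected", "unaffected"),
        ("resistant_recall", "resistant", "resistant"),
    ]:
        sub = merged[merged["true_class"] == true_cls]
        out[name] = float((sub["classification"] == pred_cls).mean()) if len(sub) else float("nan")
    out["n"] = int(len(merged))
    return out
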