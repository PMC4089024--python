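"""Cytometry-derived cell-cycle and cell-death statistics.

G0/G1 fractions are gated from DNA-content histograms by fitting a
two-component Gaussian mixture to log fluorescence (the 1C and 2C peaks)
and thresholding at the midpoint of the fitted centres.  Cell death is
the fraction of events whose propidium-iodide intensity exceeds the
99.5th percentile of the matched untreated control.  Group comparisons
use one-way ANOVA with the Tukey–Kramer post test (studentized-range
distribution, harmonic-mean correction for unequal group sizes).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.mixture import GaussianMixture

from .synth import CytometrySample

ALPHA = 0.05


class UnevaluableSample(ValueError):
    """Raised when a sample cannot support the requested statistic."""


def gate_g1_fraction(
    sample: CytometrySample,
    min_events: int = 500,
    c1_reference: float | None = None,
) -> float:
    """Fraction of events in the 1C (G0/G1) DNA-content peak.

    Fits a two-component Gaussian mixture to log DNA content and counts
    events below the midpoint of the two fitted centres.  S-phase events
    between the peaks are split by the threshold rather than modelled.
    Invariant to any global positive rescaling of the fluorescence axis.

    If the two modes are not resolvable (e.g. a fully arrested,
    single-peak population) the sample is unevaluable unless the
    instrument's 1C position is supplied via ``c1_reference``, in which
    case the threshold falls at the log-midpoint of the 1C and 2C
    positions.
    """
    dna = sample.dna_content
    if dna.size < min_events:
        raise UnevaluableSample(f"need >= {min_events} events, got {dna.size}")
    x = np.log(dna[dna > 0])
    if x.size < min_events:
        raise UnevaluableSample("too many zero-fluorescence events")
    gm = GaussianMixture(n_components=2, n_init=3, random_state=0)
    gm.fit(x.reshape(-1, 1))
    centers = np.sort(gm.means_.ravel())
    spread = np.sqrt(gm.covariances_.ravel().max())
    if centers[1] - centers[0] < 2.0 * spread:
        if c1_reference is None:
            raise UnevaluableSample("1C and 2C modes not resolvable (unimodal distribution)")
        threshold = 0.5 * (np.log(c1_reference) + np.log(2.0 * c1_reference))
    else:
        threshold = centers.mean()
    return float(np.mean(x < threshold))


def fold_change_g1(treated_fraction: float, control_fraction: float) -> float:
    """Fold change of the G0/G1 population, treated over control."""
    if control_fraction <= 0:
        raise UnevaluableSample("control fraction must be > 0")
    return treated_fraction / control_fraction


def pi_positive_fraction(
    sample: CytometrySample,
    control: CytometrySample,
    percentile: float = 99.5,
    min_control_events: int = 200,
) -> float:
    """Fraction of PI-positive (dead) cells, gated against the control.

    The positivity threshold is the given percentile (default 99.5th) of
    the matched untreated control's PI intensities, so the gate carries
    an intrinsic ~0.5% false-positive tail.
    """
    if control.pi_value.size < min_control_events:
        raise UnevaluableSample(
            f"control must have >= {min_control_events} events, got {control.pi_value.size}"
        )
    threshold = np.percentile(control.pi_value, percentile)
    return float(np.mean(sample.pi_value > threshold))


def budding_index(budded: int, unbudded: int) -> float:
    """Fraction of budded cells among all counted cells."""
    total = budded + unbudded
    if total < 1 or budded < 0 or unbudded < 0:
        raise ValueError("need non-negative counts with budded + unbudded >= 1")
    return budded / total


@dataclass
class GroupComparison:
    groups: dict[str, np.ndarray]
    f_statistic: float
    p_anova: float
    pairwise: dict[tuple[str, str], float] = field(default_factory=dict)
    alpha: float = ALPHA
    excluded: list[str] = field(default_factory=list)

    @property
    def significant(self) -> bool:
        return self.p_anova < self.alpha

    def significant_pairs(self) -> list[tuple[str, str]]:
        return [pair for pair, p in self.pairwise.items() if p < self.alpha]


def anova_tukey(groups: dict[str, list | np.ndarray], alpha: float = ALPHA) -> GroupComparison:
    """One-way ANOVA with Tukey–Kramer pairwise post test.

    Groups with fewer than two replicates are excluded with a warning
    entry; at least two usable groups are required.  Pairwise p-values
    come from the studentized-range distribution with the Tukey–Kramer
    harmonic-mean correction for unequal group sizes.
    """
    usable = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    excluded = [k for k, v in usable.items() if v.size < 2]
    usable = {k: v for k, v in usable.items() if v.size >= 2}
    if len(usable) < 2:
        raise UnevaluableSample("need >= 2 groups with >= 2 replicates each")

    labels = list(usable)
    arrays = [usable[k] for k in labels]
    degenerate = np.ptp(np.concatenate(arrays)) == 0
    if degenerate:
        f_stat, p_anova = 0.0, 1.0
        pairwise = {
            (labels[i], labels[j]): 1.0
            for i in range(len(labels))
            for j in range(i + 1, len(labels))
        }
    else:
        f_stat, p_anova = stats.f_oneway(*arrays)
        if np.isnan(f_stat):
            f_stat, p_anova = 0.0, 1.0
        res = stats.tukey_hsd(*arrays)
        pairwise = {}
        for i, a in enumerate(labels):
            for j in range(i + 1, len(labels)):
                pairwise[(a, labels[j])] = float(res.pvalue[i, j])
    return GroupComparison(
        groups=usable,
        f_statistic=float(f_stat),
        p_anova=float(p_anova),
        pairwise=pairwise,
        alpha=alpha,
        excluded=excluded,
    )
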