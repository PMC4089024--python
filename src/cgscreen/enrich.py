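"""Hypergeometric over-representation analysis of screen hit lists.

Given a hit list, a screen universe and a collection of annotation sets
(protein complexes, GO-like terms), each term is tested for
over-representation of hits with the upper-tail hypergeometric
probability P(X >= k), and p-values are adjusted across terms with the
Benjamini–Hochberg step-up false-discovery-rate procedure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AnnotationSet:
    term_id: str
    term_name: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"annotation set {self.term_id!r} has no members")


def hypergeom_upper_tail(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n), evaluated in log space.

    N: universe size, K: annotated members of the universe, n: hit-list
    size, k: hits that are annotated.
    """
    if not (0 <= K <= N and 0 <= n <= N and 0 <= k <= min(K, n)):
        raise ValueError(f"inconsistent counts k={k} K={K} n={n} N={N}")
    if k == 0:
        return 1.0
    # sf(k-1) = P(X >= k); scipy evaluates via logs internally, exponentiate
    # the log-sf for stability at extreme tails
    return float(np.exp(stats.hypergeom.logsf(k - 1, N, K, n)))


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, in input order.

    q_(i) = min over j >= i of p_(j) * m / j on the sorted p-values,
    capped at 1.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def enrich(
    hits,
    universe,
    sets: list[AnnotationSet] | dict[str, tuple[str, list[str]]],
    min_term_size: int = 3,
    max_term_size: int = 500,
) -> pd.DataFrame:
    """Test each annotation set for over-representation of the hits.

    Term memberships are intersected with the universe before the size
    filter is applied; BH adjustment runs jointly across all retained
    terms.  Hit ids outside the universe are dropped with a logged
    warning.  Returns a table sorted by (q_value, p_value) with columns
    term_id, term_name, k, K, n, N, p_value, q_value.
    """
    universe = set(universe)
    hits = set(hits)
    outside = hits - universe
    if outside:
        logger.warning("dropping %d hit ids outside the universe", len(outside))
        hits &= universe
    if isinstance(sets, dict):
        sets = [AnnotationSet(tid, name, frozenset(m)) for tid, (name, m) in sets.items()]

    N, n = len(universe), len(hits)
    rows = []
    for s in sets:
        members = s.members & universe
        K = len(members)
        if not (min_term_size <= K <= max_term_size):
            continue
        k = len(members & hits)
        rows.append(
            {
                "term_id": s.term_id,
                "term_name": s.term_name,
                "k": k,
                "K": K,
                "n": n,
                "N": N,
                "p_value": hypergeom_upper_tail(k, K, n, N),
            }
        )
    table = pd.DataFrame(
        rows, columns=["term_id", "term_name", "k", "K", "n", "N", "p_value"]
    )
    if len(table):
        table["q_value"] = bh_adjust(table["p_value"].to_numpy())
        table = table.sort_values(["q_value", "p_value"], kind="mergesort").reset_index(drop=True)
    else:
        table["q_value"] = []
    return table
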