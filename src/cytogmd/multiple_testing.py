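"""Step-wise multiplicity control across a family of region tests.

Two per-rank threshold sequences for a family of ``m`` p-values sorted
ascending are supported:

* ``paper_stepdown`` — Holm-type step-down thresholds ``alpha/(m - k + 1)``
  at rank ``k``.  This is the sequence printed in the published MIRIAD
  reliability tables (labelled a false-discovery-rate procedure there, but
  numerically the Holm sequence; this package reproduces the printed
  thresholds and documents the discrepancy).
* ``bh_classic`` — the textbook Benjamini-Hochberg sequence
  ``alpha * k / m``.

The rejection rule is step-down in both cases: reject the hypotheses at
ranks ``1..K`` where ``K`` is the largest prefix such that
``p_(k) <= threshold_k`` for every ``k <= K``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "threshold_sequence",
    "apply_correction",
    "CorrectionResult",
    "round_half_up",
]


def round_half_up(x: float, decimals: int) -> float:
    """Round with ties away from zero, as printed summary tables do
    (Python's built-in ``round`` is half-to-even: 0.003125 -> 0.00312,
    whereas a printed table shows 0.00313)."""
    from decimal import ROUND_HALF_UP, Decimal

    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))

_METHODS = ("paper_stepdown", "bh_classic")


@dataclass(frozen=True)
class CorrectionResult:
    """Per-region multiplicity decisions for a family of m tests."""

    table: pd.DataFrame  # columns: region, p, rank, threshold, reject
    method: str
    alpha: float
    m: int

    @property
    def rejected(self) -> list[str]:
        return list(self.table.loc[self.table["reject"], "region"])


def threshold_sequence(
    m: int, alpha: float = 0.05, method: str = "paper_stepdown"
) -> np.ndarray:
    """Per-rank significance thresholds for ranks 1..m (ascending p)."""
    if m < 1:
        raise ValueError("m must be >= 1")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    if method not in _METHODS:
        raise ValueError(f"unknown method {method!r}; choose from {_METHODS}")
    k = np.arange(1, m + 1)
    if method == "paper_stepdown":
        return alpha / (m - k + 1)
    return alpha * k / m


def apply_correction(
    pvalues: Mapping[str, float] | pd.Series | Sequence[float],
    alpha: float = 0.05,
    method: str = "paper_stepdown",
) -> CorrectionResult:
    """Assign per-rank thresholds and step-down reject flags to a p-value family.

    Ties in p are broken by the stable input order, so flags always map
    back to the original labels.
    """
    if isinstance(pvalues, pd.Series):
        labels = list(pvalues.index.astype(str))
        p = np.asarray(pvalues.values, dtype=float)
    elif isinstance(pvalues, Mapping):
        labels = list(pvalues)
        p = np.array([pvalues[k] for k in labels], dtype=float)
    else:
        p = np.asarray(list(pvalues), dtype=float)
        labels = [f"test_{i + 1}" for i in range(len(p))]
    if p.size == 0:
        raise ValueError("empty p-value family")
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")

    m = p.size
    thresholds = threshold_sequence(m, alpha, method)
    order = np.argsort(p, kind="stable")
    ranks = np.empty(m, dtype=int)
    ranks[order] = np.arange(1, m + 1)
    thr_by_label = thresholds[ranks - 1]

    # Step-down: reject the longest prefix of sorted p meeting its threshold.
    sorted_ok = p[order] <= thresholds
    if sorted_ok.all():
        n_reject = m
    else:
        n_reject = int(np.argmin(sorted_ok))  # first failure index
    reject = ranks <= n_reject

    table = pd.DataFrame(
        {
            "region": labels,
            "p": p,
            "rank": ranks,
            "threshold": thr_by_label,
            "reject": reject,
        }
    )
    return CorrectionResult(table=table, method=method, alpha=alpha, m=m)
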