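"""Odds ratio estimation for 2x2 tables.

The estimator is the crude odds ratio OR = ad/bc with the Woolf confidence
interval (normal approximation on the log scale, SE = sqrt(1/a+1/b+1/c+1/d))
and a two-sided Wald z-test on the log odds ratio. Tables containing a zero
cell are repaired with the Haldane-Anscombe correction (0.5 added to every
cell) before estimation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

from scipy import stats

from .models import ModelKind, TwoByTwoTable

__all__ = ["AssociationResult", "haldane_anscombe", "odds_ratio_test"]

logger = logging.getLogger(__name__)

#: Reported p-values are floored here to avoid underflow to exactly 0.
P_FLOOR = 1e-300


@dataclass(frozen=True)
class AssociationResult:
    """Odds ratio, Woolf CI and Wald z-test for one model's 2x2 table."""

    model: ModelKind
    or_estimate: float
    ci_low: float
    ci_high: float
    log_or: float
    se_log_or: float
    z: float
    p_value: float
    corrected: bool  # Haldane-Anscombe applied
    confidence: float = 0.95


def haldane_anscombe(table: TwoByTwoTable) -> TwoByTwoTable:
    """Add 0.5 to every cell of a table containing a zero.

    A table with no zero cell is returned unchanged (with a warning); an
    all-zero table is a domain error.
    """
    cells = table.cells()
    if all(cell == 0 for cell in cells):
        raise ValueError("all four cells are zero: no data to correct")
    if not table.has_zero_cell():
        logger.warning("Haldane-Anscombe requested on a table without zero cells; no-op")
        return table
    a, b, c, d = (cell + 0.5 for cell in cells)
    return TwoByTwoTable(
        table.model, a, b, c, d,
        exposed_label=table.exposed_label, baseline_label=table.baseline_label,
    )


def odds_ratio_test(table: TwoByTwoTable, confidence: float = 0.95) -> AssociationResult:
    """Crude OR with Woolf CI and two-sided Wald p for one 2x2 table.

    Zero cells trigger the Haldane-Anscombe correction automatically
    (``corrected=True`` on the result); a table of four zeros raises.
    """
    if not 0 < confidence < 1:
        raise ValueError(f"confidence must be in (0,1), got {confidence}")
    corrected = False
    if table.has_zero_cell():
        table = haldane_anscombe(table)
        corrected = True
        logger.warning(
            "%s: zero cell, Haldane-Anscombe correction applied", table.model.value
        )
    a, b, c, d = table.cells()
    log_or = math.log(a * d) - math.log(b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = log_or / se
    p_value = max(float(2 * stats.norm.sf(abs(z))), P_FLOOR)
    z_crit = float(stats.norm.ppf(0.5 + confidence / 2))
    return AssociationResult(
        model=table.model,
        or_estimate=math.exp(log_or),
        ci_low=math.exp(log_or - z_crit * se),
        ci_high=math.exp(log_or + z_crit * se),
        log_or=log_or,
        se_log_or=se,
        z=z,
        p_value=p_value,
        corrected=corrected,
        confidence=confidence,
    )
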