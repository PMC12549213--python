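"""Manual-vs-automated agreement statistics.

The assay was validated by manually counting cells, specks and %ASC on
replicate images and regressing the manual counts on the automated ones;
agreement is summarised by the OLS slope/intercept and Pearson R^2.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence

import numpy as np
from scipy import stats

QUANTITIES = ("cells", "specks", "pct_asc")


@dataclass(frozen=True)
class CountPair:
    image_id: str
    manual: float
    automated: float
    quantity: str = "cells"

    def __post_init__(self) -> None:
        if self.manual < 0 or self.automated < 0:
            raise ValueError("counts must be non-negative")


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    n: int


def fit_agreement(pairs: Sequence[CountPair]) -> RegressionResult:
    """OLS of manual (reference) on automated counts, with Pearson R^2.

    R^2 is direction-symmetric, so regressing either way reports the same
    agreement; the slope/intercept here calibrate automated -> manual.
    """
    pairs = list(pairs)
    if len(pairs) < 3:
        raise ValueError("fit_agreement requires at least 3 pairs")
    x = np.array([p.automated for p in pairs], dtype=np.float64)
    y = np.array([p.manual for p in pairs], dtype=np.float64)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("degenerate fit: zero variance in manual or automated counts")
    fit = stats.linregress(x, y)
    return RegressionResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        n=len(pairs),
    )


def pairs_from_table(rows: Sequence[dict]) -> List[CountPair]:
    """Build CountPairs from dict rows (e.g. a CSV with columns
    image_id, quantity, manual, automated)."""
    return [
        CountPair(
            image_id=str(r["image_id"]),
            manual=float(r["manual"]),
            automated=float(r["automated"]),
            quantity=str(r.get("quantity", "cells")),
        )
        for r in rows
    ]
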