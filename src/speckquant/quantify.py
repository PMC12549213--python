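"""%ASC quantification and reference-range classification.

The assay's readout is %ASC: the number of intracellular ASC specks
divided by the total number of live cells (whether or not they carry a
speck), expressed as a percentage and pooled over the five replicate
fields imaged per sample. Since inflammasome activation nucleates a
single speck per cell, the intracellular-speck count and the
cells-with-speck count coincide in practice; the formula counts specks.

Healthy-control reference ranges (RR) are two-sided t-intervals of the
mean %ASC per stimulation condition; a sample whose %ASC exceeds the
upper bound is flagged as pyrin-inflammasome overactive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field
from typing import List, Sequence, Tuple

import numpy as np
from scipy import stats

from .detection import Speck
from .segmentation import CellLabelMap, count_cells

NOMINAL_FIELDS_PER_SAMPLE = 5

CONDITIONS = ("unstimulated", "stimulated")


@dataclass(frozen=True)
class FieldCounts:
    field_id: str
    n_cells: int
    n_specks_intracellular: int
    n_specks_total: int

    def __post_init__(self) -> None:
        if self.n_specks_intracellular > self.n_specks_total:
            raise ValueError("intracellular specks cannot exceed total specks")
        if min(self.n_cells, self.n_specks_intracellular, self.n_specks_total) < 0:
            raise ValueError("counts must be non-negative")


@dataclass(frozen=True)
class ReferenceRange:
    """Healthy-control decision thresholds for one stimulation condition."""

    condition: str
    n: int
    mean: float
    ci_low: float
    ci_high: float
    confidence: float = 0.95

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("a reference range needs n >= 2")
        if not self.ci_low <= self.mean <= self.ci_high:
            raise ValueError("require ci_low <= mean <= ci_high")


#: Published healthy-control reference ranges from the assay's clinical
#: validation cohort (n = 10 donors; mean %ASC with 95% CI). These are
#: decision constants of the assay, not values this package recomputes.
PUBLISHED_RR = {
    "unstimulated": ReferenceRange("unstimulated", n=10, mean=3.1, ci_low=1.4, ci_high=4.8),
    "stimulated": ReferenceRange("stimulated", n=10, mean=14.7, ci_low=7.8, ci_high=21.6),
}

#: Published stimulated %ASC values from the same validation cohort, by
#: patient group: genetically confirmed FMF, other (non-pyrin)
#: autoinflammatory diseases, ambiguous MEFV findings, and one case with
#: no molecular diagnosis. Inputs for reproducing the published
#: classification outcomes, keyed by patient letter.
PUBLISHED_COHORT_PCT_ASC = {
    "fmf": {"A": 31.3, "B": 54.9, "C": 19.3, "D": 34.6, "E": 79.5, "F": 27.4},
    "other_disease": {"G": 8.0, "H": 7.7, "I": 5.4, "J": 9.3},
    "ambiguous_mefv": {"K": 7.4, "L": 67.0, "M": 53.8, "N": 11.6, "O": 9.8},
    "no_molecular_diagnosis": {"P": 33.5},
}


@dataclass
class SampleResult:
    sample_id: str
    condition: str
    fields: List[FieldCounts] = dc_field(default_factory=list)
    pooled_cells: int = 0
    pooled_specks: int = 0
    pct_asc: float = float("nan")
    classification: str = "unclassified"


def assign_specks(
    specks: Sequence[Speck], labelmap: CellLabelMap, field_id: str = ""
) -> Tuple[List[Speck], FieldCounts]:
    """Mark each speck intracellular iff its centre lies on a labelled cell.

    The centre is rounded to the nearest pixel and looked up in the label
    raster; out-of-bounds centres are a validation error.
    """
    rows, cols = labelmap.labels.shape
    annotated = []
    n_intra = 0
    for s in specks:
        r, c = int(round(s.row)), int(round(s.col))
        if not (0 <= r < rows and 0 <= c < cols):
            raise ValueError(f"speck centre ({s.row}, {s.col}) outside image bounds")
        intra = bool(labelmap.labels[r, c] > 0)
        n_intra += intra
        annotated.append(
            Speck(row=s.row, col=s.col, radius=s.radius, peak=s.peak, intracellular=intra)
        )
    counts = FieldCounts(
        field_id=field_id,
        n_cells=count_cells(labelmap),
        n_specks_intracellular=n_intra,
        n_specks_total=len(annotated),
    )
    return annotated, counts


def pool_counts(fields: Sequence[FieldCounts]) -> Tuple[int, int]:
    """Sum cell and intracellular-speck counts over replicate fields.

    Pooling sums the raw counts and takes a single ratio afterwards, so
    fields contribute in proportion to the number of cells they contain.
    """
    if not fields:
        raise ValueError("pool_counts requires at least one field")
    if len(fields) != NOMINAL_FIELDS_PER_SAMPLE:
        warnings.warn(
            f"pooling {len(fields)} fields; the assay nominally uses "
            f"{NOMINAL_FIELDS_PER_SAMPLE} replicate fields per sample"
        )
    return (
        sum(f.n_cells for f in fields),
        sum(f.n_specks_intracellular for f in fields),
    )


def percent_asc(pooled_cells: int, pooled_specks: int) -> float:
    """%ASC = 100 * intracellular specks / live cells."""
    if pooled_cells <= 0:
        raise ZeroDivisionError("%ASC is undefined when no cells were counted")
    return 100.0 * pooled_specks / pooled_cells


def reference_range(
    values: Sequence[float], condition: str = "stimulated", confidence: float = 0.95
) -> ReferenceRange:
    """Build a reference range from healthy-control %ASC values.

    The interval is the two-sided Student-t CI of the mean,
    mean +/- t_{(1+confidence)/2, n-1} * sd / sqrt(n); with typical
    cohort sizes (n = 10) the t correction over a normal interval is
    material.
    """
    values = np.asarray(values, dtype=np.float64)
    n = values.size
    if n < 2:
        raise ValueError("reference_range requires n >= 2 values")
    mean = float(values.mean())
    sem = float(values.std(ddof=1) / np.sqrt(n))
    t_crit = float(stats.t.ppf((1 + confidence) / 2, df=n - 1))
    half = t_crit * sem
    return ReferenceRange(
        condition=condition,
        n=n,
        mean=mean,
        ci_low=mean - half,
        ci_high=mean + half,
        confidence=confidence,
    )


def classify(pct_asc: float, rr: ReferenceRange) -> str:
    """Classify a %ASC value against a condition-matched reference range.

    Returns "above" iff strictly above ci_high, "below" iff strictly
    below ci_low, otherwise "within" — values on the boundary count as
    within, the conservative call for a screening assay.
    """
    if pct_asc > rr.ci_high:
        return "above"
    if pct_asc < rr.ci_low:
        return "below"
    return "within"


def flag_overactive(pct_asc: float, rr: ReferenceRange) -> bool:
    """The assay's clinical flag: pyrin-inflammasome overactivity.

    A sample is flagged iff its %ASC exceeds the healthy upper bound.
    Values below the lower bound are not flagged — a low %ASC is not
    pathological for this assay, so the screening decision is one-sided
    even though :func:`classify` reports the full three-way position.
    """
    return classify(pct_asc, rr) == "above"


def summarise_sample(
    sample_id: str,
    condition: str,
    fields: Sequence[FieldCounts],
    rr: ReferenceRange | None = None,
) -> SampleResult:
    """Pool per-field counts into a classified sample result."""
    pooled_cells, pooled_specks = pool_counts(list(fields))
    pct = percent_asc(pooled_cells, pooled_specks)
    cls = "unclassified"
    if rr is not None:
        if rr.condition != condition:
            raise ValueError(
                f"reference range is for {rr.condition!r}, sample is {condition!r}"
            )
        cls = classify(pct, rr)
    return SampleResult(
        sample_id=sample_id,
        condition=condition,
        fields=list(fields),
        pooled_cells=pooled_cells,
        pooled_specks=pooled_specks,
        pct_asc=pct,
        classification=cls,
    )
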