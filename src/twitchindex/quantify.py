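"""Nuclei counting, human-nuclei ratio and satellite-cell gating.

Hybrid myotubes are heterokaryons of human and mouse nuclei; the human
contribution is quantified as the ratio of human-nuclear-antigen (HNA)
positive nuclei to all nuclei per microscopy field. Inputs here are binary
masks (segmentation of the raw confocal channels is out of scope); nuclei
are counted as 8-connected components and a nucleus is called HNA-positive
when at least half of its area (configurable) is covered by the HNA channel.

Satellite cells are selected from marker-intensity tables with the fixed
boolean gate CD11b- CD31- CD34- CD45- CD56+ (blood and endothelial lineage
negative, NCAM positive). PDGFRA is carried along but never gated; it labels
fibro/adipogenic progenitors, which are outside the gate by definition.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from skimage import measure

from ._utils import require
from .errors import ParameterError, SchemaError
from .simkit import GATE_MARKERS, NucleiField

__all__ = [
    "NucleiCounts",
    "RatioSummary",
    "GateConfig",
    "count_field",
    "ratio_summary",
    "gate_satellite_cells",
]


@dataclass
class NucleiCounts:
    field_id: str
    n_total: int
    n_hna_positive: int
    ratio: float | None  # None when the field holds no nuclei


@dataclass
class RatioSummary:
    mean: float
    se: float | None
    n_fields: int
    ratios: np.ndarray
    totals: np.ndarray
    excluded_fields: list = field(default_factory=list)


@dataclass(frozen=True)
class GateConfig:
    """Per-marker thresholds for the satellite-cell gate.

    The predicate is fixed: CD11b, CD31, CD34 and CD45 must fall below their
    thresholds and CD56 must reach its threshold.
    """

    thresholds: Mapping[str, float]

    def __post_init__(self) -> None:
        missing = [m for m in GATE_MARKERS if m not in self.thresholds]
        require(not missing, f"thresholds missing for markers: {missing}")
        require(all(self.thresholds[m] > 0 for m in GATE_MARKERS),
                "thresholds must be positive")


def count_field(
    nuclei: NucleiField, overlap_threshold: float = 0.5
) -> NucleiCounts:
    """Count nuclei and HNA-positive nuclei in one field.

    A DAPI component is HNA-positive iff the fraction of its area overlapped
    by the HNA mask is at least ``overlap_threshold``. An empty DAPI mask
    yields ``n_total = 0`` and an undefined (``None``) ratio rather than 0.
    """
    require(0 < overlap_threshold <= 1,
            "overlap_threshold must lie in (0, 1]")
    labels = measure.label(nuclei.dapi_mask, connectivity=2)
    n_total = int(labels.max())
    if n_total == 0:
        return NucleiCounts(nuclei.field_id, 0, 0, None)
    areas = np.bincount(labels.ravel(), minlength=n_total + 1)[1:]
    overlap = np.bincount(
        labels[nuclei.hna_mask].ravel(), minlength=n_total + 1
    )[1:]
    n_pos = int((overlap / areas >= overlap_threshold).sum())
    return NucleiCounts(nuclei.field_id, n_total, n_pos, n_pos / n_total)


def ratio_summary(counts: Sequence[NucleiCounts]) -> RatioSummary:
    """Mean ± SE of the per-field human-nuclei ratio.

    Fields with no nuclei (undefined ratio) are excluded from the summary and
    listed in ``excluded_fields``. The SE is the sample SD over fields
    divided by sqrt(n); absent for a single field.
    """
    valid = [c for c in counts if c.ratio is not None]
    excluded = [c.field_id for c in counts if c.ratio is None]
    if not valid:
        raise ParameterError("every field is empty; no ratio to summarize")
    ratios = np.array([c.ratio for c in valid])
    totals = np.array([c.n_total for c in valid])
    n = ratios.size
    se = float(ratios.std(ddof=1) / np.sqrt(n)) if n > 1 else None
    return RatioSummary(
        mean=float(ratios.mean()),
        se=se,
        n_fields=int(n),
        ratios=ratios,
        totals=totals,
        excluded_fields=excluded,
    )


def gate_satellite_cells(
    table: pd.DataFrame, config: GateConfig
) -> tuple:
    """Apply the CD11b- CD31- CD34- CD45- CD56+ gate to a marker table.

    Returns ``(selected, subtable)`` where ``selected`` is a boolean Series
    aligned with ``table`` and ``subtable`` is the selected rows.
    """
    missing = [m for m in GATE_MARKERS if m not in table.columns]
    if missing:
        raise SchemaError(f"marker table missing columns: {missing}")
    thr = config.thresholds
    selected = (
        (table["CD11b"] < thr["CD11b"])
        & (table["CD31"] < thr["CD31"])
        & (table["CD34"] < thr["CD34"])
        & (table["CD45"] < thr["CD45"])
        & (table["CD56"] >= thr["CD56"])
    )
    return selected, table.loc[selected]
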