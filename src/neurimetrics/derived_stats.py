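"""Secondary statistics derived from the primary per-field numbers.

Branch points are not detected directly: for a forest of neurite trees
with A roots (attachment points) and E tips (endpoints), the number of
junctions is E - A, so the per-field branch count is deduced as
``max(endpoint_count - attachment_count, 0)``. Interrupted neurite
fragments or neurites detached from any soma inflate E without
inflating A and therefore inflate the deduced branch count — a known
limitation that per-field review is meant to catch.

Ratio statistics (branch density, length per neuron, ...) are unstable
on nearly empty fields; such fields are flagged low-content and
undefined values propagate as NaN, which the condition aggregation
excludes (and counts) rather than crashing a batch.

``z_factor`` implements the screening-assay dynamic-range statistic of
Zhang, Chung & Oldenburg (1999): Z = 1 - 3(sd_pos + sd_neg)/|mean_pos -
mean_neg|; Z > 0.5 indicates a robust assay.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields as _dc_fields
from typing import Iterable, Mapping

import numpy as np

from .field_pipeline import FieldMeasurements, PipelineConfig

__all__ = [
    "DerivedMeasurements",
    "ConditionSummary",
    "derive",
    "summarize_condition",
    "z_factor",
    "MEASUREMENT_NAMES",
]


@dataclass
class DerivedMeasurements:
    branch_count: int
    branch_density: float            # branches per skeleton pixel; NaN if no skeleton
    estimated_neuron_count: float    # soma area / reference soma area
    clustering_index: float          # avg cluster area / reference soma area
    avg_neurite_length_per_neuron: float
    avg_individual_neurite_length: float
    normalized_neurite_length: float  # length / soma area (pixels per pixel-area)
    low_content: bool


#: measurement columns carried through tables, summaries and heatmaps
MEASUREMENT_NAMES = (
    "total_neurite_length",
    "total_soma_area",
    "soma_count",
    "avg_soma_cluster_area",
    "endpoint_count",
    "attachment_count",
    "mean_intensity",
    "branch_count",
    "branch_density",
    "estimated_neuron_count",
    "clustering_index",
    "avg_neurite_length_per_neuron",
    "avg_individual_neurite_length",
    "normalized_neurite_length",
)


def derive(fm: FieldMeasurements, cfg: PipelineConfig) -> DerivedMeasurements:
    """Compute the secondary statistics for one field.

    Division-by-zero cases yield NaN (flagged-undefined), never an
    exception.
    """
    length = fm.total_neurite_length
    area = fm.total_soma_area
    branch_count = max(fm.endpoint_count - fm.attachment_count, 0)
    est_neurons = area / cfg.reference_soma_area

    denom_name = cfg.avg_neurite_denominator
    neurite_denom = fm.attachment_count if denom_name == "attachments" else fm.endpoint_count

    return DerivedMeasurements(
        branch_count=branch_count,
        branch_density=branch_count / length if length > 0 else math.nan,
        estimated_neuron_count=est_neurons,
        clustering_index=fm.avg_soma_cluster_area / cfg.reference_soma_area,
        avg_neurite_length_per_neuron=length / est_neurons if est_neurons > 0 else math.nan,
        avg_individual_neurite_length=length / neurite_denom if neurite_denom > 0 else math.nan,
        normalized_neurite_length=length / area if area > 0 else math.nan,
        low_content=(length < cfg.ratio_length_floor or area < cfg.ratio_soma_floor),
    )


@dataclass
class MeasurementStats:
    n_used: int
    n_excluded: int
    mean: float
    sd: float
    sem: float


@dataclass
class ConditionSummary:
    """Per-condition mean/sd/sem of every measurement over its fields."""

    condition: str
    n_fields: int
    stats: Mapping[str, MeasurementStats]

    def mean(self, measurement: str) -> float:
        return self.stats[measurement].mean

    def sd(self, measurement: str) -> float:
        return self.stats[measurement].sd


def _as_record(item) -> dict:
    if isinstance(item, Mapping):
        return dict(item)
    if isinstance(item, tuple):  # (FieldMeasurements, DerivedMeasurements)
        rec: dict = {}
        for part in item:
            rec.update({f.name: getattr(part, f.name) for f in _dc_fields(part)})
        return rec
    return {f.name: getattr(item, f.name) for f in _dc_fields(item)}


def summarize_condition(condition: str, items: Iterable) -> ConditionSummary:
    """Aggregate fields of one condition; NaN values are excluded per
    measurement and the exclusion count reported.

    ``items`` may be dicts, (FieldMeasurements, DerivedMeasurements)
    pairs, or dataclass records containing the measurement columns.
    """
    records = [_as_record(it) for it in items]
    if not records:
        raise ValueError("summarize_condition requires at least one field")
    stats: dict[str, MeasurementStats] = {}
    for name in MEASUREMENT_NAMES:
        values = np.array([float(r[name]) for r in records if name in r], dtype=float)
        finite = values[np.isfinite(values)]
        n = finite.size
        if n == 0:
            stats[name] = MeasurementStats(0, values.size, math.nan, math.nan, math.nan)
            continue
        mean = float(finite.mean())
        sd = float(finite.std(ddof=1)) if n > 1 else 0.0
        stats[name] = MeasurementStats(n, values.size - n, mean, sd,
                                       sd / math.sqrt(n) if n > 0 else math.nan)
    return ConditionSummary(condition=condition, n_fields=len(records), stats=stats)


def z_factor(positive: ConditionSummary, negative: ConditionSummary,
             measurement: str) -> float:
    """Z = 1 - 3(sd_pos + sd_neg) / |mean_pos - mean_neg|.

    Symmetric in which condition is called positive. May be arbitrarily
    negative; equal means give -inf (flagged sentinel, not an
    exception).
    """
    sp = positive.stats[measurement]
    sn = negative.stats[measurement]
    span = abs(sp.mean - sn.mean)
    if span == 0:
        return -math.inf
    return 1.0 - 3.0 * (sp.sd + sn.sd) / span
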