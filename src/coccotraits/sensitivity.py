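"""Sensitivity of estimated cellular calcite to its input parameters.

One parameter is perturbed at a time and cellular calcite is recomputed
through the full rule set:

* Ks scaled by ±5…30 % — calcite responds linearly, so the change is
  exactly the imposed percentage;
* C_L scaled by ±5…30 % — calcite responds cubically,
  100·((1+δ)³ − 1) %, e.g. +30 % length → +119.7 % calcite and −30 %
  length → −65.7 %;
* C_N shifted by ±2 or ±5 coccoliths — the change is 100·Δ/C_N %,
  so small-C_N coccospheres are the most sensitive.

Records carrying fixed-mass components (appendage conventions) deviate
from the closed forms in the attenuating direction, because those masses
do not scale with length or shape factor.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd

from .calcite import total_cell_calcite
from .errors import DomainError
from .registry import TaxonRegistry, default_registry

__all__ = [
    "Parameter",
    "PerturbationSpec",
    "default_perturbations",
    "closed_form_change",
    "run_sensitivity",
]


class Parameter(str, enum.Enum):
    KS = "ks"
    CL = "cl"
    CN = "cn"


@dataclass(frozen=True)
class PerturbationSpec:
    """A parameter, its perturbation mode, and the signed magnitudes."""

    parameter: Parameter
    mode: str  # "relative" | "absolute_count"
    magnitudes: tuple

    def __post_init__(self) -> None:
        object.__setattr__(self, "parameter", Parameter(self.parameter))
        object.__setattr__(self, "magnitudes", tuple(self.magnitudes))
        if self.mode not in ("relative", "absolute_count"):
            raise DomainError(f"unknown perturbation mode {self.mode!r}")
        if self.mode == "relative":
            if any(not -1 < m < 1 for m in self.magnitudes):
                raise DomainError("relative magnitudes must be in (-1, 1)")
        else:
            if any(m != int(m) for m in self.magnitudes):
                raise DomainError("absolute_count magnitudes must be integers")


_RELATIVE_GRID = tuple(
    s * m for m in (0.05, 0.10, 0.15, 0.20, 0.25, 0.30) for s in (+1, -1)
)


def default_perturbations() -> list[PerturbationSpec]:
    """The published scheme: Ks and C_L ±5…30 %, C_N ±2 and ±5 coccoliths."""
    return [
        PerturbationSpec(Parameter.KS, "relative", _RELATIVE_GRID),
        PerturbationSpec(Parameter.CL, "relative", _RELATIVE_GRID),
        PerturbationSpec(Parameter.CN, "absolute_count", (2, -2, 5, -5)),
    ]


def closed_form_change(
    parameter: Parameter, magnitude: float, c_n: Optional[int] = None
) -> float:
    """Analytic percent change in cellular calcite for a single perturbation.

    CL: 100·((1+δ)³ − 1); KS: 100·δ; CN: 100·Δ/C_N.  Valid for records
    whose calcite has no fixed-mass component.
    """
    parameter = Parameter(parameter)
    if parameter is Parameter.CL:
        return 100.0 * ((1.0 + magnitude) ** 3 - 1.0)
    if parameter is Parameter.KS:
        return 100.0 * magnitude
    if c_n is None:
        raise DomainError("CN perturbation requires the record's c_n")
    return 100.0 * magnitude / c_n


def run_sensitivity(
    records: Sequence,
    registry: Optional[TaxonRegistry] = None,
    specs: Optional[Sequence[PerturbationSpec]] = None,
    per_record: bool = False,
) -> pd.DataFrame:
    """Recompute cellular calcite under each single-parameter perturbation.

    Perturbations apply to the *effective* parameters, after all fallbacks
    (a C_L perturbation perturbs the averaged Umbellosphaera length, spine
    lengths, and exothecal sizes alike); perturbed counts are floored at
    one coccolith.  Returns per-taxon min/mean/max percent change, or the
    per-record table with ``per_record=True``.
    """
    if len(records) == 0:
        raise DomainError("run_sensitivity requires at least one record")
    if registry is None:
        registry = default_registry()
    if specs is None:
        specs = default_perturbations()

    rows = []
    for record in records:
        params = registry.resolve(record.taxon).params
        baseline = total_cell_calcite(record, params).cellular_pic
        for spec in specs:
            for magnitude in spec.magnitudes:
                kwargs = {}
                if spec.parameter is Parameter.KS:
                    kwargs["ks_scale"] = 1.0 + magnitude
                elif spec.parameter is Parameter.CL:
                    kwargs["cl_scale"] = 1.0 + magnitude
                else:
                    kwargs["cn_delta"] = int(magnitude)
                perturbed = total_cell_calcite(record, params, **kwargs).cellular_pic
                rows.append({
                    "record_id": record.record_id,
                    "taxon": record.taxon.label(),
                    "parameter": spec.parameter.value,
                    "magnitude": magnitude,
                    "percent_change": 100.0 * (perturbed - baseline) / baseline,
                })
    table = pd.DataFrame(rows)
    if per_record:
        return table
    grouped = table.groupby(["taxon", "parameter", "magnitude"], sort=True)
    summary = grouped["percent_change"].agg(["size", "min", "mean", "max"])
    summary = summary.rename(columns={"size": "n"})
    return summary.reset_index()
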