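"""Coccolith and cellular calcite estimation.

The core mass model is the shape-factor cube law

    coccolith PIC (pg CaCO₃) = C_L³ · Ks · 2.7

where ``C_L`` is the taxon's size metric (distal shield length for most
taxa, trumpet width for *Discosphaera*, spine length for spinose
coccoliths), ``Ks`` a dimensionless taxon-specific shape factor, and 2.7
the density of calcite in pg µm⁻³.  Cellular calcite is coccolith PIC
times the number of coccoliths per cell, plus taxon-specific additions:
exothecal coccoliths, appendage calcite (*Michaelsarsia*, *Ophiaster*),
and the 50/50 spinose/non-spinose split of dimorphic *Rhabdosphaera*
coccospheres.

:func:`total_cell_calcite` orchestrates all rules for one measurement
record and returns a :class:`CalciteBreakdown` whose components sum
exactly to the cellular total.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from .errors import (
    ConfigurationError,
    DomainError,
    IncompleteRecordError,
    RuleNotApplicableError,
)
from .geometry import (
    CoccosphereGeometry,
    coccosphere_volume,
    equivalent_spherical_diameter,
)
from .registry import LifeCyclePhase, SizeMetric, TaxonParams

__all__ = [
    "CALCITE_DENSITY",
    "CalciteBreakdown",
    "coccolith_pic",
    "back_calculate_ks",
    "cellular_pic",
    "appendage_calcite",
    "dimorphic_pic",
    "exothecal_calcite",
    "holococcolith_cn_estimate",
    "umbellosphaera_average_cl",
    "total_cell_calcite",
]

#: Mass of calcite per unit volume, pg µm⁻³ (the literal constant of the
#: cube-law mass model).
CALCITE_DENSITY = 2.7


@dataclass(frozen=True)
class CalciteBreakdown:
    """Cellular calcite of one coccosphere, split by component (pg CaCO₃).

    ``body_total`` includes both morphs of dimorphic coccospheres;
    ``body_coccolith_pic`` is the per-coccolith mass of the non-spinose
    (regular) body coccolith.  Circum-flagellar coccoliths share the body
    Ks and are counted inside C_N, so ``cfc_total`` is only non-zero when
    a caller accounts for them separately.
    """

    body_coccolith_pic: float
    body_total: float
    cfc_total: float = 0.0
    exothecal_total: float = 0.0
    appendage_total: float = 0.0
    size_metric_used: SizeMetric = SizeMetric.DISTAL_SHIELD_LENGTH
    flags: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        for name in ("body_total", "cfc_total", "exothecal_total", "appendage_total"):
            if getattr(self, name) < 0:
                raise DomainError(f"{name} must be >= 0")

    @property
    def cellular_pic(self) -> float:
        """Total cellular calcite: exact sum of the components."""
        return (
            self.body_total + self.cfc_total + self.exothecal_total
            + self.appendage_total
        )


def coccolith_pic(c_l: float, ks: float) -> float:
    """Calcite mass (pg) of one coccolith from the cube law."""
    if not c_l > 0:
        raise DomainError(f"c_l must be positive, got {c_l}")
    if not ks > 0:
        raise DomainError(f"ks must be positive, got {ks}")
    return ks * c_l**3 * CALCITE_DENSITY


def back_calculate_ks(coccolith_mass: float, c_l: float) -> float:
    """Invert the cube law: the Ks implied by a known coccolith mass and length."""
    if not coccolith_mass > 0:
        raise DomainError(f"coccolith_mass must be positive, got {coccolith_mass}")
    if not c_l > 0:
        raise DomainError(f"c_l must be positive, got {c_l}")
    return coccolith_mass / (c_l**3 * CALCITE_DENSITY)


def cellular_pic(coccolith_pic_pg: float, c_n: float) -> float:
    """Coccosphere calcite (pg): per-coccolith mass times coccolith count."""
    if not c_n >= 1:
        raise DomainError(f"c_n must be >= 1, got {c_n}")
    return coccolith_pic_pg * c_n


def appendage_calcite(
    params: TaxonParams,
    n_appendages: Optional[int] = None,
    present: Optional[bool] = None,
) -> float:
    """Appendage calcite (pg) under a taxon's appendage rule.

    Per-appendage rule (*Michaelsarsia*): mass-per-appendage times the
    counted number, or times the default count when uncounted.  Fixed-total
    rule (*Ophiaster*): the fixed mass when arms are present, zero when
    clearly absent.
    """
    if not params.has_appendage_rule:
        raise RuleNotApplicableError("taxon has no appendage rule")
    if n_appendages is not None and n_appendages < 0:
        raise DomainError(f"n_appendages must be >= 0, got {n_appendages}")
    if params.appendage_pg_per_appendage is not None:
        if n_appendages is None:
            if present is False:
                return 0.0
            n_appendages = params.appendage_default_count
        return params.appendage_pg_per_appendage * n_appendages
    # fixed-total rule
    if present or (n_appendages is not None and n_appendages > 0):
        return params.appendage_fixed_total_pg
    return 0.0


def dimorphic_pic(
    c_l: float,
    spine_length: Optional[float],
    c_n: float,
    params: TaxonParams,
) -> CalciteBreakdown:
    """Body calcite of a dimorphic coccosphere (spinose/non-spinose split).

    A fraction ``f`` of the C_N coccoliths bear spines and are massed from
    spine length (falling back to the registry's fixed spine length when
    unmeasured); the remainder are massed from C_L.  Fractional coccolith
    counts are carried as reals, never rounded.
    """
    if params.dimorphic_spinose_fraction is None:
        raise RuleNotApplicableError("taxon has no dimorphic spinose fraction")
    if not c_n >= 1:
        raise DomainError(f"c_n must be >= 1, got {c_n}")
    f = params.dimorphic_spinose_fraction
    flags = set()
    body_pic = coccolith_pic(c_l, params.ks_body)
    if f == 0:
        return CalciteBreakdown(
            body_coccolith_pic=body_pic,
            body_total=cellular_pic(body_pic, c_n),
            size_metric_used=params.size_metric,
            flags=frozenset(flags),
        )
    if params.ks_spinose is None:
        raise ConfigurationError("dimorphic taxon lacks ks_spinose")
    if spine_length is None:
        spine_length = params.fixed_spine_length
        if spine_length is None:
            raise ConfigurationError(
                "spine length unmeasured and no fixed_spine_length configured"
            )
        flags.add("fixed_spine_length_used")
    spinose_pic = coccolith_pic(spine_length, params.ks_spinose)
    body_total = (1.0 - f) * c_n * body_pic + f * c_n * spinose_pic
    return CalciteBreakdown(
        body_coccolith_pic=body_pic,
        body_total=body_total,
        size_metric_used=params.size_metric,
        flags=frozenset(flags),
    )


def exothecal_calcite(n_xc: int, c_l_xc: float, ks_xc: float = 0.02) -> float:
    """Calcite (pg) of the counted exothecal coccoliths (one Ks for all forms)."""
    if n_xc < 0:
        raise DomainError(f"n_xc must be >= 0, got {n_xc}")
    if n_xc == 0:
        return 0.0
    return n_xc * coccolith_pic(c_l_xc, ks_xc)


def holococcolith_cn_estimate(
    coccosphere_esd: float,
    c_l: float,
    c_w: float,
    packing_efficiency: float = 1.0,
) -> int:
    """Back-calculate C_N from coccosphere and coccolith surface areas.

    The coccolith footprint is modelled as an ellipse (π·L·W/4) tiling the
    spherical coccosphere surface (π·ESD²) in a single layer with the given
    packing efficiency (default full coverage, no overlap):
    ``C_N = round(packing · 4 · ESD² / (L · W))``.
    """
    for name, value in (
        ("coccosphere_esd", coccosphere_esd), ("c_l", c_l), ("c_w", c_w),
    ):
        if not value > 0:
            raise DomainError(f"{name} must be positive, got {value}")
    if c_w > c_l:
        raise DomainError(f"c_w ({c_w}) must not exceed c_l ({c_l})")
    if not 0 < packing_efficiency <= 1:
        raise DomainError(
            f"packing_efficiency must be in (0, 1], got {packing_efficiency}"
        )
    estimate = round(packing_efficiency * 4.0 * coccosphere_esd**2 / (c_l * c_w))
    if estimate < 1:
        raise DomainError(
            "surface-area back-calculation gave C_N < 1 "
            "(coccolith larger than coccosphere)"
        )
    return int(estimate)


def umbellosphaera_average_cl(
    collapsed_cls: Sequence[float], ks: float
) -> tuple[float, float]:
    """'Average' C_L back-calculated from a collapsed coccosphere's liths.

    Summing the cube-law mass of every measured coccolith and inverting at
    the full count gives the cubic-mean length; also returns its ratio to
    the largest measured coccolith.
    """
    if len(collapsed_cls) == 0:
        raise DomainError("collapsed_cls must be non-empty")
    if any(not c > 0 for c in collapsed_cls):
        raise DomainError("all coccolith lengths must be positive")
    if not ks > 0:
        raise DomainError(f"ks must be positive, got {ks}")
    total = sum(coccolith_pic(c, ks) for c in collapsed_cls)
    n = len(collapsed_cls)
    average_cl = (total / (ks * n * CALCITE_DENSITY)) ** (1.0 / 3.0)
    return average_cl, average_cl / max(collapsed_cls)


def total_cell_calcite(
    record,
    params: TaxonParams,
    *,
    cl_scale: float = 1.0,
    ks_scale: float = 1.0,
    cn_delta: int = 0,
    packing_efficiency: float = 1.0,
) -> CalciteBreakdown:
    """Cellular calcite of one record with every taxon rule applied.

    ``record`` is a :class:`~coccotraits.pipeline.CoccosphereRecord` (or any
    object with its measurement attributes).  The keyword scales support the
    sensitivity analysis: ``cl_scale`` multiplies the effective size metric
    (after fallbacks, including spine lengths), ``ks_scale`` multiplies all
    shape factors, and ``cn_delta`` shifts the effective coccolith count
    (floored at 1).  Fixed appendage masses are conventions and are never
    scaled.
    """
    flags: set[str] = set()

    # --- effective C_L (size metric value) -------------------------------
    measured_cl = record.coccolith_length
    if measured_cl is not None:
        c_l = measured_cl
        if params.fixed_cl is not None:
            flags.add("measured_overrides_fixed_cl")
        if getattr(record, "partial_length_flag", False):
            flags.add("partial_length")
    elif params.fixed_cl is not None:
        c_l = params.fixed_cl
        flags.add("fixed_cl_used")
    else:
        raise IncompleteRecordError(
            getattr(record, "record_id", "?"), "coccolith_length"
        )
    if params.umbellosphaera_cl_factor is not None and measured_cl is not None:
        # measured length is the largest visible distal shield; the mass
        # calculation uses the calibrated 'average' coccolith fraction of it
        c_l = params.umbellosphaera_cl_factor * c_l
        flags.add("average_cl_from_max")
    c_l_eff = c_l * cl_scale

    # --- effective C_N ----------------------------------------------------
    total_count = record.total_coccolith_count
    loose = getattr(record, "loose_adjacent_count", 0) or 0
    if total_count is not None:
        c_n = total_count + loose
        if loose:
            flags.add("loose_adjacent_included")
    elif params.fixed_cn is not None:
        c_n = params.fixed_cn
        flags.add("fixed_cn_used")
    elif (
        getattr(record.taxon, "life_cycle_phase", None)
        is LifeCyclePhase.HOLOCOCCOLITH
    ):
        geom = CoccosphereGeometry(
            short_axis_d=record.coccosphere_short_axis,
            long_axis_h=record.coccosphere_long_axis,
            shape_class=params.shape_class,
        )
        esd = equivalent_spherical_diameter(coccosphere_volume(geom))
        c_w = record.coccolith_width
        if c_w is None:
            c_w = c_l  # circular footprint fallback
            flags.add("cw_fallback_circular")
        c_n = holococcolith_cn_estimate(
            esd, c_l, min(c_w, c_l), packing_efficiency=packing_efficiency
        )
        flags.add("cn_backcalculated")
    else:
        raise IncompleteRecordError(
            getattr(record, "record_id", "?"), "total_coccolith_count"
        )
    c_n_eff = max(1, c_n + cn_delta)

    ks_body = params.ks_body * ks_scale

    # --- body (and spinose) coccoliths -----------------------------------
    if params.dimorphic_spinose_fraction:
        spine = getattr(record, "process_height", None)
        if spine is not None:
            spine = spine * cl_scale
        scaled = TaxonParams(
            shape_class=params.shape_class,
            ks_body=ks_body,
            ks_spinose=(
                params.ks_spinose * ks_scale
                if params.ks_spinose is not None
                else None
            ),
            ks_exothecal=params.ks_exothecal,
            size_metric=params.size_metric,
            y_fraction=params.y_fraction,
            dimorphic_spinose_fraction=params.dimorphic_spinose_fraction,
            fixed_spine_length=(
                params.fixed_spine_length * cl_scale
                if params.fixed_spine_length is not None
                else None
            ),
        )
        body = dimorphic_pic(c_l_eff, spine, c_n_eff, scaled)
        flags |= set(body.flags)
        body_pic = body.body_coccolith_pic
        body_total = body.body_total
    else:
        body_pic = coccolith_pic(c_l_eff, ks_body)
        body_total = cellular_pic(body_pic, c_n_eff)

    # --- exothecal coccoliths --------------------------------------------
    exothecal_total = 0.0
    n_xc = getattr(record, "n_exothecal", 0) or 0
    if n_xc > 0:
        # no separate XC length is measured; XC and body coccolith sizes are
        # taken as comparable, so the body size metric is reused
        exothecal_total = exothecal_calcite(
            n_xc, c_l_eff, params.ks_exothecal * ks_scale
        )
        flags.add("xc_counted")

    # --- appendages (fixed-mass conventions, never scaled) ---------------
    appendage_total = 0.0
    if params.has_appendage_rule:
        n_app = getattr(record, "n_appendages", None)
        present = getattr(record, "appendages_present", None)
        appendage_total = appendage_calcite(params, n_app, present)
        if params.appendage_pg_per_appendage is not None and n_app is None:
            if present is not False:
                flags.add("appendages_assumed")

    return CalciteBreakdown(
        body_coccolith_pic=body_pic,
        body_total=body_total,
        exothecal_total=exothecal_total,
        appendage_total=appendage_total,
        size_metric_used=params.size_metric,
        flags=frozenset(flags),
    )
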