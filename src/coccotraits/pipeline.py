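"""End-to-end trait pipeline: read measurement tables, resolve taxa, apply
geometry and calcite rules, and write the trait table.

The input schema mirrors the archived field-dataset descriptor: one row per
intact coccosphere with station, water depth, SEM image number, taxonomy
(family, genus, species), the number of coccoliths per cell, coccolith
length and width, the coccosphere long- and short-axis diameters, and a
free-text "Additional information" column.  A small controlled vocabulary
of flag tokens in that column (``multilayer=2``, ``xc=5``, ``appendages=8``,
``appendages present``, ``partial length``, ``loose=2``) is parsed into
structured fields; everything else passes through.

All lengths are µm, volumes µm³, masses pg CaCO₃, depths m.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from .calcite import CalciteBreakdown, total_cell_calcite
from .errors import (
    CoccotraitsError,
    DomainError,
    IncompleteRecordError,
    UnresolvedTaxonError,
    ValidationError,
)
from .geometry import (
    CoccosphereGeometry,
    cell_diameter_from_coccosphere,
    coccosphere_volume,
    equivalent_spherical_diameter,
    full_length_from_partial,
    multilayer_corrected_diameter,
)
from .registry import LifeCyclePhase, TaxonKey, TaxonRegistry, default_registry

__all__ = [
    "CoccosphereRecord",
    "TraitResult",
    "read_measurements",
    "compute_traits",
    "write_traits",
    "write_measurements",
    "summarize",
]


@dataclass(frozen=True)
class CoccosphereRecord:
    """One measured intact coccosphere (raw morphometrics plus rule flags)."""

    record_id: str
    taxon: TaxonKey
    coccosphere_long_axis: float
    coccosphere_short_axis: float
    station: str = ""
    water_depth: Optional[float] = None
    image_id: str = ""
    visible_coccolith_count: Optional[int] = None
    total_coccolith_count: Optional[int] = None
    coccolith_length: Optional[float] = None
    coccolith_width: Optional[float] = None
    process_height: Optional[float] = None
    n_layers: int = 1
    n_exothecal: int = 0
    n_appendages: Optional[int] = None
    appendages_present: Optional[bool] = None
    loose_adjacent_count: int = 0
    partial_length_flag: bool = False
    notes: str = ""
    axes_swapped: bool = field(default=False, compare=False)

    def __post_init__(self) -> None:
        d, h = self.coccosphere_short_axis, self.coccosphere_long_axis
        if not (d > 0 and h > 0):
            raise ValidationError(
                f"record {self.record_id!r}: coccosphere axes must be positive"
            )
        if d > h:  # normalise defensively, remembering the swap
            object.__setattr__(self, "coccosphere_short_axis", h)
            object.__setattr__(self, "coccosphere_long_axis", d)
            object.__setattr__(self, "axes_swapped", True)
        for name in ("coccolith_length", "coccolith_width", "process_height"):
            value = getattr(self, name)
            if value is not None and not value > 0:
                raise ValidationError(
                    f"record {self.record_id!r}: {name} must be positive, got {value}"
                )
        if self.n_layers < 1:
            raise ValidationError(f"record {self.record_id!r}: n_layers must be >= 1")
        for name in (
            "visible_coccolith_count", "total_coccolith_count",
            "n_exothecal", "n_appendages", "loose_adjacent_count",
        ):
            value = getattr(self, name)
            if value is not None and value < 0:
                raise ValidationError(
                    f"record {self.record_id!r}: {name} must be >= 0, got {value}"
                )


@dataclass(frozen=True)
class TraitResult:
    """Computed traits for one record."""

    record_id: str
    record: CoccosphereRecord
    taxon_label: str
    coccosphere_volume: float
    coccosphere_esd: float
    coccosphere_esd_incl_process: Optional[float]
    esd_single_layer: float  # after any multilayer correction
    cell_diameter: float
    cell_volume: float
    coccolith_length_used: float
    coccolith_pic: float
    cellular_pic: float
    breakdown: CalciteBreakdown
    resolution_level: str
    warnings: tuple[str, ...] = ()


# ----------------------------------------------------------------------
# reading
# ----------------------------------------------------------------------

_COLUMN_ALIASES = {
    "record id": "record_id",
    "id": "record_id",
    "station": "station",
    "water depth": "water_depth",
    "water depth (m)": "water_depth",
    "sem image number": "image_id",
    "image": "image_id",
    "image id": "image_id",
    "family": "family",
    "genus": "genus",
    "species": "species",
    "morpho group": "morpho_group",
    "morpho-group": "morpho_group",
    "life cycle phase": "life_cycle_phase",
    "phase": "life_cycle_phase",
    "number of coccoliths per cell": "total_coccolith_count",
    "number of coccoliths per cell (cn)": "total_coccolith_count",
    "cn": "total_coccolith_count",
    "total coccolith count": "total_coccolith_count",
    "visible coccolith count": "visible_coccolith_count",
    "number of visible coccoliths": "visible_coccolith_count",
    "coccolith length": "coccolith_length",
    "coccolith length (um)": "coccolith_length",
    "cl": "coccolith_length",
    "coccolith width": "coccolith_width",
    "coccolith width (um)": "coccolith_width",
    "cw": "coccolith_width",
    "process height": "process_height",
    "spine height": "process_height",
    "trumpet height": "process_height",
    "coccosphere diameter long axis": "coccosphere_long_axis",
    "long axis": "coccosphere_long_axis",
    "coccosphere long axis": "coccosphere_long_axis",
    "coccosphere diameter short axis": "coccosphere_short_axis",
    "short axis": "coccosphere_short_axis",
    "coccosphere short axis": "coccosphere_short_axis",
    "n layers": "n_layers",
    "number of layers": "n_layers",
    "n exothecal": "n_exothecal",
    "xc count": "n_exothecal",
    "n appendages": "n_appendages",
    "appendages present": "appendages_present",
    "loose adjacent count": "loose_adjacent_count",
    "partial length": "partial_length_flag",
    "partial length flag": "partial_length_flag",
    "additional information": "notes",
    "additional notes": "notes",
    "notes": "notes",
}

_NOTE_TOKEN = re.compile(
    r"(multilayer|xc|appendages|loose)\s*=\s*(\d+)|"
    r"(appendages present|partial length)",
    re.IGNORECASE,
)


def _parse_notes(notes: str) -> dict:
    """Extract machine-readable flag tokens from the free-text notes column."""
    out: dict = {}
    for m in _NOTE_TOKEN.finditer(notes or ""):
        if m.group(1):
            key, value = m.group(1).lower(), int(m.group(2))
            if key == "multilayer":
                out["n_layers"] = value
            elif key == "xc":
                out["n_exothecal"] = value
            elif key == "appendages":
                out["n_appendages"] = value
            elif key == "loose":
                out["loose_adjacent_count"] = value
        else:
            token = m.group(3).lower()
            if token == "appendages present":
                out["appendages_present"] = True
            elif token == "partial length":
                out["partial_length_flag"] = True
    return out


def _canon_header(name: str) -> str:
    name = re.sub(r"\s+", " ", str(name).strip().lower())
    name_u = name.replace("_", " ")
    return _COLUMN_ALIASES.get(name, _COLUMN_ALIASES.get(name_u, name.replace(" ", "_")))


_TRUE_TOKENS = {"1", "true", "yes", "y"}
_FALSE_TOKENS = {"0", "false", "no", "n"}


def _opt_float(value) -> Optional[float]:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    text = str(value).strip()
    if not text or text.lower() in ("na", "nan"):
        return None
    return float(text)


def _opt_int(value) -> Optional[int]:
    f = _opt_float(value)
    if f is None:
        return None
    if abs(f - round(f)) > 1e-9:
        raise ValueError(f"expected an integer, got {value!r}")
    return int(round(f))


def _opt_bool(value) -> Optional[bool]:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    text = str(value).strip().lower()
    if not text:
        return None
    if text in _TRUE_TOKENS:
        return True
    if text in _FALSE_TOKENS:
        return False
    raise ValueError(f"expected a boolean token, got {value!r}")


def read_measurements(
    path: str | Path,
    registry: Optional[TaxonRegistry] = None,
    cn_is_visible: bool = False,
    strict: bool = True,
    delimiter: str = ",",
) -> list[CoccosphereRecord]:
    """Read a per-coccosphere measurement table (CSV or spreadsheet).

    With ``cn_is_visible`` the count column holds the coccoliths counted on
    the visible hemisphere; it is multiplied by the taxon's count multiplier
    (2 by default, 3 for the pseudo-multilayered *Umbellosphaera*).  Records
    flagged ``partial length`` carry a centre-to-rim half length, which is
    doubled on ingest.  Axes are normalised so short <= long.
    """
    path = Path(path)
    if path.suffix.lower() in (".xlsx", ".xlsm", ".xls"):
        frame = pd.read_excel(path, dtype=object)
    else:
        frame = pd.read_csv(path, dtype=str, keep_default_na=False, sep=delimiter)
    frame.columns = [_canon_header(c) for c in frame.columns]
    if registry is None and cn_is_visible:
        registry = default_registry()

    records: list[CoccosphereRecord] = []
    for idx, row in frame.iterrows():
        line = idx + 2  # header is line 1
        try:
            records.append(_parse_record(row, line, registry, cn_is_visible))
        except (CoccotraitsError, ValueError) as exc:
            if strict:
                raise ValidationError(f"{path} line {line}: {exc}") from exc
    return records


def _parse_record(
    row: pd.Series,
    line: int,
    registry: Optional[TaxonRegistry],
    cn_is_visible: bool,
) -> CoccosphereRecord:
    def cell(name):
        return row.get(name)

    notes = str(cell("notes") or "")
    note_fields = _parse_notes(notes)

    phase = str(cell("life_cycle_phase") or "").strip() or "heterococcolith"
    taxon = TaxonKey(
        family=str(cell("family") or "").strip(),
        genus=str(cell("genus") or "").strip(),
        species=str(cell("species") or "").strip() or None,
        morpho_group=str(cell("morpho_group") or "").strip() or None,
        life_cycle_phase=LifeCyclePhase(phase.lower()),
    )

    c_l = _opt_float(cell("coccolith_length"))
    partial = (
        _opt_bool(cell("partial_length_flag"))
        or note_fields.get("partial_length_flag", False)
    )
    if partial and c_l is not None:
        c_l = full_length_from_partial(c_l)

    visible = _opt_int(cell("visible_coccolith_count"))
    total = _opt_int(cell("total_coccolith_count"))
    if cn_is_visible:
        # the count column held a visible-hemisphere count
        if total is not None and visible is None:
            visible, total = total, None
        if visible is not None and total is None:
            multiplier = 2
            if registry is not None:
                try:
                    multiplier = registry.resolve(taxon).params.cn_multiplier
                except UnresolvedTaxonError:
                    pass
            total = visible * multiplier

    long_axis = _opt_float(cell("coccosphere_long_axis"))
    short_axis = _opt_float(cell("coccosphere_short_axis"))
    if long_axis is None or short_axis is None:
        raise ValidationError("missing coccosphere axis measurement")

    record_id = str(cell("record_id") or "").strip() or f"row-{line}"
    return CoccosphereRecord(
        record_id=record_id,
        taxon=taxon,
        station=str(cell("station") or "").strip(),
        water_depth=_opt_float(cell("water_depth")),
        image_id=str(cell("image_id") or "").strip(),
        visible_coccolith_count=visible,
        total_coccolith_count=total,
        coccolith_length=c_l,
        coccolith_width=_opt_float(cell("coccolith_width")),
        process_height=_opt_float(cell("process_height")),
        coccosphere_long_axis=long_axis,
        coccosphere_short_axis=short_axis,
        n_layers=_opt_int(cell("n_layers")) or note_fields.get("n_layers", 1),
        n_exothecal=_opt_int(cell("n_exothecal"))
        or note_fields.get("n_exothecal", 0),
        n_appendages=(
            _opt_int(cell("n_appendages"))
            if _opt_int(cell("n_appendages")) is not None
            else note_fields.get("n_appendages")
        ),
        appendages_present=(
            _opt_bool(cell("appendages_present"))
            if _opt_bool(cell("appendages_present")) is not None
            else note_fields.get("appendages_present")
        ),
        loose_adjacent_count=_opt_int(cell("loose_adjacent_count"))
        or note_fields.get("loose_adjacent_count", 0),
        partial_length_flag=bool(partial),
        notes=notes,
    )


# ----------------------------------------------------------------------
# computing
# ----------------------------------------------------------------------

def compute_traits(
    records: Sequence[CoccosphereRecord],
    registry: Optional[TaxonRegistry] = None,
    strict: bool = True,
) -> tuple[list[TraitResult], list[tuple[CoccosphereRecord, str]]]:
    """Compute traits for every record, in input order.

    Returns ``(results, skipped)``.  In strict mode an unresolved taxon or
    incomplete record raises; in lenient mode the record lands in
    ``skipped`` with the reason, so every input appears in exactly one of
    the two lists.
    """
    if registry is None:
        registry = default_registry()
    results: list[TraitResult] = []
    skipped: list[tuple[CoccosphereRecord, str]] = []
    for record in records:
        try:
            results.append(_compute_one(record, registry))
        except (UnresolvedTaxonError, IncompleteRecordError, DomainError) as exc:
            if strict:
                raise
            skipped.append((record, str(exc)))
    return results, skipped


def _compute_one(record: CoccosphereRecord, registry: TaxonRegistry) -> TraitResult:
    resolution = registry.resolve(record.taxon)
    params = resolution.params
    warnings: list[str] = []
    if record.axes_swapped:
        warnings.append("axes_swapped: long/short axes arrived reversed")

    geom = CoccosphereGeometry(
        short_axis_d=record.coccosphere_short_axis,
        long_axis_h=record.coccosphere_long_axis,
        shape_class=params.shape_class,
        n_layers=record.n_layers,
    )
    volume = coccosphere_volume(geom)
    esd = equivalent_spherical_diameter(volume)

    esd_incl = None
    if record.process_height is not None:
        # approximate including-process diameter: both axes extended by one
        # process height on each side
        p = record.process_height
        geom_incl = CoccosphereGeometry(
            short_axis_d=record.coccosphere_short_axis + 2 * p,
            long_axis_h=record.coccosphere_long_axis + 2 * p,
            shape_class=params.shape_class,
        )
        esd_incl = equivalent_spherical_diameter(coccosphere_volume(geom_incl))

    esd_single = esd
    if record.n_layers > 1:
        if params.coccolith_thickness is None:
            warnings.append(
                "multilayer_uncorrected: n_layers > 1 but no coccolith "
                "thickness in registry"
            )
        else:
            esd_single = multilayer_corrected_diameter(
                esd, record.n_layers, params.coccolith_thickness
            )
    cell_diameter = cell_diameter_from_coccosphere(esd_single, params.y_fraction)
    cell_volume = params.y_fraction * (math.pi / 6.0) * esd_single**3

    breakdown = total_cell_calcite(record, params)
    if "cw_fallback_circular" in breakdown.flags:
        warnings.append("cw_fallback: coccolith width missing, used length")
    if "measured_overrides_fixed_cl" in breakdown.flags:
        warnings.append("measured coccolith length used despite fixed_cl fallback")

    c_l_used = (
        record.coccolith_length
        if record.coccolith_length is not None
        else params.fixed_cl
    )
    if params.umbellosphaera_cl_factor is not None and record.coccolith_length:
        c_l_used = params.umbellosphaera_cl_factor * record.coccolith_length

    return TraitResult(
        record_id=record.record_id,
        record=record,
        taxon_label=record.taxon.label(),
        coccosphere_volume=volume,
        coccosphere_esd=esd,
        coccosphere_esd_incl_process=esd_incl,
        esd_single_layer=esd_single,
        cell_diameter=cell_diameter,
        cell_volume=cell_volume,
        coccolith_length_used=c_l_used,
        coccolith_pic=breakdown.body_coccolith_pic,
        cellular_pic=breakdown.cellular_pic,
        breakdown=breakdown,
        resolution_level=resolution.level,
        warnings=tuple(warnings),
    )


# ----------------------------------------------------------------------
# writing / summarising
# ----------------------------------------------------------------------

def _fmt_len(value: Optional[float]) -> str:
    """Raw measurement columns: shortest exact round-trip representation."""
    return "" if value is None else repr(float(value))


def _fmt_4g(value: Optional[float]) -> str:
    return "" if value is None else f"{value:.4g}"


def _fmt_mass(value: Optional[float]) -> str:
    return "" if value is None else f"{value:.2f}"


def _measurement_row(rec: CoccosphereRecord) -> dict:
    """The descriptor-schema columns for one record.  Partial-length records
    store the centre-to-rim half length, so a write/read cycle (which
    re-doubles on ingest) round-trips exactly."""
    c_l = rec.coccolith_length
    if c_l is not None and rec.partial_length_flag:
        c_l = c_l / 2.0
    return {
        "record id": rec.record_id,
        "station": rec.station,
        "water depth": _fmt_len(rec.water_depth),
        "SEM image number": rec.image_id,
        "family": rec.taxon.family,
        "genus": rec.taxon.genus,
        "species": rec.taxon.species or "",
        "morpho group": rec.taxon.morpho_group or "",
        "life cycle phase": rec.taxon.life_cycle_phase.value,
        "number of coccoliths per cell": (
            "" if rec.total_coccolith_count is None else rec.total_coccolith_count
        ),
        "coccolith length": _fmt_len(c_l),
        "coccolith width": _fmt_len(rec.coccolith_width),
        "process height": _fmt_len(rec.process_height),
        "coccosphere diameter long axis": _fmt_len(rec.coccosphere_long_axis),
        "coccosphere diameter short axis": _fmt_len(rec.coccosphere_short_axis),
        "n layers": rec.n_layers,
        "n exothecal": rec.n_exothecal,
        "n appendages": "" if rec.n_appendages is None else rec.n_appendages,
        "appendages present": (
            "" if rec.appendages_present is None
            else str(rec.appendages_present).lower()
        ),
        "loose adjacent count": rec.loose_adjacent_count,
        "partial length flag": str(bool(rec.partial_length_flag)).lower(),
        "additional information": rec.notes,
    }


def write_traits(results: Sequence[TraitResult], path: str | Path) -> None:
    """Write the trait table: descriptor measurement columns echoed exactly,
    derived quantities formatted (4 significant figures for sizes, 2
    decimals for masses), plus provenance columns."""
    rows = []
    for r in results:
        row = _measurement_row(r.record)
        row.update({
            "coccosphere volume": _fmt_4g(r.coccosphere_volume),
            "coccosphere esd": _fmt_4g(r.coccosphere_esd),
            "coccosphere esd incl process": _fmt_4g(r.coccosphere_esd_incl_process),
            "cell diameter": _fmt_4g(r.cell_diameter),
            "cell volume": _fmt_4g(r.cell_volume),
            "coccolith length used": _fmt_4g(r.coccolith_length_used),
            "coccolith pic": _fmt_mass(r.coccolith_pic),
            "cellular pic": _fmt_mass(r.cellular_pic),
            "body pic total": _fmt_mass(r.breakdown.body_total),
            "exothecal pic total": _fmt_mass(r.breakdown.exothecal_total),
            "appendage pic total": _fmt_mass(r.breakdown.appendage_total),
            "resolution level": r.resolution_level,
            "provenance flags": ";".join(sorted(r.breakdown.flags)),
            "warnings": ";".join(r.warnings),
        })
        rows.append(row)
    try:
        pd.DataFrame(rows).to_csv(path, index=False, lineterminator="\n")
    except OSError as exc:
        raise CoccotraitsError(f"cannot write traits to {path}: {exc}") from exc


def write_measurements(records: Sequence[CoccosphereRecord], path: str | Path) -> None:
    """Write records back to the measurement-table schema (see
    :func:`_measurement_row` for the partial-length convention)."""
    rows = [_measurement_row(rec) for rec in records]
    try:
        pd.DataFrame(rows).to_csv(path, index=False, lineterminator="\n")
    except OSError as exc:
        raise CoccotraitsError(f"cannot write measurements to {path}: {exc}") from exc


def summarize(results: Sequence[TraitResult]) -> pd.DataFrame:
    """Per-taxon summary: n plus min/median/max of the principal traits."""
    if len(results) == 0:
        raise DomainError("summarize requires at least one result")
    frame = pd.DataFrame({
        "taxon": [r.taxon_label for r in results],
        "coccolith_length": [r.coccolith_length_used for r in results],
        "coccosphere_esd": [r.coccosphere_esd for r in results],
        "cell_diameter": [r.cell_diameter for r in results],
        "cellular_pic": [r.cellular_pic for r in results],
    })
    grouped = frame.groupby("taxon", sort=True)
    parts = {"n": grouped.size()}
    for col in ("coccolith_length", "coccosphere_esd", "cell_diameter", "cellular_pic"):
        parts[f"{col}_min"] = grouped[col].min()
        parts[f"{col}_median"] = grouped[col].median()
        parts[f"{col}_max"] = grouped[col].max()
    return pd.DataFrame(parts).reset_index()
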