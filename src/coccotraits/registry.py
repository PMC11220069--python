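"""Taxon parameter registry.

Every taxon-specific constant in the trait computation lives here: the
coccosphere shape class, the shape factor *Ks* converting coccolith length
cubed to calcite mass, the coccosphere-volume-to-cell-volume fraction *y*,
and the per-taxon correction-rule constants (fixed coccolith counts and
lengths, appendage masses, the dimorphic spinose split, multilayer coccolith
thickness, the Umbellosphaera average-length factor).

A registry is a flat table of rows keyed by taxonomy.  Lookup resolves with
a documented fallback hierarchy: exact species match, then within-genus
morpho-group, then genus, then a life-cycle-phase default (holococcolith
coccospheres share a single estimated Ks of 0.036 and y of 80%).  Matching
is case-insensitive on genus and species; morpho-group names are compared
after whitespace normalisation.

The packaged default registry encodes the constants of the source field
protocol.  Ks values that the protocol cites from the wider literature but
does not itself state are shipped as clearly-marked placeholder rows
(``source_note`` starting with ``placeholder``) that users should confirm
before relying on them quantitatively.
"""

from __future__ import annotations

import enum
import math
import re
from dataclasses import dataclass, fields as dc_fields
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd

from .errors import UnresolvedTaxonError, ValidationError
from .geometry import ShapeClass

__all__ = [
    "LifeCyclePhase",
    "SizeMetric",
    "TaxonKey",
    "TaxonParams",
    "Resolution",
    "TaxonRegistry",
    "load_registry",
    "default_registry",
    "write_registry",
]

WILDCARD_GENUS = "*"


class LifeCyclePhase(str, enum.Enum):
    HETEROCOCCOLITH = "heterococcolith"
    HOLOCOCCOLITH = "holococcolith"
    NANNOLITH = "nannolith"
    POLYCRATER = "polycrater"


class SizeMetric(str, enum.Enum):
    """Which linear measurement enters the calcite cube law for a taxon."""

    DISTAL_SHIELD_LENGTH = "distal_shield_length"
    TRUMPET_WIDTH = "trumpet_width"
    SPINE_LENGTH = "spine_length"


def _norm_name(text: Optional[str]) -> Optional[str]:
    if text is None:
        return None
    text = text.strip()
    return text.casefold() if text else None


def _norm_group(text: Optional[str]) -> Optional[str]:
    if text is None:
        return None
    text = re.sub(r"\s+", " ", text.strip())
    return text if text else None


@dataclass(frozen=True)
class TaxonKey:
    """Taxonomic identity of a record or registry row."""

    family: str = ""
    genus: str = ""
    species: Optional[str] = None
    morpho_group: Optional[str] = None
    life_cycle_phase: LifeCyclePhase = LifeCyclePhase.HETEROCOCCOLITH

    def __post_init__(self) -> None:
        if not self.genus or not self.genus.strip():
            raise ValidationError("TaxonKey.genus must be non-empty")
        object.__setattr__(
            self, "life_cycle_phase", LifeCyclePhase(self.life_cycle_phase)
        )

    def label(self) -> str:
        parts = [self.genus]
        if self.species:
            parts.append(self.species)
        elif self.morpho_group:
            parts.append(f"({self.morpho_group})")
        if self.life_cycle_phase is not LifeCyclePhase.HETEROCOCCOLITH:
            parts.append(self.life_cycle_phase.value.upper()[:3])
        return " ".join(parts)


@dataclass(frozen=True)
class TaxonParams:
    """Per-taxon computation parameters.

    Units: lengths µm, masses pg CaCO₃, Ks and fractions dimensionless.
    """

    shape_class: ShapeClass = ShapeClass.PROLATE_SPHERE
    ks_body: float = float("nan")
    ks_spinose: Optional[float] = None
    ks_exothecal: float = 0.02
    size_metric: SizeMetric = SizeMetric.DISTAL_SHIELD_LENGTH
    y_fraction: float = float("nan")
    y_fraction_incl_process: Optional[float] = None
    cn_multiplier: int = 2
    fixed_cn: Optional[int] = None
    fixed_cl: Optional[float] = None
    fixed_spine_length: Optional[float] = None
    dimorphic_spinose_fraction: Optional[float] = None
    appendage_pg_per_appendage: Optional[float] = None
    appendage_default_count: Optional[int] = None
    appendage_fixed_total_pg: Optional[float] = None
    coccolith_thickness: Optional[float] = None
    umbellosphaera_cl_factor: Optional[float] = None
    source_note: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "shape_class", ShapeClass(self.shape_class))
        object.__setattr__(self, "size_metric", SizeMetric(self.size_metric))
        if math.isnan(self.ks_body) or not 0 < self.ks_body < 1:
            raise ValidationError(f"ks_body must be in (0, 1), got {self.ks_body}")
        if self.ks_spinose is not None and not 0 < self.ks_spinose < 1:
            raise ValidationError(f"ks_spinose must be in (0, 1), got {self.ks_spinose}")
        if not 0 < self.ks_exothecal < 1:
            raise ValidationError(
                f"ks_exothecal must be in (0, 1), got {self.ks_exothecal}"
            )
        if math.isnan(self.y_fraction) or not 0 < self.y_fraction <= 1:
            raise ValidationError(
                f"y_fraction must be in (0, 1], got {self.y_fraction}"
            )
        if self.y_fraction_incl_process is not None and not (
            0 < self.y_fraction_incl_process <= 1
        ):
            raise ValidationError(
                f"y_fraction_incl_process must be in (0, 1], "
                f"got {self.y_fraction_incl_process}"
            )
        if self.cn_multiplier not in (2, 3):
            raise ValidationError(
                f"cn_multiplier must be 2 or 3, got {self.cn_multiplier}"
            )
        if self.fixed_cn is not None and self.fixed_cn < 1:
            raise ValidationError(f"fixed_cn must be >= 1, got {self.fixed_cn}")
        for name in ("fixed_cl", "fixed_spine_length", "coccolith_thickness"):
            value = getattr(self, name)
            if value is not None and not value > 0:
                raise ValidationError(f"{name} must be positive, got {value}")
        if self.dimorphic_spinose_fraction is not None and not (
            0 <= self.dimorphic_spinose_fraction <= 1
        ):
            raise ValidationError(
                "dimorphic_spinose_fraction must be in [0, 1], "
                f"got {self.dimorphic_spinose_fraction}"
            )
        if self.umbellosphaera_cl_factor is not None and not (
            0 < self.umbellosphaera_cl_factor <= 1
        ):
            raise ValidationError(
                "umbellosphaera_cl_factor must be in (0, 1], "
                f"got {self.umbellosphaera_cl_factor}"
            )
        per_item = self.appendage_pg_per_appendage is not None
        fixed_total = self.appendage_fixed_total_pg is not None
        if per_item and fixed_total:
            raise ValidationError(
                "per-appendage and fixed-total appendage rules are exclusive"
            )
        if per_item and self.appendage_default_count is None:
            raise ValidationError(
                "appendage_pg_per_appendage requires appendage_default_count"
            )
        if self.appendage_default_count is not None and not per_item:
            raise ValidationError(
                "appendage_default_count requires appendage_pg_per_appendage"
            )

    @property
    def has_appendage_rule(self) -> bool:
        return (
            self.appendage_pg_per_appendage is not None
            or self.appendage_fixed_total_pg is not None
        )


@dataclass(frozen=True)
class Resolution:
    """A resolved lookup: the parameters plus which fallback level matched."""

    params: TaxonParams
    level: str  # "species" | "morpho_group" | "genus" | "phase_default"
    matched_key: TaxonKey


class TaxonRegistry:
    """Immutable lookup table from :class:`TaxonKey` to :class:`TaxonParams`."""

    def __init__(self, entries: Iterable[tuple[TaxonKey, TaxonParams]]):
        self._entries: tuple[tuple[TaxonKey, TaxonParams], ...] = tuple(entries)
        seen: set[tuple] = set()
        for key, _ in self._entries:
            ident = (
                _norm_name(key.genus),
                _norm_name(key.species),
                _norm_group(key.morpho_group),
                key.life_cycle_phase,
            )
            if ident in seen:
                raise ValidationError(f"duplicate registry key: {key}")
            seen.add(ident)

    def __len__(self) -> int:
        return len(self._entries)

    def __iter__(self):
        return iter(self._entries)

    def resolve(self, key: TaxonKey) -> Resolution:
        """Resolve a key through species → morpho-group → genus → phase default."""
        genus = _norm_name(key.genus)
        species = _norm_name(key.species)
        group = _norm_group(key.morpho_group)
        phase = key.life_cycle_phase

        def rows():
            for rk, rp in self._entries:
                if rk.life_cycle_phase is phase:
                    yield rk, rp

        if species is not None:
            for rk, rp in rows():
                if _norm_name(rk.genus) == genus and _norm_name(rk.species) == species:
                    return Resolution(rp, "species", rk)
        if group is not None:
            for rk, rp in rows():
                if (
                    _norm_name(rk.genus) == genus
                    and rk.species is None
                    and _norm_group(rk.morpho_group) == group
                ):
                    return Resolution(rp, "morpho_group", rk)
        for rk, rp in rows():
            if (
                _norm_name(rk.genus) == genus
                and rk.species is None
                and rk.morpho_group is None
            ):
                return Resolution(rp, "genus", rk)
        for rk, rp in rows():
            if rk.genus == WILDCARD_GENUS:
                return Resolution(rp, "phase_default", rk)
        raise UnresolvedTaxonError(
            f"no registry entry for {key} at species, morpho-group, genus "
            f"or phase-default level"
        )


_KEY_COLUMNS = ["family", "genus", "species", "morpho_group", "life_cycle_phase"]
_PARAM_COLUMNS = [f.name for f in dc_fields(TaxonParams)]
_INT_FIELDS = {"cn_multiplier", "fixed_cn", "appendage_default_count"}
_STR_FIELDS = {"shape_class", "size_metric", "source_note"}


def load_registry(path: str | Path, strict: bool = True) -> TaxonRegistry:
    """Load a registry from a delimited-text file (UTF-8, header row).

    Columns are named exactly as the :class:`TaxonParams` fields plus the
    key columns ``family, genus, species, morpho_group, life_cycle_phase``.
    Empty cells mean "unset".  Malformed rows raise :class:`ValidationError`
    naming the row and field; with ``strict=False`` malformed rows are
    skipped (an empty result still raises).
    """
    path = Path(path)
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in _KEY_COLUMNS + ["ks_body", "y_fraction"] if c not in frame.columns]
    if missing:
        raise ValidationError(f"registry {path}: missing columns {missing}")
    entries: list[tuple[TaxonKey, TaxonParams]] = []
    bad: list[str] = []
    for idx, row in frame.iterrows():
        try:
            entries.append(_parse_row(row))
        except (ValidationError, ValueError, KeyError) as exc:
            msg = f"registry {path} row {idx + 2}: {exc}"
            if strict:
                raise ValidationError(msg) from exc
            bad.append(msg)
    if not entries:
        raise ValidationError(f"registry {path}: no valid rows")
    return TaxonRegistry(entries)


def _parse_row(row: pd.Series) -> tuple[TaxonKey, TaxonParams]:
    def cell(name: str) -> Optional[str]:
        value = row.get(name, "")
        value = str(value).strip()
        return value if value else None

    key = TaxonKey(
        family=cell("family") or "",
        genus=cell("genus") or "",
        species=cell("species"),
        morpho_group=cell("morpho_group"),
        life_cycle_phase=LifeCyclePhase(
            cell("life_cycle_phase") or LifeCyclePhase.HETEROCOCCOLITH
        ),
    )
    kwargs: dict = {}
    for name in _PARAM_COLUMNS:
        raw = cell(name)
        if raw is None:
            continue
        if name in _STR_FIELDS:
            kwargs[name] = raw
        elif name in _INT_FIELDS:
            kwargs[name] = int(float(raw))
        else:
            try:
                kwargs[name] = float(raw)
            except ValueError as exc:
                raise ValidationError(f"field {name!r}: {exc}") from exc
    return key, TaxonParams(**kwargs)


def write_registry(registry: TaxonRegistry, path: str | Path) -> None:
    """Write a registry back to delimited text; numeric fields round-trip."""
    rows = []
    for key, params in registry:
        row: dict = {
            "family": key.family,
            "genus": key.genus,
            "species": key.species or "",
            "morpho_group": key.morpho_group or "",
            "life_cycle_phase": key.life_cycle_phase.value,
        }
        for name in _PARAM_COLUMNS:
            value = getattr(params, name)
            if value is None:
                row[name] = ""
            elif isinstance(value, enum.Enum):
                row[name] = value.value
            elif isinstance(value, float):
                row[name] = repr(value)  # shortest exact round-trip
            else:
                row[name] = value
        rows.append(row)
    pd.DataFrame(rows, columns=_KEY_COLUMNS + _PARAM_COLUMNS).to_csv(
        path, index=False
    )


def default_registry() -> TaxonRegistry:
    """The packaged default registry (see module docstring for provenance)."""
    source = resources.files("coccotraits.data").joinpath("default_registry.csv")
    with resources.as_file(source) as path:
        return load_registry(path, strict=True)
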