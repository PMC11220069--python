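"""Seeded generator of synthetic per-coccosphere measurement tables.

The generator emulates the structure of the archived SEM-derived field
dataset — one row per intact coccosphere with taxonomy, coccolith length
and width, coccolith count, coccosphere axes, and rule flags — together
with a per-record ground truth, so every pipeline stage is testable
without the archived data.

Statistical choices (the field protocol constrains error magnitudes, not
population distributions): coccolith length is lognormal between
coccospheres with a lognormal within-coccosphere spread (sizes on one
coccosphere can vary by up to ~30 %); coccolith counts are shifted
negative-binomial with a floor of 4.  The measured length is a single
draw from the within-coccosphere distribution, emulating the one
flat-lying coccolith measured per coccosphere.  Noise modes: doubled
partial-length measurements carry a mean error of −0.6 % ranging about
±8 %, and counts can be off by ±1–5 coccoliths.  Coccosphere axes are
drawn so that the coccosphere surface area is consistent with the
coccolith count and footprint, which makes the holococcolith
surface-area count back-calculation self-consistent by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .calcite import CALCITE_DENSITY
from .errors import DomainError, ValidationError
from .geometry import _SHAPE_COEFFICIENT
from .pipeline import CoccosphereRecord, TraitResult
from .registry import LifeCyclePhase, TaxonKey, TaxonRegistry, default_registry

__all__ = [
    "SizeModel",
    "NoiseModel",
    "MixEntry",
    "SyntheticConfig",
    "SyntheticTruth",
    "default_config",
    "noiseless",
    "generate",
    "recovery_report",
]


@dataclass(frozen=True)
class SizeModel:
    """Per-taxon distributions for coccolith size and count."""

    cl_median: float
    cl_gcv: float = 0.15  # between-coccosphere geometric spread (sigma of log)
    cn_mean: float = 20.0
    cn_dispersion: float = 8.0  # negative-binomial shape; larger = tighter
    cn_min: int = 4
    width_ratio: float = 0.8  # C_W / C_L
    aspect_mean: float = 1.1  # long/short axis ratio
    aspect_sd: float = 0.05
    spine_median: Optional[float] = None  # spine / process height, µm

    def __post_init__(self) -> None:
        if not self.cl_median > 0:
            raise ValidationError("cl_median must be positive")
        if self.cl_gcv < 0 or self.cn_dispersion <= 0:
            raise ValidationError("dispersion parameters must be positive")
        if self.cn_min < 1 or self.cn_mean < self.cn_min:
            raise ValidationError("need cn_mean >= cn_min >= 1")


@dataclass(frozen=True)
class NoiseModel:
    """Measurement-noise modes; all switchable to zero for closed-loop tests."""

    within_cl_sd: float = 0.10  # relative SD of lith sizes on one coccosphere
    partial_prob: float = 0.15
    partial_bias: float = -0.006  # mean relative error of doubled half-lengths
    partial_sd: float = 0.03
    partial_range: float = 0.08  # hard clip on the relative error
    miscount_prob: float = 0.25
    miscount_max: int = 5
    appendage_unknown_prob: float = 0.3
    spine_unmeasured_prob: float = 0.2

    @classmethod
    def none(cls) -> "NoiseModel":
        return cls(
            within_cl_sd=0.0, partial_prob=0.0, miscount_prob=0.0,
            appendage_unknown_prob=0.0, spine_unmeasured_prob=0.0,
        )


@dataclass(frozen=True)
class MixEntry:
    key: TaxonKey
    weight: float
    size: SizeModel
    has_xc: bool = False


@dataclass(frozen=True)
class SyntheticConfig:
    """Full description of one synthetic community draw."""

    mix: tuple
    noise: NoiseModel = field(default_factory=NoiseModel)
    layer_probs: tuple = (0.80, 0.15, 0.05)  # P(1, 2, 3 layers), multilayer taxa
    xc_prob: float = 0.7
    xc_mean: float = 8.0
    appendage_presence_prob: float = 0.6  # fixed-total appendage taxa
    loose_mean: float = 0.3  # Poisson mean of loose adjacent coccoliths
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "mix", tuple(self.mix))
        if not self.mix:
            raise ValidationError("taxon mix must be non-empty")
        total = sum(e.weight for e in self.mix)
        if not total > 0:
            raise ValidationError("mix weights must sum to a positive value")
        if abs(sum(self.layer_probs) - 1.0) > 1e-9:
            raise ValidationError("layer_probs must sum to 1")


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth for one generated record (internally consistent with
    the cube law applied to the true per-coccolith list)."""

    record_id: str
    taxon_label: str
    cl_list: tuple
    true_cn: int
    true_cell_diameter: float
    true_cellular_pic: float


def _mix_entries() -> list[MixEntry]:
    """Default community: every special-rule code path is exercised."""
    het = LifeCyclePhase.HETEROCOCCOLITH
    return [
        MixEntry(
            TaxonKey("Noelaerhabdaceae", "Emiliania", "huxleyi", None, het), 0.20,
            SizeModel(cl_median=3.2, cn_mean=22.0),
        ),
        MixEntry(
            TaxonKey("Noelaerhabdaceae", "Gephyrocapsa", None, None, het), 0.12,
            SizeModel(cl_median=3.5, cn_mean=18.0),
        ),
        MixEntry(
            TaxonKey("Calcidiscaceae", "Calcidiscus", None, None, het), 0.08,
            SizeModel(cl_median=6.5, cn_mean=15.0),
        ),
        MixEntry(
            TaxonKey("Syracosphaeraceae", "Syracosphaera", None, "pulchra group", het),
            0.10, SizeModel(cl_median=4.5, cn_mean=30.0), has_xc=True,
        ),
        MixEntry(
            TaxonKey("Syracosphaeraceae", "Syracosphaera", None, "molischii group", het),
            0.08, SizeModel(cl_median=2.5, cn_mean=25.0), has_xc=True,
        ),
        MixEntry(
            TaxonKey("Syracosphaeraceae", "Michaelsarsia", None, None, het), 0.05,
            SizeModel(cl_median=3.0, cn_mean=30.0),
        ),
        MixEntry(
            TaxonKey("Syracosphaeraceae", "Ophiaster", None, None, het), 0.05,
            SizeModel(cl_median=2.5, cn_mean=25.0),
        ),
        MixEntry(
            TaxonKey("Rhabdosphaeraceae", "Rhabdosphaera", "clavigera", None, het),
            0.07, SizeModel(cl_median=2.5, cn_mean=20.0, spine_median=5.0),
        ),
        MixEntry(
            TaxonKey("Rhabdosphaeraceae", "Discosphaera", "tubifera", None, het),
            0.06, SizeModel(cl_median=1.8, cn_mean=20.0, spine_median=4.0),
        ),
        MixEntry(
            TaxonKey("Calciosoleniaceae", "Calciosolenia", None, None, het), 0.04,
            SizeModel(cl_median=5.0, cn_mean=30.0, aspect_mean=3.0, aspect_sd=0.3),
        ),
        MixEntry(
            TaxonKey("Umbellosphaeraceae", "Umbellosphaera", None, None, het), 0.05,
            SizeModel(cl_median=6.0, cl_gcv=0.2, cn_mean=30.0),
        ),
        MixEntry(
            TaxonKey("", "Florisphaera", "profunda", None, LifeCyclePhase.NANNOLITH),
            0.04, SizeModel(cl_median=2.5, cn_mean=145.0, cn_dispersion=30.0,
                            cn_min=90),
        ),
        MixEntry(
            TaxonKey("Alisphaeraceae", "Alisphaera", None, None,
                     LifeCyclePhase.POLYCRATER),
            0.03, SizeModel(cl_median=0.8, cn_mean=400.0, cn_dispersion=40.0,
                            cn_min=200),
        ),
        MixEntry(
            TaxonKey("Calyptrosphaeraceae", "Calyptrolithina", None, None,
                     LifeCyclePhase.HOLOCOCCOLITH),
            0.03, SizeModel(cl_median=1.5, cn_mean=80.0, cn_dispersion=20.0),
        ),
    ]


def default_config(seed: int = 0, noise: Optional[NoiseModel] = None) -> SyntheticConfig:
    return SyntheticConfig(mix=tuple(_mix_entries()), noise=noise or NoiseModel(),
                           seed=seed)


def noiseless(config: SyntheticConfig) -> SyntheticConfig:
    """The same community with every noise mode and within-spread at zero."""
    return replace(config, noise=NoiseModel.none())


def _draw_cn(rng: np.random.Generator, size: SizeModel) -> int:
    mu = size.cn_mean - size.cn_min
    if mu <= 0:
        return size.cn_min
    r = size.cn_dispersion
    return int(size.cn_min + rng.negative_binomial(r, r / (r + mu)))


def _truth_pic(components: Sequence[tuple]) -> float:
    """Explicit per-coccolith enumeration: Σ weight · Ks · L³ · 2.7 (+ fixed)."""
    total = 0.0
    for weight, length, ks in components:
        total += weight * ks * length**3 * CALCITE_DENSITY
    return total


def generate(
    config: SyntheticConfig,
    n_records: int,
    registry: Optional[TaxonRegistry] = None,
) -> tuple[list[CoccosphereRecord], list[SyntheticTruth]]:
    """Draw ``n_records`` coccosphere records plus their ground truth."""
    if n_records < 1:
        raise DomainError(f"n_records must be >= 1, got {n_records}")
    if registry is None:
        registry = default_registry()
    rng = np.random.default_rng(config.seed)
    noise = config.noise
    weights = np.array([e.weight for e in config.mix], dtype=float)
    weights /= weights.sum()

    records: list[CoccosphereRecord] = []
    truths: list[SyntheticTruth] = []
    for i in range(n_records):
        entry = config.mix[int(rng.choice(len(config.mix), p=weights))]
        size = entry.size
        params = registry.resolve(entry.key).params  # raises on unresolvable mix

        # --- true coccolith population -------------------------------
        cn_body = _draw_cn(rng, size)
        loose = 0
        if params.coccolith_thickness is not None and config.loose_mean > 0:
            loose = int(rng.poisson(config.loose_mean))
        cn_total = cn_body + loose
        med = size.cl_median * math.exp(rng.normal(0.0, math.log1p(size.cl_gcv)))
        if noise.within_cl_sd > 0:
            sigma = math.sqrt(math.log1p(noise.within_cl_sd**2))
            liths = med * np.exp(rng.normal(0.0, sigma, cn_total))
        else:
            liths = np.full(cn_total, med)

        # one flat-lying coccolith is measured (largest for Umbellosphaera)
        if params.umbellosphaera_cl_factor is not None:
            measured = float(liths.max())
        else:
            measured = float(liths[rng.integers(cn_total)])

        partial = False
        if noise.partial_prob > 0 and rng.random() < noise.partial_prob:
            err = float(np.clip(
                rng.normal(noise.partial_bias, noise.partial_sd),
                -noise.partial_range, noise.partial_range,
            ))
            measured *= 1.0 + err
            partial = True
        c_w = size.width_ratio * measured

        # --- spine / process height ----------------------------------
        spine_true = None
        process_height = None
        if size.spine_median is not None:
            spine_true = size.spine_median * math.exp(rng.normal(0.0, 0.1))
            process_height = spine_true
            if noise.spine_unmeasured_prob > 0 and (
                rng.random() < noise.spine_unmeasured_prob
            ):
                process_height = None

        # --- exothecal coccoliths and appendages ---------------------
        n_xc = 0
        if entry.has_xc and rng.random() < config.xc_prob:
            n_xc = 1 + int(rng.poisson(config.xc_mean))
        n_app: Optional[int] = None
        app_present: Optional[bool] = None
        app_truth_pg = 0.0
        if params.appendage_pg_per_appendage is not None:
            true_app = int(rng.integers(8, 13))
            app_truth_pg = params.appendage_pg_per_appendage * true_app
            app_present = True
            n_app = true_app
            if noise.appendage_unknown_prob > 0 and (
                rng.random() < noise.appendage_unknown_prob
            ):
                n_app = None
                app_truth_pg = params.appendage_pg_per_appendage * true_app
        elif params.appendage_fixed_total_pg is not None:
            app_present = bool(rng.random() < config.appendage_presence_prob)
            app_truth_pg = params.appendage_fixed_total_pg if app_present else 0.0

        # --- multilayer structure ------------------------------------
        n_layers = 1
        if params.coccolith_thickness is not None:
            n_layers = 1 + int(rng.choice(3, p=np.asarray(config.layer_probs)))

        # --- coccosphere axes: surface area consistent with the count
        if entry.key.life_cycle_phase is LifeCyclePhase.HOLOCOCCOLITH:
            # exact footprint tiling in *measured* sizes, so the pipeline's
            # surface-area back-calculation recovers the true count
            esd_single = math.sqrt(cn_total * measured * c_w) / 2.0
        else:
            esd_single = math.sqrt(
                cn_total * med * (size.width_ratio * med)) / 2.0
        esd_outer = esd_single
        if n_layers > 1:
            esd_outer += 2.0 * (n_layers - 1) * params.coccolith_thickness
        aspect = max(1.0, rng.normal(size.aspect_mean, size.aspect_sd))
        shape_factor = (math.pi / 6.0) / _SHAPE_COEFFICIENT[params.shape_class]
        d = (shape_factor * esd_outer**3 / aspect) ** (1.0 / 3.0)
        h = aspect * d

        # --- recorded counts -----------------------------------------
        recorded_total: Optional[int] = cn_body
        if params.fixed_cn is not None or (
            entry.key.life_cycle_phase is LifeCyclePhase.HOLOCOCCOLITH
        ):
            recorded_total = None  # counting impossible; pipeline falls back
        elif noise.miscount_prob > 0 and rng.random() < noise.miscount_prob:
            delta = int(rng.integers(1, noise.miscount_max + 1))
            delta *= 1 if rng.random() < 0.5 else -1
            recorded_total = max(1, cn_body + delta)

        record_id = f"syn-{i:04d}"
        record = CoccosphereRecord(
            record_id=record_id,
            taxon=entry.key,
            station="SYN",
            water_depth=10.0,
            image_id=f"img-{i:05d}",
            total_coccolith_count=recorded_total,
            coccolith_length=measured,
            coccolith_width=c_w,
            process_height=process_height,
            coccosphere_long_axis=h,
            coccosphere_short_axis=d,
            n_layers=n_layers,
            n_exothecal=n_xc,
            n_appendages=n_app,
            appendages_present=app_present,
            loose_adjacent_count=loose,
            partial_length_flag=partial,
            notes="",
        )

        # --- ground truth via per-coccolith enumeration --------------
        f_spin = params.dimorphic_spinose_fraction or 0.0
        components: list[tuple] = []
        for length in liths:
            if f_spin:
                components.append(((1.0 - f_spin), float(length), params.ks_body))
                spine_len = spine_true if spine_true is not None else (
                    params.fixed_spine_length)
                components.append((f_spin, float(spine_len), params.ks_spinose))
            else:
                components.append((1.0, float(length), params.ks_body))
        for _ in range(n_xc):
            components.append((1.0, med, params.ks_exothecal))
        true_pic = _truth_pic(components) + app_truth_pg
        truths.append(SyntheticTruth(
            record_id=record_id,
            taxon_label=entry.key.label(),
            cl_list=tuple(float(x) for x in liths),
            true_cn=cn_total,
            true_cell_diameter=esd_single * params.y_fraction ** (1.0 / 3.0),
            true_cellular_pic=true_pic,
        ))
        records.append(record)
    return records, truths


def recovery_report(
    records: Sequence[CoccosphereRecord],
    truths: Sequence[SyntheticTruth],
    results: Sequence[TraitResult],
) -> pd.DataFrame:
    """Relative bias and RMSE of recovered cellular calcite and cell size.

    Inputs must align one-to-one by record id (results may be a subset when
    records were skipped, but every result must have a truth).
    """
    if len(records) != len(truths) or any(
        r.record_id != t.record_id for r, t in zip(records, truths)
    ):
        raise ValidationError("records and truths are misaligned")
    truth_by_id = {t.record_id: t for t in truths}
    rows = []
    for res in results:
        truth = truth_by_id.get(res.record_id)
        if truth is None:
            raise ValidationError(f"no truth for result {res.record_id!r}")
        rows.append({
            "taxon": truth.taxon_label,
            "pic_rel_err": (res.cellular_pic - truth.true_cellular_pic)
            / truth.true_cellular_pic,
            "cell_d_rel_err": (res.cell_diameter - truth.true_cell_diameter)
            / truth.true_cell_diameter,
        })
    if not rows:
        raise ValidationError("no aligned results to report on")
    frame = pd.DataFrame(rows)

    def _agg(sub: pd.DataFrame) -> pd.Series:
        return pd.Series({
            "n": len(sub),
            "pic_bias": sub["pic_rel_err"].mean(),
            "pic_rmse": math.sqrt((sub["pic_rel_err"] ** 2).mean()),
            "pic_abs_err_p90": sub["pic_rel_err"].abs().quantile(0.9),
            "cell_d_bias": sub["cell_d_rel_err"].mean(),
            "cell_d_rmse": math.sqrt((sub["cell_d_rel_err"] ** 2).mean()),
        })

    per_taxon = frame.groupby("taxon", sort=True).apply(_agg, include_groups=False)
    overall = _agg(frame).to_frame().T
    overall.index = ["(all)"]
    report = pd.concat([overall, per_taxon])
    report.index.name = "taxon"
    report["n"] = report["n"].astype(int)
    return report.reset_index()
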