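# Methods

## The trait computation

`coccotraits` estimates three cellular traits for each intact coccosphere
measured on an SEM image: coccosphere size, cell size, and cellular calcite
(particulate inorganic carbon, PIC).

**Coccosphere volume and size.**  Only two axes of a coccosphere are
measurable on a 2-D image, so each taxon is assigned one of three idealised
shape classes: prolate sphere (π/6·d²h — also used for spherical,
sub-spherical and ellipsoid shapes, since a third axis cannot be measured),
cone-plus-half-sphere (π/4·d²h), and double cone (π/12·d²h, the tapering
fusiform coccospheres of *Calciosolenia*).  Axes are normalised defensively
so d ≤ h, with a warning when inputs arrive reversed.  Size is reported as
equivalent spherical diameter (ESD), making shapes comparable.

**Cell size.**  The organic cell is hidden inside the coccosphere, so cell
volume is estimated as a taxon-specific fraction *y* of coccosphere volume,
calibrated externally from light-microscope measurements of coccosphere and
internal cell diameter.  The cell diameter closed form is ESD·*y*^⅓.
Multilayer coccospheres (*E. huxleyi*) are first shrunk to a single-layer
equivalent by subtracting two coccolith thicknesses (2·0.13 µm) per extra
layer; otherwise *y* would be applied to an inflated volume.

**Calcite.**  The cube law `coccolith PIC = C_L³·Ks·2.7` converts the
taxon's linear size metric to the calcite mass of one coccolith; cellular
PIC multiplies by the coccolith count and adds taxon-specific components.
The result is returned as an exact component breakdown (body, exothecal,
appendage), so the total always equals the sum of its parts.
Circum-flagellar coccoliths are not a separate component: they share the
body shape factor and are included in C_N, which is why the breakdown's
CFC slot stays zero in the standard pipeline.

## Taxon-specific rules

All constants are rows of a delimited-text registry shipped with the
package and overridable by the user (`--registry`).  Lookup falls back
species → morpho-group → genus → life-cycle-phase default, case-insensitive
on genus and species.  The encoded rules:

| Rule | Constants |
|---|---|
| Visible-count multiplier | ×2 (one hemisphere visible); ×3 for *Umbellosphaera* (hidden pseudo-layer) |
| Partial length | centre-to-rim half-length doubled; flagged in provenance |
| *E. huxleyi* | single Ks across morphotypes; y = 86 %; 0.13 µm coccolith thickness for the multilayer correction; loose adjacent coccoliths added to C_N |
| *Syracosphaera* morpho-groups | Ks 0.03 (pulchra group, y 65 %), 0.022 (molischii group, y 75 %), 0.015 (nodosa group, y 75 %), 0.02 genus-level fallback |
| Exothecal coccoliths | counted per record; Ks 0.02 for all morphologies; sized as the body coccolith (no separate XC length is measured) |
| *Rhabdosphaera* | dimorphic 50/50 split; non-spinose Ks 0.025; spinose massed from spine length with a fixed 5 µm fallback; fractional coccolith counts kept as reals |
| *Discosphaera* | trumpet width is the size metric |
| *Michaelsarsia* | 12.5 pg per appendage (four 5.5 µm segments at Ks 0.007); 8 appendages assumed when uncounted (100 pg) |
| *Ophiaster* | fixed 33 pg appendage calcite when arms are clearly present |
| *Alisphaera* polycrater | fixed C_N 400 and C_L 0.8 µm when counting/measuring is impossible |
| *Florisphaera* | fixed C_N 145; nannolith Ks 0.03; y = 10 % |
| Holococcolithophores | Ks 0.036 and y = 80 % as a phase-wide default; C_N back-calculated from surface areas when uncountable |
| *Umbellosphaera* | calcite computed from 0.7·C_L max (the cubic-mean 'average' coccolith calibrated on collapsed coccospheres is 55–81 % of the largest) |

Shape factors that the protocol cites from the wider literature without
stating numerically (e.g. *Gephyrocapsa*, *Calcidiscus*, *Helicosphaera*,
*Umbellosphaera*, the *Rhabdosphaera* spinose Ks) ship as placeholder rows
whose `source_note` says so; no test or reported number depends on them.
The genus-level *Syracosphaera* y is not stated either; the registry uses
0.75, the value shared by two of the three named morpho-groups.

**Holococcolith count back-calculation.**  The protocol states only that
C_N is back-calculated from the surface areas of coccosphere and coccolith.
We model the coccolith footprint as an ellipse (π·L·W/4) tiling the
spherical surface (π·ESD²) in one layer at full coverage:
C_N = round(4·ESD²/(L·W)).  A packing-efficiency parameter (default 1.0)
exposes the coverage assumption.  A missing coccolith width falls back to a
circular footprint (W = L) with a warning.

**Fixed values are fallbacks.**  When a measurement exists alongside a
fixed registry fallback, the measurement wins and a warning is logged.

## Sensitivity analysis

`run_sensitivity` perturbs one parameter at a time — Ks and C_L by
±5…30 %, C_N by ±2 and ±5 coccoliths (floored at one) — and recomputes
cellular calcite through the full rule set.  Perturbations apply to the
*effective* parameters after fallbacks: a C_L perturbation also scales
spine lengths, exothecal sizes and the Umbellosphaera averaged length, so
the cubic law holds exactly for records without fixed-mass components
(the analytic forms 100·δ for Ks, 100·((1+δ)³−1) for C_L and 100·Δ/C_N for
counts are the module's test oracle).  Fixed appendage masses are
conventions and are never scaled; records carrying them respond less than
the closed forms, which the tests assert as an attenuation inequality.
The same attenuation applies to the C_N law for exothecal-bearing records,
since a body-count error does not change the counted XCs.  For
holococcolith records the count back-calculation uses the measured (not
perturbed) sizes, keeping the three perturbation channels orthogonal.

## Synthetic data

The generator draws a taxon mix covering every special-rule code path
(multilayer *E. huxleyi*, exothecal *Syracosphaera*, both appendage rules,
dimorphic *Rhabdosphaera*, trumpet-width *Discosphaera*, double-cone
*Calciosolenia*, *Umbellosphaera*, *Florisphaera*, polycrater *Alisphaera*,
one holococcolithophore).  Coccolith length is lognormal between
coccospheres (geometric spread 15–20 %) with a lognormal
within-coccosphere spread (default relative SD 10 %, configurable up to
the ~30 % observed on single coccospheres); the measured value is a single
draw from that within-coccosphere distribution, emulating the one
flat-lying coccolith measured in practice.  Counts are shifted
negative-binomial with a floor of 4.  Coccosphere axes are drawn so the
coccosphere surface area is consistent with the coccolith count and
footprint — sizes come out realistic (ESD ≈ 6–13 µm) and the holococcolith
surface-area back-calculation recovers the true count by construction.
Noise modes: doubled partial lengths carry a clipped normal relative error
(mean −0.6 %, within ±8 %); counts are mis-recorded by ±1–5 coccoliths;
appendage counts can be unrecorded; spine lengths can be unmeasured.  One
`numpy` Generator seeded from the config drives everything, so identical
seeds give identical tables.

**What the truth is, and what recovery means.**  Each record's ground
truth is an explicit per-coccolith enumeration: the cube-law mass summed
over every true coccolith (body, spinose fraction, exothecal) plus the
fixed appendage conventions.  With all noise at zero the pipeline output
equals this truth to machine precision for every taxon computed from
measured quantities — including the multilayer, exothecal, appendage,
dimorphic and holococcolith paths.  Taxa whose pipeline values are fixed
conventions cannot match a per-coccolith truth by definition:
*Florisphaera* (C_N fixed at 145 regardless of the true count),
*Alisphaera* polycrater (400 × 0.8 µm), and *Umbellosphaera*, whose
0.7·C_L-max rule applied to a zero-spread coccosphere yields exactly
0.7³ ≈ 0.343 of the uniform-lith truth — the tests assert these offsets
rather than pretending they recover.  Passing tests therefore demonstrate
the correctness of the computation rules, not the field accuracy of the
fixed conventions themselves.

The generator emulates table structure and error magnitudes, not ecology:
community composition, depth structure, covariances between size and
count, and morphotype-level variability are not modelled.

## Numerical choices

* Closed-form arithmetic only; equality assertions use 1e−9 relative
  tolerance (1e−12 where a path is algebraically exact).
* Fractional coccolith counts from the dimorphic split are carried as
  reals — mass, not coccolith identity, is the quantity of interest.
* Output formatting: raw measurement columns are echoed with
  shortest-round-trip float representation so that write → read → compute
  → write is byte-identical; derived lengths/volumes print at 4
  significant figures and masses at 2 decimals.
* The holococcolith count estimate rounds to the nearest integer and
  errors if it falls below one coccolith (coccolith larger than the
  coccosphere).
* Degenerate inputs (non-positive lengths, counts below one, multilayer
  corrections exceeding the diameter) raise typed domain errors rather
  than propagating NaNs.
* Problem sizes in the test suite and acceptance script (120–400 synthetic
  records, a 10⁶-point Monte-Carlo volume check) were chosen as the
  smallest sizes at which the distributional checks are stable; everything
  runs in seconds on one CPU.

## Known limitations

* True triaxial-ellipsoid volumes are not computed; elongated shapes use
  the prolate-spheroid formula, as the measurement geometry dictates.
* *Acanthoica* polar-spine calcite is left unmodelled (no single shape
  factor reproduces the cited spine-mass range), so its coccosphere
  calcite is underestimated.
* The ±19 % calcite uncertainty attached to the single-Ks *E. huxleyi*
  policy is recorded as registry metadata only; no morphotype
  classification is attempted.
* Placeholder shape factors (see above) must be confirmed against the
  primary literature before quantitative cross-taxon comparisons.
* No combined-uncertainty propagation: parameters are perturbed one at a
  time, matching the published scheme; correlated Ks–C_L perturbation is
  out of scope.
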