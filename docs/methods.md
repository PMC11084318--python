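# Methods

## Physical model

The pipeline treats X-ray image formation as primary-beam Beer–Lambert
attenuation. For a ray from a point source through a phantom of homogeneous
primitives, the detector reads

    I = I0 · Σ_E W(E) · exp(−Σ_m μ_m(E) · L_m) / Σ_E W(E)

where `L_m` is the exact chord length of the ray through material `m`
(closed-form for axis-aligned boxes and z-aligned finite cylinders), `μ_m`
is the material's linear attenuation coefficient, and `W(E)` is the spectral
weight — the relative photon fluence `S(E)` for a photon-counting detector or
`S(E)·E` for an energy-integrating one. A disk embedded in a slab replaces
the slab material over its chord, so along any ray the total attenuating
length equals the slab chord. No scatter, no detector blur, no inverse-square
or obliquity falloff: `I0` is a per-image flat-field constant. These are the
standard assumptions of analytic projection simulators; they bias absolute
intensities but cancel out of the ratio-based comparison statistics the
pipeline reports.

Material attenuation uses the elemental mixture rule
`μ/ρ = Σ_i w_i (μ/ρ)_i` with weight fractions from parsed molecular formulas
(IUPAC atomic masses rounded to 3 decimals) and a bundled elemental table
(H, C, N, O, Na, Al, Rh, I) transcribed from the public NIST XCOM
tabulation. Anchor energies are interpolated log-log linearly — exact for the
power-law photoelectric regime between absorption edges, accurate to ~1%
elsewhere. Absorption edges (Rh K at 23.2199 keV, I K at 33.1694 keV) are
duplicated grid rows; evaluation exactly at an edge returns the above-edge
value (half-open `[edge, ∞)` convention), with `side="below"` available.
Below 10 keV the curves are smooth extensions used only for beam filtration;
iodine L-edge structure near 5 keV is deliberately smoothed out, since those
photons do not survive any modelled filter/phantom combination.

## Study materials and conditions

The two agents are compared at a fixed per-cavity iodine concentration of
23.35 mg I/mL:

* NaDITMB, C10H9I2NaO5 (485.98 g/mol, 52.2% iodine by mass): 4.47% w/w in
  water.
* Iohexol (Omnipaque), C19H26I3N3O9 (821.14 g/mol, 46.4% iodine): 5.03% w/w
  in water.

Computational solutions use unit density (required for the stated weight
fractions to produce 23.35 mg I/mL); the experiment emulation uses the
measured solution density of 1.04 g/cm³ and derives the weight fraction from
the target iodine concentration instead. Both are configurable.

Phantoms:

* Simulation phantom: 45 mm PMMA slab (ρ = 1.19 g/cm³), 14 disks of radius
  10 mm, thicknesses linearly spaced 0.2–2.6 mm (a 0.2 mm step would give
  only 13 values, so the 14 printed thicknesses are spaced 2.4/13 mm apart),
  centered in depth, laid out 2 × 7 with 5 mm gaps. The lateral arrangement
  is not physically constrained — any non-overlapping layout gives the same
  per-disk statistics. Geometry: source–object 100 cm, source–detector
  130 cm, detector 4000×4000 at 0.1 mm (desk-scale default 500×500 at
  0.8 mm — identical physics on a coarser grid).
* Well plate: 1 mm polystyrene base, two rows of eight liquid columns
  (inner diameter 6.4 mm, 9 mm pitch — standard 96-well format; none of
  these is stated by the source experiment, all are configurable), row A
  NaDITMB / row B Omnipaque, volumes 0.2 mL (cavities 1–3) and 0.1 mL
  (4–8), column height = V/(πr²). Geometry: 100 cm / 110 cm, 1240×380 at
  0.148 mm.

## Spectra

Published tube spectra for the study's beam qualities are not tabulated in a
redistributable form, so the bundled fixtures are generated: Kramers
continuum `S(E) ∝ (kVp − E)/E` on a 0.5 keV grid from 5 keV, hardened by
exponential filtration, plus Rh Kα/Kβ lines (20.2/22.7 keV, 18%/4.5% of the
filtered continuum fluence) for the Rh anode. Filter thicknesses of the two
simulation beams were calibrated once against the declared beam qualities —
mean energy 20.0 keV at 35 kVp Rh/Rh and 51.0 keV at 100 kVp W/Al — and are
frozen in `FIXTURE_TUBES` (`scripts/make_spectrum_fixtures.py` regenerates
the TSVs). Because the continuum model omits anode self-filtration and
characteristic W lines, the calibrated thicknesses (0.32 mm Rh, 5.2 mm Al)
are thicker than real tube filters; the spectra are honest approximations of
beam quality, not of any specific tube. The 46/80/95 kVp survey beams use a
fixed 2.5 mm Al filtration. User-supplied two-column spectra override the
fixtures everywhere.

## Two-branch K-edge parametrization

Tabulated μ/ρ of iodinated materials is summarized by the five-parameter
form

    μ/ρ(E) = exp(−λ1 − λ2·ln E + λ3/ln E + λ4/(ln E)²) + λ5

fitted independently below and above a branch boundary (natural logarithm,
E in keV, μ/ρ in cm²/g — the convention is stored with every fit). A smooth
branch cannot absorb a discontinuity, so quality fits must split exactly at
the table's iodine K-edge (33.1694 keV); this is the `boundary="edge"`
default. A boundary elsewhere (e.g. the sometimes-quoted 31.17 keV) is
accepted but leaves the edge jump inside the upper branch and degrades it —
the CLI warns in that case. Fitting profiles the additive offset λ5 (the
model is linear in λ1–λ4 in log space at fixed λ5) over a dense scan with
local refinement of every candidate basin, then polishes all five parameters
by least squares on relative residuals. This recovers generating parameters
of synthetic curves to ~1e−12 and fits the study solutions' tables with max
relative residual ≤ 1.8% per branch. Published λ tables for these agents are
not reproduced: their log/unit convention is not recoverable, so the package
always refits and reports its own convention alongside.

## Synthetic radiographs (what the generator emulates)

The generator emulates the physical well-plate experiment: an
energy-integrating polychromatic projection, automatic exposure control, and
photon noise.

* AEC: the incident fluence is scaled so the mean background signal (base
  present, no liquid column) lands on a fixed target digital number, 60% of
  the 16-bit range — mimicking an AEC's constant-detector-signal behaviour.
* Photon budget: 10,000 mean counts per background pixel at the AEC
  solution; Poisson noise is sampled in the count domain and quantized to
  16 bits. DN-per-photon gain = target/10,000.
* Polarity: raw detector signal (more photons → larger grey value). The
  deviation statistic is a ratio of like-for-like ROI means, so it is
  invariant under common positive rescaling and insensitive to display
  transforms applied to the whole image.

Emulated, not modelled: scatter, detector MTF, glare, automatic
post-processing of a clinical radiography system, and the actual fluence of
any specific tube. Consequently the synthetic images reproduce the
qualitative experimental behaviours (contrast falls monotonically from 46 to
100 kVp; low-kVp images fluctuate more behind the wells) and give matched-
iodine deviations well below 2%, but they cannot reproduce an experiment's
specific deviation values — e.g. a 3.7% outlier at 46 kVp driven by real
low-fluence conditions. Analyzing the deposited experimental images, when
available locally, uses the identical ROI pipeline.

## ROI statistics

Each ROI is the set of exactly N pixels (default 1124, the study's ROI size)
closest to the magnified cavity center, ranked by distance with a
deterministic angle-then-index tie-break. Means use the arithmetic mean; the
spread is the population standard deviation. Deviation:
`100·|mean_test − mean_ref|/mean_ref` with Omnipaque as reference, paired by
cavity column across rows, grouped by (kVp, volume). Line-integral profiles
average the central 50% of each disk's projected footprint (projected radius
= r·D2/z).

## Numerical choices and degenerate inputs

* Chord formulas handle rays parallel to faces/axes explicitly; misses
  return 0. Path lengths are aggregated per distinct material so the energy
  loop is independent of the primitive count.
* Air pixels get line integral exactly 0; effective line integrals clamp
  |value| < 1e−12 to 0 to absorb log/exp round-off.
* Spectrum loading: inputs already on a uniform grid are kept verbatim
  (lossless round-trip); irregular inputs are deposited into the nearest
  0.5 keV bin, conserving fluence.
* All randomness (Poisson noise) flows through explicit integer seeds;
  identical seeds give byte-identical images.
* Solutions validate weight-fraction closure to 1e−9; formulas validate
  element symbols and positive counts.

## Desk-scale defaults

Tests and the acceptance script run the simulation study at 500×500 (or
smaller) detectors with the physical detector area kept fixed, and the
radiograph study at the native 1240×380. These sizes were chosen as the
package's own desk-scale defaults: the physics is resolution-independent
(per-disk means at 500×500 match finer grids to well within the reported
tolerances), and full 4000×4000 runs remain available via configuration.

## Known limitations

* Elemental attenuation anchors are accurate to a few percent, not XCOM's
  native precision; all pipeline conclusions are ratio-based and insensitive
  at this level.
* Primary-beam-only imaging: no scatter or detector response, so absolute
  grey values are not comparable to a real system's.
* The tube model is a calibrated approximation of beam quality only.
* No voxel/DICOM phantoms, no tomography, no Monte Carlo transport, no
  dual-energy subtraction.
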