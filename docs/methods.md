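# Methods

## Measurement model

A heated, body-shaped manikin divided into 17 independently controlled
surface zones (head, chest, back, stomach, buttocks, paired upper/lower
arms, hands, thighs, calves, feet) is regulated at a 34 °C surface
set-point while zone surface temperatures (°C) and heat losses (W) are
logged at 10-second intervals. Two protocols are supported:

* **Dry**: the chamber is cooler than the manikin (typically 20 °C for
  single items and light combinations, 10 °C for heavy protective gear),
  mean radiant temperature equal to air temperature, low air velocity.
  The steady heat loss through each zone measures its total thermal
  insulation.
* **Wet (isothermal sweating skin)**: the manikin wears a wetted textile
  skin and the chamber is held at the surface set-point (34 °C, 40 % RH).
  With no dry temperature gradient, the measured heat loss is evaporative,
  and resistances to vapour transfer follow from vapour-pressure
  gradients. The relative humidity at the wetted skin is taken as 96 %
  (a per-trial field, not a constant of nature).

## Reductions

Zone total insulation: `I_T,i = (T_s,i − T_o) A_i / H_c,i` (m²K/W). The
whole-body aggregation offers three conventions:

* **global** (default): area-weight the temperatures, sum the losses —
  `I_T = (Σ T_s,i A_i / A − T_o) · A / Σ H_c,i`. Chosen as default because
  heavily layered zones (buttocks, abdomen) can drop to near-zero or even
  negative measured flux, which destabilises any per-zone division; the
  global form only ever divides by the whole-body loss.
* **serial**: area-weighted mean of zone insulations, `Σ (A_i/A) I_T,i`.
* **parallel**: area-weighted conductance sum, `A / Σ (A_i / I_T,i)`.
  The parallel formula is a literature convention (the source protocol
  only names the method); we implement the reciprocal area-weighted form.

Serial ≥ parallel for any heterogeneous zone set (weighted AM–HM
inequality, equality iff all zones equal), and with a uniform surface
temperature global coincides with parallel exactly — both identities are
enforced in tests to machine precision.

Intrinsic (clothing-only) values subtract the boundary air layer scaled by
the clothing area factor: `I_cl = I_T − I_a / f_cl`, with the whole-body
nude value `I_a = 0.099 m²K/W` shipped as a constant (zone-level air-layer
values are not part of the database). A negative result — possible for
very thin items with `f_cl ≈ 1` and rounded inputs — is reported with a
warning, never clamped.

Wet mode computes vapour pressures from the psychrometric closed form
`p = exp(18.956 − 4030/(T + 235)) · RH` with RH in **percent**, which
yields pascals directly (the exponential alone is in hPa; at 34 °C it is
≈ 53.2, so saturation ≈ 5322 Pa). The raw resistance uses the set-point
surface temperature; the corrected value first depresses each zone's skin
temperature by `0.0132 K per W/m²` of evaporative flux, area-weights the
corrected temperatures, and recomputes the driving pressure. Further
published corrections (skin-material resistance, moist-skin insulation)
are deliberately not applied. Clothing-only resistance mirrors the dry
relation: `R_ecl = R_et − R_ea / f_cl` with `R_ea = 8.0 m²Pa/W` (the
corrected whole-body value of the wetted textile skin alone).

## Steady-state selection and QC

The stable period is chosen automatically: the latest window of
configurable length (default 600 s, mirroring the "last 10 minutes"
convention) in which both the whole-body heat loss and the area-weighted
mean surface temperature have |linear-trend slope| ≤ 0.5 % of the window
mean per minute and coefficient of variation ≤ 0.02. The criteria and
defaults are this package's choices — measurement protocols state the
goal ("constant heat loss") but not the test. The window is applied
whole-body, not per zone.

Per-zone *mean* heat losses are floored at 0.01 W before any division
(raw samples are left untouched, including negative readings), so the
serial/parallel variants remain finite on pathological zones while the
global method is unaffected.

Duplicate measurements are accepted when their relative difference,
`|a − b| / mean(a, b)`, is at most 4 % (pass at equality). The denominator
choice (symmetric mean) is ours; the convention is configurable.

## Ensemble models

Ensemble intrinsic insulation is predicted from the plain sum of member
items' intrinsic insulation through `I_cl = slope · ΣI_clu + intercept`
(clo). Three built-in lines ship in `data/model_coefficients.yaml`:

| model | slope | intercept (clo) | provenance |
|---|---|---|---|
| standard | 0.835 | 0.161 | literature convention, not fitted here |
| incident | 0.835 | 0.311 | turnout ensembles, fixed conventional slope |
| operational_uniform | 0.975 | −0.194 | station-wear ensembles, free fit |

The clothing area factor is estimated as `f_cl = 1.02 + 0.2314 · I_cl`
(I_cl in clo; fitted on the 25 packaged ensembles, R² ≈ 0.978) or as
`f_cl = 1.01 + 1.599 · I_cl` (I_cl in m²K/W; a modern-Western-wardrobe
line). Unit mismatches between a model and its input are errors, not
silent conversions.

Refitting uses ordinary least squares (statsmodels) for free fits and the
closed form `intercept = ȳ − slope·x̄` for fixed-slope fits, whose R² is
reported against the constrained line (never above the free fit's). The
group split used for refits — operational uniform = C1…C3B (14 rows),
incident = C4…C9B (11 rows) — is stored as an editable database column;
the exact subsets behind the published refit statistics are not
enumerable from the source tables, so refits report their own R² with
provenance instead of asserting equality with published values. On this
split, the free station-wear refit lands on slope ≈ 0.975 /
intercept ≈ −0.19, matching the published line's coefficients.

## Wardrobe database

`data/items.csv` (37 items, ids 1…31B; the historical numbering skips 20)
and `data/ensembles.csv` (reference rows AL = nude, SK = textile skin,
plus 25 ensembles with semicolon-separated composition lists) are UTF-8
comma-separated with `.` decimals. Loading validates schema, uniqueness,
composition resolution, group labels and the all-or-none rule for
evaporative columns; the audit recomputes every derived column
(`I_clu/I_cl` from `I_T, f_cl, I_a`; the clo conversion; `R_ecl`; both
permeability indices) with per-row tolerances of one unit in the last
printed digit (0.0015 m²K/W, 0.005 clo, 0.15 m²Pa/W, 0.015 on indices).
Two documented exceptions: ensembles C4 and C6A carry clo values converted
from unrounded SI inputs upstream, so their clo check uses one full
printed unit (0.01); and the SK reference row's intrinsic value does not
follow the clothed-row recomputation, so only its clo conversion is
audited. The CSVs are pinned by SHA-256 in the tests. Ensemble C1B's
composition is normalised to item 14A (fully zipped softshell) per its
dressing note; companion schemas for zone-level (local/regional) values
are out of scope and ship empty.

## Synthetic generator

The generator inverts the reductions: given true per-zone insulation
(dry) or evaporative resistance (wet) it produces the steady per-zone
losses — dry via `H_i = (T_set − T_o) A_i / I_i`; wet by solving the
scalar fixed point `Q = (p_sk(T_set − 0.0132 Q) − p_a)/R` per zone with
damped iteration (factor 0.5, tolerance 1e-6 W/m², ≤ 50 steps; the
damping is for robustness of the mildly contracting map). An optional
exponential warm-up (heat loss starting at twice the steady value) models
the approach to equilibrium after dressing. Noise is i.i.d. Gaussian per
sample: additive on temperatures (°C) and multiplicative-fractional on
heat losses — the simplest model consistent with the small reported
chamber variation; it deliberately omits drift, zone-correlated control
errors, humidity-sensor lag and radiative coupling, so recovery results
bound estimator behaviour under idealised noise, not instrument systematics.
Identical spec + seed reproduces a trial bit for bit.

The default geometry is a **nominal** 17-zone area table summing to
1.77 m² (the source instrument's zone areas are not published); it is a
package default for synthetic work, and user-supplied geometry is expected
for real reductions.

Recovery experiments define the true whole-body value operationally as the
reduction of the noise-free, warm-up-free trial, so any method variant can
be benchmarked against its own noise-free limit. Test problem sizes
(1200–1800 s trials at 10 s sampling, 20–100 seeds) keep the whole suite
in the seconds range while the standard-error bounds asserted remain
comfortably above the Monte-Carlo noise floor.

## Known limitations

* Wind/motion corrections, sensor offset calibration, photographic
  clothing-area-factor measurement and the mass-loss evaporative method
  are out of scope; only heat-loss-based values are handled.
* The wet reduction assumes isothermality; deviations are flagged beyond
  0.5 °C and fail beyond 3 °C, and no dry/evaporative partitioning is
  attempted in between.
* Zone-level evaporative resistances use the corrected skin temperature;
  whole-body and zone values are self-consistent within the package but
  local values from other protocols may use the set-point convention.
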