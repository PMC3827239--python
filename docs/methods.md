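# Methods

## Scope and assumptions

The package treats each pond visit as an independent observation of a
well-mixed surface layer. Gases are ideal; ponds are fresh (no salinity
correction) and near sea level (1 atm default, configurable per
measurement); CO₂ is treated as a dissolved gas without carbonate-system
speciation — adequate for the acidic, DOC-rich waters these ponds typically
are, and consistent with the headspace method, which measures free CO₂.

## Dissolved gas from headspace equilibration

The inversion assumes the water–headspace system reaches Henry equilibrium
and conserves mass:

    C₀·V_w + p_air·V_h/(R·T_K) = K_H(T)·p_eq·V_w + p_eq·V_h/(R·T_K)

solved for C₀. Two estimators are exposed: the full mass balance (default)
and the simple `K_H·p_eq` approximation; with the standard 2 L / 20 mL
protocol they differ by well under 1% for CO₂ (high solubility) and by a few
percent for CH₄ at high supersaturation, which is why the mass balance is
the default. A negative inversion result signals mutually inconsistent GC
readings; it is returned flagged, never clamped or dropped, so QC can count
failures.

Henry constants use the van 't Hoff form with reference solubilities at
25 °C (CO₂ 3.4×10⁻² mol L⁻¹ atm⁻¹, B = 2400 K; CH₄ 1.4×10⁻³, B = 1700 K) —
standard freshwater values. The equilibration temperature is taken as the
water temperature recorded with the sample; a lab temperature can be
supplied instead. All per-gas constants, including the atmospheric mixing
ratios used for C_eq (CO₂ 390 ppm, CH₄ 1.8 ppm), live in
`pondghg.constants` and can be overridden from a TOML file — nothing is
hard-coded in the operations.

## Diffusive flux

k₆₀₀ comes from the classic low-wind lake wind model
(2.07 + 0.215·U₁₀^1.7 cm h⁻¹); the Schmidt conversion uses
(Sc/600)^(−2/3) below 3 m s⁻¹ and (Sc/600)^(−1/2) at or above, with the
boundary assigned to −1/2 (the rippled-surface convention). Wind is averaged
over the 2 h preceding the sample; an empty window is an error naming the
interval, never a silent default. The multiplicative correction (default
0.2458) compensates the wind model's bias in small, sheltered, thermally
stratifying ponds; it was derived from CO₂ chamber series and is applied to
both gases, with a per-call override. The calibration regression is
through the origin (a pure factor); an intercept mode exists for sensitivity
analysis, and the conventional centred r² is reported either way.
Micro-ebullition is not folded into diffusive flux, so diffusive CH₄
estimates are conservative. Diurnal variability is summarised as a
coefficient of variation (100·sd/mean, sample sd); a range/mean mode is
available since the convention is ambiguous in parts of the literature.

## Ebullition

Funnel accumulations convert collected volume × CH₄ fraction to moles via
the ideal-gas molar volume at ambient air temperature and divide by funnel
area × accumulation days. The flux is linear in the CH₄ fraction and
invariant to splitting a collection into sub-collections (time-weighted).
Bubble dissolution during rise and point-source/hotspot ebullition are out
of scope (no supporting data in the sampling design being emulated).

## Stable isotopes

The CD diagram uses rectangular regions — acetoclastic δ¹³C ∈ [−65, −50] ‰ ×
δD ∈ [−400, −250] ‰; hydrogenotrophic δ¹³C ∈ [−110, −60] ‰ ×
δD ∈ [−250, −150] ‰ — literature-convention defaults, fully configurable,
and every classification records the boundary set used. Rectangles (not
polygons) keep membership testable; the regions overlap only on a
measure-zero line, where the call is "mixed". δD is mandatory for the CD
call: without it, hydrogenotrophic production cannot be excluded, so the
classifier refuses rather than guesses. The αC classifier uses
[1.040, 1.055] (acetoclastic), (1.055, 1.090] (hydrogenotrophic), and flags
αC < 1.040 as oxidation-affected, since methanotrophy enriches residual CH₄
in ¹³C and compresses the apparent fractionation. Instrument precisions
(±0.2‰ for carbon, ±3‰ for hydrogen) are used by the synthetic generator
only; classification itself is deterministic.

## Radiocarbon

Δ¹⁴C → fraction modern uses the reporting decay constant 1/8267 yr⁻¹
referenced to 1950 and the year of measurement (default 2011); conventional
ages use the Libby mean life 8033 yr. Fm = 1 is age 0; Fm > 1 is post-bomb
and flagged rather than given a negative age. The modern/old boundary is a
conventional-age window (default 60 yr). Old-carbon apportionment is linear
in Fm between a contemporary endmember (default Fm = 1.05, a plausible
recent-decade value for atmosphere-fixed carbon; the result is mildly
sensitive to this choice, which is why it is configuration) and an old
endmember at the basal-peat age of 3670 BP. Samples outside the endmember
interval are clamped to [0, 1] with a flag — AMS noise routinely pushes
near-pure samples past an endmember. Since Fm is linear in Δ¹⁴C and f_old
linear in Fm, Gaussian Δ¹⁴C noise propagates without bias; the tests verify
this at the 2.5–3.1‰ AMS error level. Calendar-year calibration (IntCal) is
out of scope.

## Group statistics and upscaling

Welch's t (statistic and Welch–Satterthwaite df from the formulas, two-sided
p from the t distribution) compares runnel vs polygonal groups; a paired t
handles repeated measures. Degenerate inputs (zero pooled variance) return
flagged results instead of dividing by zero. No multiple-testing correction
is applied; the report manifest records the number of tests run. Landscape
shares are area fraction × mean areal flux, normalised; negative mean fluxes
(net uptake) contribute zero emission share. Other waterbody types (lakes)
enter the share simply as additional rows.

## The synthetic campaign generator

The generator emulates the sampling design the analysis targets: 33
polygonal and 58 runnel pond visits with dissolved CO₂ of
9.6 ± 8.9 / 119 ± 124 µM and CH₄ of 1.3 ± 1.7 / 4.1 ± 4.7 µM
(polygonal/runnel, arithmetic mean ± sd), drawn from lognormals
moment-matched to those summaries — lognormal because concentrations are
positive and the CH₄ summaries have sd > mean, which excludes anything
near-symmetric. Headspace GC readings are forward-simulated from the true
concentrations by the same mass balance the inversion solves, with 2%
multiplicative lognormal GC noise (a typical FID repeatability; the design
being emulated does not state one). Wind is lognormal with mean 4 m s⁻¹ —
the 45% coefficient of variation is the stated condition, the mean is not —
at 10-minute cadence, covering a 2 h lead before every sample. Water
temperatures are uniform on 4–18 °C and air temperatures on 2–21.4 °C
(ice-free-season bounds, kept inside the Schmidt fit's validity). Funnel
collections are drawn so the implied CH₄ flux follows a lognormal
(median 0.5 mmol m⁻² d⁻¹, σ = 0.9) truncated at the observed maximum of
2.13 mmol m⁻² d⁻¹, with bubble CH₄ content uniform on 1.5–32% by volume;
the recorded gas volume is back-computed from the true flux, so ebullition
recovery is exact at zero noise. Isotope samples are drawn from the interior
of the configured pathway regions (default mixture: 100% acetoclastic, the
summer situation) with a pathway-consistent αC, then perturbed at instrument
precision. Radiocarbon samples mix the endmembers with true old fractions
uniform on 0–0.04 (polygonal) and 0.05–0.105 (runnel) — spans chosen so the
resulting Δ¹⁴C covers the observed −1.1 to 114.9‰ range and preserves the
runnel-higher ordering — with 2.8‰ Gaussian AMS noise.

Every observational row traces to a ground-truth row, and a fixed seed gives
byte-identical CSVs. What the generator does **not** emulate: temporal
autocorrelation of repeated visits (draws are independent), within-pond
spatial structure, mechanistic production/oxidation dynamics, seasonal
pathway shifts, and point-source ebullition. Passing recovery tests
therefore demonstrates that the analysis chain is internally consistent and
unbiased under the stated noise model — not that it is robust to field
phenomena the generator omits.

## Numerical choices and problem sizes

Headspace inversion and its forward simulator are closed-form; the test
oracle is an independent bisection on the equilibrium partial pressure (200
iterations, bracketing [0, all-gas-in-headspace]). Recovery suites use 1000
random equilibrations (relative error < 10⁻⁹ enforced), 500 calibration
replicates at n = 57 for the correction factor, 1000 joint draws for
classifier agreement, 10⁴ draws for radiocarbon mixture bias, and 200
campaigns of 30 + 30 ponds for the group-contrast study (100 in the
acceptance script), with 2000 equal-group replicates for the Welch type-I
calibration — sizes at which Monte-Carlo error is comfortably below the
asserted tolerances while the whole suite runs in well under a minute of
the respective budgets. Ratio-of-group-means estimators carry a small
positive finite-sample bias under lognormal spread (~+5% at n = 30); the
group-contrast check accounts for it by asserting a 10% band, and the
generator-level unit test uses pooled means, which are unbiased.
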