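# Methods

This document records the models implemented in `pcdsim`, the assumptions
behind them, how the synthetic data was generated and validated, and where
the simplifications are known to matter.

## 1. Attenuation data (`pcdsim.materials`, `scripts/generate_attenuation_tables.py`)

Mass-attenuation tables for the 17 elements used by the bundled materials
(H, Be, C, N, O, F, Al, Ar, Cu, Zn, Br, Cd, I, Te, La, Ce, W) are shipped as
plain text under `src/pcdsim/data/attenuation/` and were generated by
`scripts/generate_attenuation_tables.py` from first-principles ingredients:

* **Photoelectric**: from Cromer–Liberman anomalous-scattering imaginary
  parts f″(E) via μ/ρ = 2 r_e λ f″ N_A / A.
* **Incoherent (Compton)**: analytic Klein–Nishina cross section per
  electron times Z/A (free-electron approximation; binding corrections
  omitted — a few-percent effect below ~30 keV for high-Z elements).
* **Coherent (Rayleigh)**: Thomson cross section times squared atomic form
  factors (IT92 analytic fits), integrated over momentum transfer.  The fits
  are only valid to s = sin(θ/2)/λ ≤ 2 Å⁻¹; beyond that the form factor is
  extrapolated as s⁻³, without which the integrated coherent cross section
  is overestimated ~3× for high-Z elements.

Each table holds ~90 geometrically spaced points from 1 to 300 keV plus
points straddling each K edge at E_K·(1±0.001), so log-log interpolation
never crosses an edge.  Totals were spot-checked against standard reference
values during generation (e.g. Pb-free anchors: water at 60 keV 0.211 vs
0.206 cm²/g reference; Cu at 100 keV within ~3%).  Accuracy is a few percent,
adequate for the behavioral claims of the framework; it is **not** a
metrology-grade attenuation library.

Mixtures combine elemental μ/ρ by mass-fraction additivity; fractions are
normalized on load.  K-fluorescence data (edge energies, fluorescence yields
ω_K, Kα/Kβ line energies and relative intensities) is bundled in
`fluorescence.yaml`.  The K-shell share of photoelectric absorption above the
edge is derived from the tabulated edge jump ratio J as 1 − 1/J.

## 2. Tube spectrum (`pcdsim.spectra`)

The X-ray tube model is Kramers' law, N(E) ∝ (kVp/E − 1), attenuated by
9 µm of tungsten anode self-filtration, plus the tungsten K lines
(Kα₁, Kα₂, Kβ₁, Kβ₃ at their tabulated energies and relative intensities)
carrying 6 % of the emitted fluence at 120 kVp and scaling as
(kVp/E_K − 1)^1.65.  The two calibration constants (self-filtration
thickness, characteristic fraction) were chosen once so that the filtered
beam quality is realistic; they were not adjusted afterwards.

The RQA9 operating beam is 120 kVp filtered by 0.8 mm Be + 0.10 mm Cu
(intrinsic) + 40 mm Al (added).  The model beam has a kerma-weighted
first half-value layer of 11.35 mm Al against the nominal 11.6 mm, and a
fluence-weighted mean energy of 76.6 keV.  Published descriptions of RQA9
sometimes quote a much lower mean energy (~63 keV); that value is not
reproducible from any beam with an 11.6 mm Al HVL (such a beam has an
effective energy ≳ 74 keV) and likely refers to a differently weighted or
deposited-energy mean.  The fluence-weighted mean is reported as computed.

Spectra live on a fixed 1 keV grid.  `half_value_layer` solves the Beer–
Lambert condition with Brent's method; `match_thickness` finds the
LaBr₃:Ce thickness with the same spectrum-averaged transmission as 2 mm CZT
(result: 2.81 mm, reported as 2.8).

## 3. Photon transport (`pcdsim.transport`)

Per-photon energy deposition in the 5×5 pixel array is computed by a
vectorized simplified Monte Carlo, replacing full particle transport while
keeping the effects the pPSF analysis relies on: absorption efficiency,
K-escape and fluorescence crosstalk between pixels, Compton scatter
crosstalk, and the reflector dead area of the indirect detector.

* Photons arrive uniformly over the array (operating spectrum) or over one
  pixel's pitch (probe); photons entering the 60 µm reflector septum of the
  LaBr₃:Ce detector are absorbed without signal.
* Free path lengths are sampled from μ_pe + μ_incoherent; coherent scatter
  is excluded from transport (it redirects without depositing energy and its
  small-angle dominance makes its crosstalk contribution minor at this pixel
  pitch).
* Photoelectric events deposit the full photon energy locally minus, with
  probability (K share)·ω_K, one K photon sampled from the element's line
  table (element chosen ∝ its share of elemental photoelectric absorption).
  The fluorescence photon is transported isotropically and deposits its full
  energy at its next interaction point or escapes.
* Incoherent scatter deposits the Compton electron energy locally and
  continues the photon, with the scattering angle sampled by Kahn's
  rejection method (validated against numerical integration of the
  Klein–Nishina distribution to 4 decimals).
* The recursion depth is 5 scatters, after which the photon is forced to
  absorb or escape; at these energies and geometry the ≥5-scatter population
  is negligible.
* Electron range is zero: no charge sharing (direct detector) and no light
  spread (indirect detector).  The closed-form border-overlap estimate
  `charge_sharing_fraction` quantifies how many events this omission
  affects (11–24 % depending on pixel geometry).

Deposits in the same pixel from one photon history are merged into a single
deposition event at the arrival time.  All randomness flows through named
`numpy` `SeedSequence` substreams (arrivals, energies, transport, blur,
probe, thinning) so that adding a probe or a lesion never perturbs the
baseline realization (common random numbers).

## 4. Pulse train and counting (`pcdsim.pulsetrain`, `pcdsim.counting`)

Each deposition event is blurred in energy by the detector's Gaussian
resolution (relative FWHM ∝ E^(−1/2), anchored at 59.5 keV; negative draws
clamp to zero) and stamped onto a 1 ns grid as a unit-peak pulse scaled by
the blurred energy: a 14 ns-FWHM Gaussian for the direct detector, a
biexponential exp(−t/16 ns) − exp(−t/7 ns) for the indirect one.  Pulses add
linearly; there is no baseline shift or pulse-shape distortion model.

Counting thresholds at 20 keV.  A *crossing* at sample t means
signal[t−1] < threshold ≤ signal[t].

* **P-like (paralyzable)**: every upward crossing produces one count; the
  registered energy is the signal maximum over the following τ_pd samples.
* **NP-like (non-paralyzable)**: a crossing opens a τ_np dead window; the
  registered energy is the maximum over τ_pd within it; the next count
  requires a *fresh* crossing after the window ends.

Both match the analytic dead-time rates n·e^(−nτ) (P) and n/(1+nτ) (NP) for
random arrivals.  A consequence of the fresh-crossing rule: at extreme rates
where the summed signal never falls below threshold, no new windows can open
and the NP rate collapses toward zero — the fully saturated regime.  NP count
rate is monotone in input rate only below that regime (asserted in the
tests), and NP ≤ P always.

The timing windows are *derived*, not set: the amplitude of the largest
pulse is 120 keV plus the absolute FWHM at 120 keV, τ_np is the time over
the 20 keV threshold rounded up plus 1 ns, τ_pd the rising-crossing-to-peak
interval rounded up plus 1 ns.  This yields (τ_np, τ_pd) = (51, 11) ns for
LaBr₃:Ce and (24, 13) ns for CZT.

Implementation note: counting is exact but avoids materializing the dense
waveform when possible.  Events are clustered by gaps ≥ kernel + τ + 2 ns;
isolated events are counted analytically, clusters are synthesized and
scanned; a dense-waveform fallback covers pathologically dense trains.  A
property test asserts the fast path is bit-identical to the dense scan over
12 rate/shape regimes.

## 5. pPSF estimation (`pcdsim.ppsf`)

The pPSF is estimated by paired runs sharing the operating-spectrum
realization: the baseline pixel×bin rates are counted once, then for each
probe energy only the pixels whose pulse trains the probe can touch are
re-counted with the probe photons added.  The estimate is

    h = (d_with_probe − d_baseline) / (ΔΦ̇_probe · A)

with A = 0.25 mm² the pixel area.  Standard errors come from splitting the
exposure into 8 sections and treating per-section paired differences as
replicates.  The probe grid defaults to 20–150 keV in 2 keV steps.

**Probe rate.** The probe must be weak against the operating beam but strong
enough for statistics.  The default is 10⁶ mm⁻² s⁻¹ (probe self-pile-up
within the longest window is ~1 %, still small-signal) — raised from an
earlier 10⁴ floor at which the estimator needed seconds of simulated train
for usable error bars.  Estimates at operating rates ≥ 10⁸ use min(10⁶,
1 % of the operating rate) semantics via `default_probe_rate`.

## 6. Contrast and CNR (`pcdsim.metrics`)

* **Direct contrast**: two coupled exposures; the lesioned stream is an
  exact Bernoulli thinning of the baseline stream with per-photon keep
  probability exp(−(μ/ρ)ρx) at the photon's energy, reusing the transport
  and blur draws.  This couples the runs so the contrast estimate is not
  drowned by independent Monte-Carlo noise.
* **Small-signal contrast**: C_k = Σ_Δn Σ_l h_kΔ(Δn, E_l)·A·ΔΦ̇_l / d_k.
  The sum runs over *all* pixel offsets because the lesion dims the beam
  homogeneously over the array: the Δn = 0 slice alone captures counts the
  perturbed photons add or remove in their own pixel (including
  fluorescence escaping *out*) but misses the crosstalk flowing *in* from
  neighbors.  The distinction is numerically large precisely in the
  20–40 keV bins, which under this transport model are fed mostly by Cd/Te
  K-fluorescence photons from adjacent pixels; with the Δn = 0 slice only,
  the predicted contrast there disagrees with the direct measurement by a
  factor of ~3, with the offset sum the two agree within combined
  Monte-Carlo errors at 10⁶ and 10⁸ mm⁻² s⁻¹ (asserted in the acceptance
  tests).  The 1 keV perturbation spectrum is folded onto the probe grid
  through the transpose of linear interpolation so estimator variances are
  propagated at the probe points where they are actually independent.
* **CNR**: σ(C_k) = sqrt(Var(d_k))/mean(d_k) with the variance taken over
  per-section baseline bin rates, sections sized ∝ 1/rate so every section
  integrates the same dose; then CNR_k = C_k/σ(C_k).  With equal dose the
  CNR of an ideal linear detector is rate-invariant (Poisson oracle,
  asserted in the tests).
* **Macro bins**: contrast is rebinned by recomputing from summed
  numerators and denominators, never by averaging contrasts, so
  cancellation and sign inversion between micro bins remain visible.

## 7. Problem sizes and numerics

* Array: 5×5 pixels, 500 µm pitch; energy bins 1 keV wide, centers
  20–250 keV; time grid 1 ns.
* Typical runs: 10⁶ mm⁻² s⁻¹ uses 10⁷–4×10⁷ ns exposures;
  10⁸ mm⁻² s⁻¹ uses 10⁶–2×10⁶ ns (≈ 2×10⁶ photons on the array either
  way).  A 14-energy pPSF sweep at 10⁸ costs ~15 s on one core.
* All derived seeds stay below 2³¹; every public entry point takes an
  explicit seed and is reproducible bit-for-bit (asserted by the pipeline
  idempotence test).
* Root finds (HVL, thickness matching, threshold crossings) use Brent's
  method from `scipy`; interpolation of attenuation data is log-log.

## 8. Known limitations

* No charge sharing, charge summing logic, or optical crosstalk; the
  border-overlap fraction only bounds the affected event population.
* Coherent scatter is not transported; Compton uses free-electron
  Klein–Nishina without binding/Doppler corrections.
* The tube model is analytic (Kramers + K lines), not a measured or
  simulated anode spectrum; beam quality is matched at the HVL level, and
  the spectrum's fluence-weighted mean energy (76.6 keV) should be read as
  a property of this model.
* Pulse pile-up is purely additive; no detector polarization, baseline
  drift, or ASIC-level effects.
* Quantitative deposited-spectrum fidelity (e.g. exact photopeak-to-escape
  ratios) is not claimed; the framework's validity rests on the behavioral
  properties asserted in the test suite (dead-time oracles, linear-detector
  limits, small-signal vs. direct agreement, Poisson CNR oracle).
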