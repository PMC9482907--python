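# Methods

## The indexing model

`napsri` normalizes reversed-phase LC–MS retention information by converting
retention times (RT, minutes) into retention indices (RI) against a
co-injected homologous series of N-alkylpyridinium-3-sulfonates (NAPS).
The n-carbon homolog defines RI = 100·n, so the C1–C20 series spans
RI 100–2000. For an analyte with retention time RT bracketed by anchors
(RI₀, RT₀) and (RI₁, RT₁), the linear method computes

    RI = RI₀ + (RI₁ − RI₀) · (RT − RT₀) / (RT₁ − RT₀)

applied piecewise over consecutive anchor pairs. Because this map is
invariant under affine transformations of the RT axis applied jointly to
analyte and anchors, RIs transfer across instruments whose RT warps are
locally affine — the property that makes retention information portable
where raw RTs are not.

Two spline alternatives are provided: a natural cubic spline and an Akima
spline, both interpolating the anchors exactly. The natural boundary
condition (zero second derivative at the ends) was chosen because it
reproduces collinear anchors exactly; spline evaluation is delegated to
`scipy.interpolate` (`CubicSpline(bc_type="natural")`,
`Akima1DInterpolator`, the 1970 Akima slope formula with the conventional
endpoint extension and 50/50 tie weighting). Cubic splines overshoot where
anchor spacing changes abruptly — in practice below the C3–C4 anchors,
where the weakly retained homologs pile up near the void volume — which the
`compare_methods` diagnostic quantifies. Linear interpolation and Akima
splines agree much more closely there; whichever method is used, libraries
and queries must use the same one.

### Anchor handling

* **Bracketing policies.** Anchors may come from the standards injected
  before a sample block, after it, or the per-homolog average of the two
  RTs (`policy="average"`), which absorbs slow drift over a block. The
  average is taken over anchor RTs, not over two independently computed
  RIs; the two differ only in nonlinear segments.
* **Co-elution collapse.** Consecutive anchors closer than 0.01 min are
  merged keeping the highest-carbon member (the C1–C3 void pileup becomes a
  single RI-300 anchor). This guarantees the strict RT monotonicity every
  interpolant requires.
* **Extrapolation.** Outside the anchor RT range the terminal anchor chord
  is extended linearly for all three methods (continuous at the end
  anchors, method-independent) and the result is flagged `extrapolated`;
  batch conversion never aborts.
* **Usability floor.** RIs at or below `usable_ri_min` (default 300, the C3
  anchor) are flagged `below_usable`. The library builder excludes such
  entries from the usable set; the converter only flags them.

### Inversion

`ri_to_rt` inverts the linear map algebraically. For splines it locates the
root of the interpolant inside the bracketing segment; a segment in which
the spline is non-monotone at the requested index (multiple preimages,
possible in the overshoot region) is reported as an error naming the
segment rather than silently picking a root.

## Library building

RIs are computed per replicate run against that run's own anchors and only
then averaged, so run-to-run drift is absorbed by the calibration rather
than inflating dispersion. Dispersion is the sample standard deviation
(n−1; replicates sample run-to-run variability); RSD = 100·sd/mean.
Single-replicate entries report sd 0 (no dispersion estimate exists).
Merging two libraries pools collision entries by replicate-weighted means
and pooled variance (including the between-batch term). Compounds detected
in both polarities keep separate per-adduct entries; the mode summary
(`both` / `pos_only` / `neg_only`) is computed over compound ids.

## Exact-mass chemistry

Monoisotopic masses use NIST most-abundant-isotope atomic masses (≥ 9
decimals) with electron-mass correction for charged species — required to
match the series' diagnostic fragment [C5H6NO3S]+ at m/z 160.0063 to the
fourth decimal. The neutral reference mass M is the zwitterion, so
"[M+H]+" means protonation of the intact zwitterion. The supported adduct
catalogue covers [M+H]+, [M+Na]+, [M−H]−, [M+HCOO]− for monomer, dimer and
trimer. For the negative-mode fragment the package reports the theoretical
[SO3]−• radical-anion mass (79.9574); instrument-calibrated readings a
fraction of a mDa higher are sometimes quoted, and the theoretical value is
preferred over hard-coding any observed figure.

## Annotation

Candidates match on |Δm/z| ≤ `mz_tol` (default 0.005 Da absolute; a ppm
mode is available, mutually exclusive with the absolute one) and, in
combined mode, |ΔRI| ≤ `ri_tol` (default 10). Comparisons are inclusive at
the boundary for cross-platform reproducibility. Candidate m/z comes from
an explicit library `mz` column or is computed from a neutral `formula`
plus the adduct. Relative errors between library and observed values use
the observed value as denominator, reported to one decimal below 10% and
to the nearest integer above. No scoring beyond |Δ| sorting is attempted;
MS/MS-based consensus scoring is out of scope.

## Ion suppression

Spiked and unspiked runs are paired one-to-one greedily by (|Δm/z|, |ΔRT|)
within tolerances (defaults 0.005 Da, 0.1 min — exposed as flags since
post-alignment tolerances are instrument-specific). Each pair within
±0.20 min of a NAPS apex (inclusive; a pair inside two overlapping windows
goes to the nearer apex) is expressed as 100·I_spiked/I_unspiked. Only
apexes with RI > 300 are evaluated: the void region suppresses heavily
regardless of the spike. Pairs with zero unspiked intensity are flagged
undefined and excluded from summaries. The module operates on picked
feature tables and uses the intensity field directly; raw-data processing
is out of scope.

## The simulator

Retention follows the linear-solvent-strength model
log₁₀ k(φ) = log kw − S·φ, with the apex RT solving the gradient-elution
integral ∫₀^(tR−t0) dt / (t0·k(φ_col(t))) = 1 numerically on a dense time
grid (2 ms steps, vectorized over compounds; reduces to tR = t0(1+k) for a
flat gradient). The programmed gradient is delayed at the column inlet by
dwell_volume/flow_rate; t0 = dead_volume/flow_rate.

Default conditions (chosen once as the study conditions, stated here as the
package's own design):

* **Reference method**: 2 min hold at φ = 0.05, linear ramp to 0.999 over
  15 min, 3 min hold; flow 0.30 mL/min, column dead volume 0.25 mL, dwell
  volume 0.80 mL (a low-pressure-gradient mixer regime — the hardware class
  for which cross-system RT differences are largest). Flow-rate panel:
  0.20, 0.25, 0.35, 0.40 mL/min with the time program fixed.
* **NAPS series**: log kw = −2.40 + 0.30·n, S = 4 (constant methylene
  selectivity). The C1–C3 pileup at the void emerges from the retention
  model, not from special-casing.
* **Analyte panel**: 50 compounds, log kw uniform on (0.3, 3.5) — retained
  standards spanning the gradient, the population an RI library is actually
  built from; compounds eluting at the void are excluded by the RI-300 rule
  anyway. Solvent-strength slopes S ~ N(4, 0.3): indexing presumes locally
  similar gradient warping between analytes and references, and strongly
  deviating slopes would violate that assumption by construction.
* **Noise**: RT jitter Gaussian, sd 0.02 min, added after the deterministic
  retention calculation; intensity noise log-normal, sd 0.1 log₁₀ units.
  Triplicate runs, each indexed against its own jittered anchors.
* **Suppression kernel**: Gaussian around each NAPS apex, width 0.10 min,
  amplitude 0.5 at 1:20 spike dilution scaling inversely with dilution
  (0.25 at 1:40, 0.125 at 1:80), applied to 300 matrix features.

All randomness flows from one `numpy` `default_rng(seed)`; identical
(config, seed) inputs give identical outputs.

### What the simulator does and does not emulate

It reproduces the mechanisms the indexing method relies on: smooth,
system-dependent RT warps (flow, dwell, dead volume), homolog anchor
structure with the void pileup, replicate jitter, and apex-centered
suppression. It does **not** simulate peak shapes, matrix-specific
suppression magnitudes, pH/temperature/column-chemistry effects,
detectability limits, or MS/MS — so passing tests demonstrate the
correctness and internal consistency of the indexing arithmetic and
workflows under realistic warps, not instrument-level performance on any
particular matrix.

## Numerical choices and problem sizes

* Gradient integral: trapezoidal accumulation on a 2 ms grid to 90 min,
  linear interpolation at the unit crossing; exponent clipped at ±300 to
  avoid overflow for extreme k.
* Spline inversion tolerance: exact polynomial root finding via the
  piecewise representation; round-trip verified to 1e-6 min (linear) and
  1e-4 min (splines) in tests.
* Window membership and tolerance comparisons carry a 1e-9 epsilon against
  float-representation artifacts at the boundary.
* Test and acceptance problem sizes — 50-analyte panel, 5 flow rates,
  triplicates, 300 matrix features — were chosen as the smallest sizes at
  which the medians and fractions involved are stable across seeds.

## Known limitations

* RI portability is only as good as the affine/smooth-warp assumption;
  columns of different chemistry or strongly differing solvent-strength
  behavior are outside the model.
* The early-eluting region (RI ≲ 750, between the void and the arrival of
  the gradient front) compresses many indices into a short RT span, so
  index precision there is intrinsically poor — the reason the usable floor
  and the method-consistency warning exist.
* The greedy suppression pairing is deterministic but not globally optimal;
  for dense feature tables an assignment solver would pair a handful of
  features differently.
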