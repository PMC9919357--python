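# Methods

## The measurement being modelled

Hyperpolarized ¹²⁹Xe dissolved in a membrane-protein preparation
exchanges in and out of a cryptophane-A (CrA) cage tethered to the
receptor. Saturating RF applied at the resonance of cage-bound xenon
depletes, via exchange, the large signal of freely dissolved xenon
(chemical exchange saturation transfer, CEST). Stepping the saturation
frequency scan by scan and plotting the remaining free-xenon signal
against it yields a z-spectrum whose dips report every distinguishable
chemical environment of the caged xenon — and hence, indirectly,
conformational states of the receptor–cage conjugate.

## Forward model

For exchange that is slow on the NMR timescale, the depletion caused by
a single exchanging pool is exponential in an effective saturation rate
with Lorentzian frequency dependence, so `N` pools multiply:

    S(x) = A · Π_i exp( −B_i · a_i² / (a_i² + (b_i − x)²) )

with `A` the baseline, `b_i` the pool's position, `B_i` a dimensionless
saturation amplitude and `a_i` the angular half-width (`(b_i − x)` is
converted from ppm to rad/s via the observe frequency). When `B_i < 0.2`
for all but one dominant pool, first-order expansion of the weak
exponentials gives the mixed linearized form (dominant pool exact, weak
pools plain Lorentzians reflected at the baseline); the Taylor remainder
bounds the error by `2·max B_i²` of the expanded pools.

The lineshape parameters encode the exchange mechanism. With
saturation time `t`, nutation frequency `ω₁`, entry/exit rates
`k_on`/`k_off` and bound-pool relaxation `R₂`:

    B = t · k_on · ω₁² / (ω₁² + k_off² + k_off·R₂)
    a = sqrt( ω₁² + k_off² + R₂² + (R₂/k_off)(ω₁² + 2·k_off²) )

The width expression is stated in the primary source in a typographically
ambiguous form; the grouping above is adopted because it (i) expands
exactly to the printed token sequence, (ii) reduces to the separately
printed high-power simplification `a ≈ sqrt(ω₁² + R₂² + R₂ω₁²/k_off)`
when `ω₁ ≫ k_off`, and (iii) collapses to `a = ω₁` when
`k_off = R₂ = 0`. Note it is monotone in `ω₁` and `R₂` but *not* in
`k_off` (the `R₂ω₁²/k_off` term falls as exchange accelerates), and it
diverges as `k_off → 0` with `R₂ > 0` (saturation never leaves the
cage), which the code rejects. For linewidth → exchange-rate
conversion two conventions are offered: `numeric` (a 320 Hz line means
k_off = 320 s⁻¹, the reading used in the source's own comparisons) and
`lorentzian` (k_off = π·FWHM).

Units: widths are held internally in rad/s; every file and report uses
`a/π` in Hz, which is the FWHM of the underlying Lorentzian. Positions
are ppm referenced to xenon gas (0 ppm; free dissolved xenon at
196 ppm). The observe frequency defaults to 83.0 MHz (¹²⁹Xe at 7 T)
and is always overridable.

## Acquisition grid and scan integration

Defaults mirror the experiment: cw saturation at `ω₁ = 2π·99` rad/s for
20 s; irradiation offsets from 5 kHz downfield to 13 kHz upfield of the
free-xenon line in 200 Hz steps (91 points; ≈ 256.2 down to 39.4 ppm at
83 MHz). Each scan is reduced to one intensity by trapezoidal
integration over a 7 ppm window centred on the signal maximum
(re-centred per scan by default, with a fixed-centre option; a 3-point
median pre-smoothing of the peak search is available and off by
default). Integration uses the native grid with interpolated window
edges — no resampling. Baseline normalization divides by an upper
quantile (0.9) of the intensities; the fitted `A` absorbs any residual
scale.

## Fitting

Weighted nonlinear least squares (scipy trust-region-reflective) with
an analytic Jacobian of the product model; per-point sigmas weight the
residuals when present. Bounds: positions inside the sampled band
± 2 ppm, `0 ≤ B ≤ 10`, width `a/π ∈ [10, 5000]` Hz — spanning every
published value with wide margins. Standard errors come from the
scaled covariance `(JᵀJ)⁻¹·s²` at the optimum; singular covariances
yield NaN with a warning; non-convergence is flagged, never raised.

Initialization works on the negative log-spectrum `E = −ln(S/A)`, where
the product model becomes a *sum* of Lorentzians: dips are located by
greedy peeling (deepest remaining maximum; width from the half-height
span; subtract; exclude the peeled core from later searches), then
refined by four backfitting passes in which each component is
re-estimated against the residual of the others, with amplitudes
re-solved by non-negative least squares to handle overlap. Weak
components are floored at `B = 0.02` so the subsequent nonlinear fit
retains gradient on them. On the noiseless preset spectra this lands
every starting position within ~4 ppm of its generating value and the
bounded fit then recovers all parameters to machine precision.

Model selection fits each candidate resonance count `n` with 12 seeded
multi-starts, then lets adjacent counts warm-start each other (upward:
add a component at the deepest unexplained dip; downward: drop the
component with the smallest integrated saturation `B·a`; two
alternating rounds) so the per-n RSS sits close to its global envelope.
Counts are scored by BIC under a Gaussian noise model: with known
per-point sigma, `rss/σ² + k·ln N`; otherwise `N·ln(rss/N) + k·ln N`
with the RSS floored at `(10⁻⁸A)²·N` so noiseless data cannot reward
complexity without bound. All randomness flows through one generator
seeded by the caller. The "most intense" resonance of a fit is ranked
by `B·a` rather than `B`, because a forced-n fit can park spare
components as sub-gridwidth spikes with large `B` that absorb single
noisy points.

### Detectability of the weakest resonances

On a single 91-point spectrum with 1% noise, the weakest published
components (B ≈ 0.07–0.09, widths ≈ 800–1600 Hz, heavily overlapped
with the dominant dip) carry an RSS reduction of only ~5–15 noise
variances — straddling the BIC penalty `3·ln 91 ≈ 13.5`. Their own
published uncertainties say the same thing (e.g. B = 0.069 ± 0.047).
Consequently BIC selection recovers the full 5/6-component count only
in a minority of noise realizations; the modal selected counts are 4
(apo) and 5 (ligand-bound). The test suite states the
full-count-majority expectation and reports the shortfall rather than
relaxing it; all fixed-count parameter-recovery results are unaffected.

## Contact analysis

A residue (or lipid molecule) is in contact in a frame when the xenon
lies within a cutoff (default 8.5 Å) of any of its *heavy* atoms;
solvent is ignored by definition and the cage is excluded because the
xenon permanently resides inside it. Each retained frame (after a
configurable equilibration discard, default 100 ns) receives exactly
one environment category — "just lipid", "just protein" (receptor
and/or ligand), "lipid and protein", or "no contacts" — so category
probabilities sum to 1 exactly. Contact instances are counted per
frame per residue. Lipid contacts are resolved per molecule for
categorization and aggregated to the class for reporting. Minimum-image
distances are used when box vectors are present; otherwise plain
Euclidean distances with a warning (toy fixtures are non-periodic).
Named contact sites (five receptor sites; two ligand sites in the
complex) ship as a packaged YAML file; a site's score is the mean
contact probability of its three most-contacted residues, with ties
broken by listing order. Surface-projection normalization divides
counts by the per-system maximum and is therefore not comparable
across systems.

## Order parameters

Overall receptor motion is removed by Kabsch superposition of each
frame onto a reference structure over the receptor Cα atoms only
(never ligand or cage). The per-residue order parameter is the
generalized S² from the time-averaged second-moment tensor of the
aligned Cα–H unit vectors,

    S² = (3/2) Σ_{αβ} ⟨u_α u_β⟩² − 1/2 ,

computed from full-trajectory moments (no window averaging). The
P₂-autocorrelation route is deliberately not used: it requires overall
rotation to average out, which fails for a membrane-embedded receptor
on the NMR timescale. Values are clipped to [0, 1] (warning beyond
1e-6). When hydrogens are missing, an optional reconstruction places
an effective Cα–H direction opposite the summed unit vectors toward
N, C (and Cβ when present); off by default. Region averages are plain
arithmetic means over receptor / ligand residues. RMSD series are
post-superposition by default with a plain (no-fit) option.

The published whole-receptor order-parameter averages derive from
30 × 1 µs of membrane-protein MD and are not reproducible at desk
scale; the implementation is validated on closed-form synthetic motion
instead (below).

## Synthetic data: what it emulates and what it does not

* **Z-spectra** are forward-model evaluations of the published
  parameter sets (5-component apo, 6-component ligand-bound,
  1-component construct-in-bicelles control; the free-CrA control
  carries only its two direct-detection lines) on the experimental
  grid, plus iid Gaussian noise of σ = 0.01·A by default — the
  published spectra show ≈1% point scatter. Real spectra add
  correlated baseline drift, B₀/B₁ inhomogeneity and
  polarization-level fluctuations between bubbling cycles, none of
  which are modelled; parameter-recovery results therefore bound the
  estimator's behaviour under ideal noise only.
* **Scan sets** place a single Lorentzian free-xenon peak whose *area*
  encodes the z-value, exercising the integration stage; real scans
  have phase/baseline residuals that are declared out of scope.
* **Hop trajectories** move the xenon between fixed sites (lipid
  pocket, protein site, optional lipid/protein interface, bulk) as an
  irreducible Markov chain with a known stationary distribution; all
  other atoms are static. Frame-category statistics are therefore
  exactly computable, but nothing about real diffusive kinetics is
  claimed. A sub-jitter (0.3 Å) avoids exactly degenerate coordinates
  without changing any contact set.
* **Cone trajectories** sample Cα–H unit vectors uniformly over
  spherical caps of per-residue semi-angles about fixed axes
  (closed-form S² = [cosθ(1+cosθ)/2]²), with an optional random global
  rotation per frame to exercise alignment. Cα positions are fixed on
  a non-collinear ring; a distant dummy xenon satisfies the trajectory
  container's single-xenon invariant.

Every generator is a pure function of (parameters, seed) and emits its
ground truth alongside the data.

## Numerical choices and degenerate inputs

* Coincident resonance positions are rejected at model construction
  (not merged): a product of identical Lorentzians is unidentifiable.
* The empty resonance list is the flat baseline (empty product).
* Grid/window edges: the integration window is clipped to the scan
  axis with a warning; a window centre may be fixed across a series.
* `cest_width` with `k_off = R₂ = 0` returns `ω₁` exactly (the
  division by `k_off` is taken in the `R₂ = 0` limit first).
* The hemisphere limit of the cone model (θ = 90°) gives S² = 0 — the
  hemisphere has isotropic second moments.
* Problem sizes in the test suite — 10⁴-frame chains, 10⁵-sample
  isotropic checks, 2·10⁴-frame cone runs, 10-seed noise ensembles —
  were chosen so each statistical tolerance sits at ≥3 standard errors
  of its estimator while the full suite runs in minutes on one CPU.

## Known limitations

* Single-spectrum fits only; no global multi-spectrum fitting, no
  Bloch–McConnell integration, no B₀/B₁ maps (declared non-goals).
* The exchange-parameter mapping is per-resonance closed form; pools
  do not interact.
* Contact analysis assumes orthorhombic boxes for minimum-image
  distances.
* Order parameters use full-trajectory second moments; slowly
  interconverting substates that a windowed estimator would separate
  are averaged together.
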