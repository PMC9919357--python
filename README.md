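# xecest

Analysis tools for hyperCEST ¹²⁹Xe NMR of cryptophane-tagged membrane
receptors, paired with xenon-contact and order-parameter analysis of MD
trajectories.

**Who it is for.** Experiments that tether a xenon-binding cryptophane-A
cage to a G-protein-coupled receptor detect receptor conformational
states through chemical exchange saturation transfer (CEST): saturating
cage-bound hyperpolarized xenon depletes the free-xenon signal, and
stepping the saturation frequency yields a z-spectrum whose dips mark
distinguishable cage environments. This package turns per-scan spectra
into z-spectra, fits multi-resonance models to them, and — on the
computational side — quantifies where the cage-held xenon sits on the
receptor surface and how much the probe perturbs receptor dynamics.

## Model

A z-spectrum of `N` slowly exchanging pools is an exponential-Lorentzian
product,

    S(x) = A · Π_i exp( −B_i a_i² / (a_i² + (b_i − x)²) ) ,

with baseline `A`, position `b_i` (ppm, xenon gas = 0), amplitude `B_i`
and angular half-width `a_i` (reported as `a/π` in Hz, the Lorentzian
FWHM). The lineshape parameters map to the exchange mechanism through

    B = t·k_on·ω₁² / (ω₁² + k_off² + k_off·R₂) ,
    a = √( ω₁² + k_off² + R₂² + (R₂/k_off)(ω₁² + 2k_off²) ) ,

where `t` is the saturation time, `ω₁` the RF nutation frequency,
`k_on`/`k_off` the cage entry/exit rates and `R₂` the bound-pool
transverse relaxation rate.

On the MD side, a residue (or lipid molecule) counts as a xenon contact
in a frame when any of its heavy atoms lies within 8.5 Å of the xenon;
frames are categorized as *just lipid* / *just protein* / *lipid and
protein* / *no contacts*, and named contact sites are scored by the mean
contact probability of their three most-contacted residues. Internal
dynamics are summarized per residue by the alignment-based order
parameter `S² = (3/2)Σ⟨u_α u_β⟩² − 1/2` of the Cα–H bond vector.

No raw spectra or trajectories are distributed; `xecest.synthetic_data`
generates every input with known ground truth (published fit-parameter
sets on the experimental acquisition grid, Markov site-hopping
trajectories, wobble-in-cone bond vectors), so the full pipeline runs
self-contained. See `docs/methods.md` for assumptions, defaults and
limitations.

## Worked example

Fit a six-resonance model to a noiseless synthetic z-spectrum of the
ligand-bound receptor–cage conjugate:

```python
from xecest.synthetic_data import table1_presets, gen_zspectrum
from xecest.zspec_fit import initial_guess, fit_zspectrum

z = gen_zspectrum(table1_presets()["npy"])          # 91-point grid
fit = fit_zspectrum(z, initial_guess(z, 6))
print(f"rss={fit.rss:.3g} converged={fit.converged}")
for r in fit.params.resonances:
    print(f"{r.b_ppm:6.1f}  {r.B:5.3f}  {r.width_hz:6.0f}")
```

prints

```
rss=4.14e-31 converged=True
 104.9  0.089     322
  92.4  0.136     704
  77.5  2.120     618
  70.0  0.181     466
  63.0  0.182     785
  49.5  0.109     417
```

i.e. the generating parameter set (position ppm, amplitude, width a/π
Hz) is recovered to machine precision, with the dominant 77.5 ppm dip
(cage in the lipid phase) and the 49.5 ppm resonance unique to the
ligand-bound state. For the contact arm:

```python
from xecest.synthetic_data import gen_hop_trajectory
from xecest.contact_analysis import build_contact_table

traj, truth = gen_hop_trajectory(n_frames=10_000, seed=1)
table = build_contact_table(traj, cutoff=8.5, discard_ns=0.0)
for cat, p in table.category_probabilities().items():
    print(f"{cat:18s} observed {p:.3f}   analytic {truth['category_probs'][cat]:.3f}")
```

```
just lipid         observed 0.542   analytic 0.542
just protein       observed 0.283   analytic 0.292
lipid and protein  observed 0.000   analytic 0.000
no contacts        observed 0.174   analytic 0.167
```

— frame-category frequencies agree with the hopping chain's analytic
stationary distribution within sampling error. Cone-wobble order
parameters behave the same way: residues wobbling in 10°/30°/60° cones
return S² of 0.955/0.654/0.138 against closed-form values
0.955/0.653/0.141.

The same stages are scriptable from the shell:

```
xecest simulate zspec --preset npy --out z.csv
xecest fit --zspec z.csv --n 6 --out fit.json
xecest contacts --top traj_dir/ --discard-ns 0 --system apo --out contacts/
xecest orderparams --top cone_dir/ --out op/
```

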