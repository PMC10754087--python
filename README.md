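# molspan

Integrative analysis of **molecule-spanning nanosecond dynamics** in
multi-domain proteins, combining three experimental windows on the same
100–200 ns physics:

* **single-molecule fluorescence** — burst selection, subpopulation-specific
  nanosecond correlation spectroscopy (nsFCS) and time-resolved anisotropy
  of freely diffusing FRET-labeled molecules,
* **molecular-dynamics mode analysis** — inertia-axis rotational
  autocorrelation, mass-weighted cartesian PCA, accessible dye volumes and
  anisotropic-network modes of (real or synthetic) trajectories,
* **quasi-elastic neutron scattering** — effective diffusion D_eff(q) from
  neutron spin echo, PCA-mode amplitude functions A_k(q), and
  backscattering fits for apparent diffusion and confinement radius.

The package is aimed at biophysicists who want to reproduce or adapt this
kind of multi-technique inference — e.g. for the Hsp90 chaperone dimer,
where a ~150 ns bunching time in nsFCS is assigned to concerted internal
motions by excluding rotation (anisotropy, rigid-body diffusion) and
locating the motion in space (PCA modes, A_k(q), NSE).

Because photon records, microsecond trajectories and neutron counts are
not shippable, every stage comes with a **synthetic generator** whose
ground truths default to the published fitted values (149/187 ns bunching
times, 0.35/3/52 ns rotational hierarchy, 81 ns axis decay,
D_app = 3.27 Å²/ns, a = 1.95 Å); correctness is demonstrated by parameter
recovery.

## Core models

* nsFCS (linear window, fitted globally over D×D, A×A, A×D with shared
  bunching time τ_b):

      G(τ) = a (1 − c_ab e^{−|τ−τ₀|/τ_ab}) (1 + c_b e^{−|τ−τ₀|/τ_b})

* full FCS with triplet and 3D diffusion:

      G(τ) = n (1 − c_ab e^{−τ/τ_ab})(1 + c_b e^{−τ/τ_b})(1 + c_T e^{−τ/τ_T})
             / [(1 + τ/τ_D) √(1 + τ/(κ²τ_D))]

* corrected FRET efficiency, stoichiometry and anisotropy per burst
  (α, δ, γ, β, G, l₁, l₂ corrections; route-correction matrix supported),
* cone-in-cone anisotropy decay
  r(t) = r₀((1−A_dye)e^{−t/ρ_dye}+A_dye)((1−A_local)e^{−t/ρ_local}+A_local)e^{−t/ρ_global},
* inertia-axis ACF fitted with A e^{−τ/τ₁} + B cos(2πωτ + θ),
* coherent first-cumulant rigid-body D_eff(q), oligomer rescaling
  (D_t/n^⅓, D_r/n), mode amplitudes
  A_k(q) = ⟨|Σ_α b_α e^{iq·r_α}(q̂·v̂_kα)|²⟩,
* backscattering: Voigt-profile two-Lorentzian global fit with the
  diffusion-in-a-sphere EISF A₀(q) = [3 j₁(qa)/(qa)]².

See `docs/methods.md` for assumptions, estimator choices and limitations.

## Worked example

Recover the closed-state bunching time from one synthetic measurement:

```python
from molspan.synthetic import default_closed_a_config
from molspan.pipeline import recover_tau_b

report = recover_tau_b(default_closed_a_config(seed=1, duration=30.0),
                       e_range=(0.4, 0.8))
print(report["tau_b_ns"], report["n_bursts"], report["redchi"])
```

prints (seed 1):

```
155.2  5402  1.01
```

i.e. a 30 s photon stream yields ~5400 single-molecule bursts; selecting
transfer efficiencies 0.4–0.8, correlating the three channel pairs on a
1 ns grid and fitting the nsFCS model globally recovers a bunching time
of 155 ns for this realization (ground truth 149 ns; six replicas average
to within a few ns — the per-stream scatter is ~6 ns). `redchi ≈ 1`
says the Poisson error model matches the correlation noise.

The same stages are scriptable from the shell:

```bash
molspan simulate closed-a --seed 1 --duration 10 --out stream.h5
molspan bursts stream.h5 --out bursts.tsv
molspan fitns stream.h5 --e-min 0.4 --e-max 0.8
molspan simulate qens --seed 1 --out spectra.txt
molspan nbs-fit spectra.txt
```

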