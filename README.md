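# myowalk

Monte Carlo simulation of diffusion tensor cardiovascular magnetic resonance
(DT-CMR): random-walk diffusion of water in a periodic, helix-rotated
cardiomyocyte substrate with permeable membranes, combined with an
anisotropic capillary perfusion model, under three diffusion-encoding
sequences — monopolar stimulated echo (STEAM), monopolar pulsed-gradient
spin echo (PGSE), and second-order motion-compensated spin echo (MCSE).

The package is for researchers studying how myocardial microstructure —
extracellular volume fraction (ECV), sarcolemma and intercalated-disk
permeability, and microvascular perfusion — maps onto the measurable
diffusion tensor (MD, FA, eigenvalues, eigenvectors), and how acquisition
choices (sequence, reference b-value) modulate that mapping.

## Model

**Diffusion.** Walkers take steps `X(t+δt) = X(t) + sqrt(2 D δt) R`, each
component of `R` an independent ±1, with `D ∈ {D_ICS = 1, D_ECS = 2.5}
μm²/ms`. The substrate is a block of extruded polygonal cell cross-sections
(generated as jittered-Voronoi packings, or loaded from a plain-text polygon
file) tiled over all space, each Y-row of blocks rigidly rotated about Y by
10°/mm (helix angle) and alternate rows shifted half a block along Z.
Membrane encounters use the hybrid transit model

    p_b = 2 κ δx / (D_ICS + 2 κ δx),      p_t(ECS→ICS) = p_b · p_d,

with `δx` the start-of-step distance to the membrane along its normal and
`p_d = D_ICS/D_ECS` the diffusivity-step factor; failed transits reflect
specularly. End caps (and side walls within 2 μm of a cap) carry a separate
intercalated-disk permeability `κ_ICD`. Each spin's phase is
`φ = γ ∫ X(t)·G(t) dt` and the signal is `S/S0 = |Σ exp(−iφ)| / N` over
walkers inside the voxel at echo time.

**Perfusion.** Perfusing spins move at one constant speed each (truncated
Gaussian, mean 0.5 mm/s, bounds [−0.1, 1]) along chains of straight
capillary segments whose zenith angles follow a hemispherical Dimroth–Watson
axial density `∝ sin θ exp(2K cos²θ)` (default K = 3.25) about the local
cell long axis, with Weibull segment lengths (mean 60 μm, SD 40 μm). For a
piecewise-straight path the phase reduces to an exact sum over segments of
the integrated normalized gradient moment — no time stepping.

**Tensor.** Total signal `S = f·S_perf + (1−f)·S_diff` (default perfusion
fraction f = 10%) is fitted log-linearly on six dual-gradient directions at
b = 0.6 ms/μm², against either b = 0 or a reference b-value
b_ref = 0.15 ms/μm² (per-direction signal ratios), then eigen-decomposed.

## Worked example

`examples/03_perfusion_signals.py` computes the normalized perfusion signal
along the mean capillary axis at b = 0.6 ms/μm² while widening the
intercapillary speed distribution:

```
normalized perfusion signal S_perf/S0 along E1 (b = 0.6 ms/um^2):
 sigma_v (mm/s)    STEAM     PGSE     MCSE
          0.001    0.837    0.961    0.999
          0.050    0.456    0.938    0.999
          0.150    0.010    0.775    0.998
```

With near-constant speeds (σ_v = 0.001) the spins stay largely coherent;
widening the distribution dephases the long-encoding STEAM sequence almost
completely, affects PGSE moderately, and leaves the motion-compensated MCSE
untouched (its nulled first and second gradient moments cancel
constant-velocity phase exactly).

`examples/04_diffusion_tensor.py` runs the full chain on a synthetic
substrate (ECV 24.7%, κ_sarco = 0.03 μm/ms, PGSE, 10⁴ walkers):

```
diffusion-only tensor:  MD = 0.838 um^2/ms, FA = 0.392
with f=10% perfusion:   MD = 0.794 um^2/ms, FA = 0.365
```

For short-encoding sequences the perfusing spins lose *less* signal than the
diffusing ones, so raising the perfusion fraction lowers the apparent MD —
the counter-intuitive direction; for STEAM the effect reverses.

The other examples build substrates (`01`), inspect waveforms and gradient
moments (`02`), and everything is scriptable through the thin CLI:

```bash
myowalk substrate --n-cells 196 --ecv 0.2469 --seed 1 --out block.txt
myowalk diffuse --substrate block.txt --sequence STEAM --kappa 0.02 --out signals.csv
myowalk fit --signals signals.csv --bref 0.15
myowalk run --preset paper-all --seed 1 --out results/
```

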