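# Methods

This note documents the models implemented in `myowalk`, the defaults and
why they were chosen, the numerical choices that affect results, and what
the synthetic substrate does and does not capture.

## Units and constants

Internally: micrometres, milliseconds, milliTesla. The gyromagnetic ratio is
γ = 267.522 rad·ms⁻¹·mT⁻¹ and gradient amplitudes are stored in mT/μm, so
b-values come out in ms/μm² (1 ms/μm² = 1000 s/mm²). Velocities in mm/s are
numerically equal to μm/ms. Public constructors accept Gmax in mT/m.

## Substrate

Cardiomyocyte cross-sections are Voronoi cells of a jittered hexagonal
lattice (jitter 0.35 of the spacing), made periodic by ghost replication,
clipped to the block, and offset inward by 0.75 μm so the extracellular
space (ECS) forms a connected sheet network, as between real myocytes. The
default block uses a mean cell diameter of 18 μm (cardiomyocytes run
10–25 μm) and an extrusion length Lz = 127 μm matching the histology-block
depth the tissue model emulates; cells cut by the block border meet their
periodic copies across it, just as segmented contours cut by a region of
interest would.

The extracellular volume fraction is tuned by a uniform mitre-joined polygon
offset found by binary search (tolerance 10⁻³ on ECV). Because the cells
descend from a Voronoi partition, growth back toward the partition cannot
create overlaps; an explicit union-area check guards the limit and
infeasible targets raise.

Tiling: every Y-row of blocks is rigidly rotated about the global Y axis by
`ha_rate × (row base y)` — piecewise-constant per row, 10°/mm by default, to
emulate the transmural helix-angle variation — and alternate rows are
shifted half a block in Z to break up straight extracellular channels.
Rigid per-row rotation necessarily leaves geometric mismatch at row
boundaries; walkers crossing a row plane are re-located in the new frame,
and if the compartment type flips there the sarcolemma transit model is
applied with the plane normal (otherwise they pass freely). Boundary
convention: points exactly on a membrane belong to the ECS; crossing
searches use a half-open parametric interval with a 10⁻⁶ μm post-event
nudge so walkers never sit exactly on a face.

Geometry queries run in numba kernels over flat polygon/edge arrays with a
uniform acceleration grid (cell size ≈ half a cell diameter); shapely is
used for construction and as the test oracle, not in the inner loop.

## Random walk and membranes

Steps have fixed per-component magnitude sqrt(2 D δt) with independent fair
signs; δt = T/Nt. Membrane transit uses the hybrid model: barrier
probability p_b = 2κδx/(D_ICS + 2κδx), where δx is the distance from the
step start to the membrane projected on its normal (clamped at 10⁻⁶ μm),
and a diffusivity-step factor p_d applied on ECS→ICS transits only. The
p_d exponent is configurable; the default is the plain ratio
p_d = D_ICS/D_ECS because a uniform-density flux-balance argument (attempt
flux ∝ n·2Dδt with p_b carrying D_ICS on both sides) requires exactly that
for stationary compartment occupancy, and the equilibrium property test
confirms it empirically (ICS-fraction drift < 1 SD over 1500 steps, vs ≈10
SD for a square-root exponent). Failed transits reflect specularly about the
membrane plane; successful transits rescale the remaining step length by
sqrt(D_to/D_from). The deflected remainder is not resampled within a step;
a step is abandoned (position kept, remainder dropped, event counted) after
50 substeps, which is effectively never reached at default step sizes.

End caps of the extruded cells — the intercalated-disk (ICD) junctions —
and side-wall area within `icd_depth` (default 2 μm) of a cap carry κ_ICD
instead of κ_sarco, covering the whole junction regardless of cross-section
irregularity.

Reproducibility: each walker derives a counter-based random stream
(splitmix64 keyed by seed and walker id), so results are independent of
execution order and identical across runs for a fixed seed.

Phase uses the midpoint rule — mean of the step's endpoints against the
gradient at the step's temporal midpoint — on a normalized amplitude, so one
trajectory yields signals at every Gmax (hence every b-value) of a waveform
shape. The signal averages walkers located inside the voxel at echo time;
walkers are seeded over the voxel plus a buffer margin of 4·sqrt(2·D_ECS·T)
to balance in/out flux across the voxel faces.

## Sequences

Effective gradients fold all refocusing sign flips into G(t), making the
phase a single integral and refocusing equivalent to m0(T) = 0. STEAM and
PGSE are two matched trapezoidal lobes with opposite effective sign;
defaults are δ = 20, ε = 1, Δ = 30 ms for PGSE (T = 52 ms) and δ = 6,
ε = 1, Δ = 1000 ms for STEAM, whose mixing interval is of the order of one
cardiac cycle — representative clinical timings, all overridable in the
sequence spec. MCSE is four trapezoidal lobes of alternating sign around a
6 ms refocusing pause within T = 70 ms; the four flat-top durations are
solved numerically (trust-region least squares) so that m0, m1 and m2 all
vanish at T, to better than 10⁻¹⁰ of natural scale. b-values, gradient
moments and the normalized-moment antiderivative are evaluated exactly on
the piecewise-linear waveform (piecewise-polynomial integration; 3-point
Gauss where the integrand is quartic), and Gmax for a target b uses
b ∝ Gmax².

## Perfusion

Each spin gets one speed from a Gaussian (mean 0.5 mm/s, SD σ_v) truncated
to [−0.1, 1] mm/s; negative speeds traverse the sampled path backwards.
Segment zenith angles are rejection-sampled from the hemispherical Watson
axial density ∝ sin θ · exp(2K cos²θ) using the isotropic density as
proposal (acceptance ≈ 1/(4K) at large K); azimuths are uniform; lengths
are Weibull with shape/scale solved from mean 60 μm and SD 40 μm. A spin's
local frame is fixed by the helix angle at its seed Y position — paths are
at most ~1 mm long against a 10°/mm rotation, so following the instantaneous
Y position would change directions by well under a degree.

For a piecewise-straight path, integrating the phase by parts gives

    φ = −γ Gmax v T² Σ_k (e_g·e_xk) ∫_{s_{k−1}}^{s_k} m0(s) ds,

evaluated exactly on the piecewise-cubic antiderivative of m0 — the
perfusion signal therefore carries no quadrature error, only sampling error.
The per-spin normalized phase Φ = φ/(v·b·T) is available for distribution
plots. Spins are seeded on the voxel face at z = 0 and need no buffer; they
do not interact with the cell geometry (perfusion and diffusion are
simulated independently and mixed at the signal level,
S = f·S_perf + (1−f)·S_diff).

Segments per spin are drawn in one vectorized block sized to cover the
slowest-case path with a five-sigma margin; the rare spin that still runs
short is topped up individually.

## Tensor fitting

Log-linear least squares on the six-direction dual-gradient scheme.
With b_ref > 0 each direction contributes ln S(b) − ln S(b_ref) against
−(b − b_ref)·g gᵀ, absorbing any direction-independent low-b offset (this
per-direction ratio form is used rather than a joint 12-point regression
with intercept; the ratio form is what a "reference b-value" denotes).
With b_ref = 0 the b = 0 sample anchors ln S0. Eigenvalues are sorted
descending; E1's sign is fixed against the mean long axis, E2/E3 by first
non-zero component. The 95% cone of uncertainty of an eigenvector across
replicates uses the mean dyadic tensor (sign-invariant) and the 95th
percentile of angular deviations from its principal axis. Replicate
aggregation uses normal-theory 95% confidence intervals (t distribution).

## Scaled problem sizes

Full study conditions are 10⁵ walkers × 10⁴ steps with six replicates.
The test suite and the acceptance script use those sizes only where a
quantitative closed form is checked (free diffusion, perfusion signals);
substrate trend experiments run at 10⁴ walkers × 10³ steps on a 36-cell
block, which resolves the directional trends (MD vs ECV, FA vs κ, ICD and
perfusion-fraction effects) well beyond their Monte Carlo error while
keeping a full sweep in minutes on one CPU.

## What the synthetic substrate does and does not show

The generator produces convex-ish, roughly equal-sized polygonal
cross-sections with a connected ECS at a controllable volume fraction, and
supports the same morphing range (ECV 18.8–41.8%) as segmented histology.
It does not reproduce real histology's cell-size dispersion, elongated or
interdigitated cross-sections, or sheetlet laminae beyond what the packing
induces; consequently λ2/λ3 structure is weaker than in tissue, and
absolute tensor values differ from any particular histology region of
interest. Trend results (directions of change with ECV, κ, κ_ICD, f,
b_ref) are the meaningful outputs at this scale; one documented consequence
is that with the default timings the reference-b-value fit corrects the
STEAM perfusion bias in MD but overcorrects FA on this substrate.

## Known limitations

- Sequence timings are representative defaults, not a specific scanner
  protocol; perfusion signal values at a given b depend on them (roughly
  through Gmax·δ·Δ), so quantitative comparisons require matching timings.
- Constant intracapillary speed per spin: no pulsatility, no intracapillary
  velocity profile, no capillary–tissue exchange, no explicit network
  topology. MCSE's perfusion insensitivity consequently fails only through
  direction changes between segments (visible at mean speeds ≳1 mm/s).
- No relaxation weighting, imaging gradients, or noise model.
- Rigid per-row helix rotation leaves geometric mismatch at row boundaries;
  its effect is confined to a layer one step wide around the row planes.
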