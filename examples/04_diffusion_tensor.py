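"""Random-walk diffusion on the substrate and the fitted tensor.

Seeds walkers in the voxel + buffer, propagates them through the permeable
cardiomyocyte geometry under a PGSE waveform, reads out signals along six
encoding directions at two b-values, fits the tensor, and then mixes in a
10% perfusion fraction to show its effect on the fitted mean diffusivity.
"""

import numpy as np

from myowalk import (
    EncodingScheme,
    PerfusionConfig,
    TissueBlock,
    WalkConfig,
    build_substrate,
    default_buffer,
    default_spec,
    generate_cross_sections,
    make_waveform,
    morph_ecv,
    run_perfusion,
    run_walk,
    signals_from_walk,
    solve_gmax,
)
from myowalk.tensorfit import fit_from_frame

cs = morph_ecv(generate_cross_sections(36, 18.0, seed=1), 0.247)
w = make_waveform(default_spec("PGSE", b=0.6))
s = build_substrate(TissueBlock(cs), voxel=(2800, 2800, 8000), ha_rate=10.0,
                    buffer=default_buffer(2.5, w.T))

scheme = EncodingScheme(b=0.6, bref=0.0)
cfg = WalkConfig(n_walkers=10_000, n_steps=1_000, kappa_sarco=0.03, seed=3)
ens = run_walk(s, cfg, w, directions=scheme.directions)
df = signals_from_walk(ens, w, scheme.directions, [0.6])
fit = fit_from_frame(df, scheme)
print(f"diffusion-only tensor:  MD = {fit.md:.3f} um^2/ms, FA = {fit.fa:.3f}")
print(f"eigenvalues: {np.round(fit.eigenvalues, 3)} (E1 along the cell long axis)")

wb = w.with_gmax(solve_gmax(w, 0.6))
sperf = np.array([
    run_perfusion(PerfusionConfig(n_spins=10_000, sigma_v=0.15, seed=10 + j), wb, d)
    for j, d in enumerate(scheme.directions)
])
df2 = df.copy()
df2["S_over_S0"] = 0.10 * sperf + 0.90 * df2["S_over_S0"]
fit2 = fit_from_frame(df2, scheme)
print(f"with f=10% perfusion:   MD = {fit2.md:.3f} um^2/ms, FA = {fit2.fa:.3f}")
print("-> for short-encoding sequences the perfusing spins lose less signal")
print("   than diffusing ones, so adding them *lowers* the apparent MD.")
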