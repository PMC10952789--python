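"""Perfusion signal along the mean capillary axis vs velocity dispersion.

Spins traverse Watson-distributed capillary segments (K=3.25) at constant
per-spin speeds from a truncated Gaussian.  Widening the speed distribution
dephases STEAM and PGSE; the motion-compensated sequence barely responds.
"""

from myowalk import PerfusionConfig, default_spec, make_waveform, run_perfusion

EZ = (0.0, 0.0, 1.0)

print("normalized perfusion signal S_perf/S0 along E1 (b = 0.6 ms/um^2):")
print(f"{'sigma_v (mm/s)':>15s} {'STEAM':>8s} {'PGSE':>8s} {'MCSE':>8s}")
for sv in (0.001, 0.05, 0.15):
    row = []
    for kind in ("STEAM", "PGSE", "MCSE"):
        w = make_waveform(default_spec(kind, b=0.6)).with_direction(EZ)
        cfg = PerfusionConfig(n_spins=20_000, sigma_v=sv, seed=7)
        row.append(run_perfusion(cfg, w))
    print(f"{sv:15.3f} {row[0]:8.3f} {row[1]:8.3f} {row[2]:8.3f}")
print()
print("STEAM (1 s encoding) collapses with dispersion; MCSE stays near 1")
print("because its nulled gradient moments cancel constant-velocity phase.")
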