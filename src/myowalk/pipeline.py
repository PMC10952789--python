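"""Experiment orchestration: substrate -> diffusion -> perfusion -> tensor fit.

A single :class:`RunConfig` (loadable from YAML) drives replicate
simulations, combines diffusion and perfusion signals at the configured
perfusion fraction, fits tensors with the configured reference b-value, and
aggregates replicate metrics with normal-theory 95% confidence intervals.
All randomness derives deterministically from the global seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from . import __version__
from .montecarlo import WalkConfig, run_diffusion
from .perfusion import PerfusionConfig, run_perfusion
from .sequences import SequenceSpec, default_spec, make_waveform
from .substrate import (
    Substrate,
    TissueBlock,
    build_substrate,
    default_buffer,
    generate_cross_sections,
    load_block,
    morph_ecv,
)
from .tensorfit import EncodingScheme, TensorResult, fit_from_frame

log = logging.getLogger("myowalk")


@dataclass(frozen=True)
class SubstrateConfig:
    n_cells: int = 196
    mean_diameter: float = 18.0
    jitter: float = 0.35
    ecv: float = 0.2469
    Lz: float = 127.0
    icd_depth: float = 2.0
    ha_rate: float = 10.0
    half_shift: bool = True
    voxel: tuple[float, float, float] = (2800.0, 2800.0, 8000.0)
    geometry_file: str | None = None  # overrides the generator when set


@dataclass(frozen=True)
class RunConfig:
    """Full experiment description with the study-default parameters."""

    substrate: SubstrateConfig = field(default_factory=SubstrateConfig)
    sequences: tuple[str, ...] = ("STEAM", "PGSE", "MCSE")
    walk: WalkConfig = field(default_factory=WalkConfig)
    perfusion: PerfusionConfig = field(default_factory=PerfusionConfig)
    b: float = 0.6
    bref: float = 0.15
    perfusion_fraction: float = 0.10
    replicates: int = 6
    seed: int = 0

    @staticmethod
    def from_yaml(path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sub = SubstrateConfig(**{**raw.get("substrate", {})})
        if "voxel" in raw.get("substrate", {}):
            sub = replace(sub, voxel=tuple(raw["substrate"]["voxel"]))
        walk = WalkConfig(**raw.get("walk", {}))
        perf = PerfusionConfig(**raw.get("perfusion", {}))
        top = {
            k: raw[k]
            for k in ("b", "bref", "perfusion_fraction", "replicates", "seed", "sequences")
            if k in raw
        }
        if "sequences" in top:
            top["sequences"] = tuple(top["sequences"])
        return RunConfig(substrate=sub, walk=walk, perfusion=perf, **top)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def build_configured_substrate(cfg: RunConfig, T_max: float) -> Substrate:
    sc = cfg.substrate
    if sc.geometry_file:
        block = load_block(sc.geometry_file)
    else:
        cs = generate_cross_sections(sc.n_cells, sc.mean_diameter, sc.jitter, seed=cfg.seed)
        cs = morph_ecv(cs, sc.ecv)
        block = TissueBlock(cs, Lz=sc.Lz, icd_depth=sc.icd_depth)
    buf = default_buffer(cfg.walk.D_ecs, T_max)
    return build_substrate(
        block, voxel=sc.voxel, ha_rate=sc.ha_rate, half_shift=sc.half_shift, buffer=buf
    )


def _ci95(values: np.ndarray) -> float:
    """Half-width of the normal-theory 95% CI (t distribution)."""
    n = len(values)
    if n < 2:
        return float("nan")
    return float(stats.t.ppf(0.975, n - 1) * np.std(values, ddof=1) / np.sqrt(n))


def run_experiment(cfg: RunConfig, outdir=None) -> dict:
    """Run the full pipeline; returns a results bundle (and writes files).

    The bundle holds per-replicate signal tables, fitted tensors for the
    diffusion-only and diffusion+perfusion signals, aggregated MD/FA/lambda
    statistics, and a provenance record.
    """
    scheme = EncodingScheme(b=cfg.b, bref=cfg.bref)
    b_values = list(scheme.b_values)
    specs = {k: default_spec(k, b=cfg.b) for k in cfg.sequences}
    waves = {k: make_waveform(v) for k, v in specs.items()}
    T_max = max(w.T for w in waves.values())
    substrate = build_configured_substrate(cfg, T_max)
    log.info("substrate ECV %.4f, %d cells", substrate.block.cross_sections.ecv,
             len(substrate.block.cross_sections.polygons))

    signal_frames = []
    fits: dict[str, list] = {}
    for kind, w in waves.items():
        from .sequences import solve_gmax

        waves_by_b = {
            b: w.with_gmax(solve_gmax(w, b)) for b in b_values if b > 0.0
        }
        kind_tag = sum(ord(ch) for ch in kind)  # stable across processes
        for rep in range(cfg.replicates):
            wseed = (cfg.seed * 100_003 + rep * 1009 + kind_tag) % (2**31)
            wcfg = replace(cfg.walk, seed=wseed)
            df = run_diffusion(substrate, wcfg, w, directions=scheme.directions,
                               b_values=b_values)
            df["replicate"] = rep
            # perfusion signal per (direction, b)
            pseed = (wseed + 7_777_777) % (2**31)
            pcfg = replace(cfg.perfusion, seed=pseed, ha_rate=cfg.substrate.ha_rate,
                           voxel=cfg.substrate.voxel)
            sperf = []
            for _, row in df.iterrows():
                if row["b"] == 0.0:
                    sperf.append(1.0)
                else:
                    wb = waves_by_b[float(row["b"])]
                    sperf.append(
                        run_perfusion(pcfg, wb, (row["gx"], row["gy"], row["gz"]))
                    )
            df["S_perf"] = sperf
            df["S_total"] = (
                cfg.perfusion_fraction * df["S_perf"]
                + (1.0 - cfg.perfusion_fraction) * df["S_over_S0"]
            )
            signal_frames.append(df)

            fit_d = fit_from_frame(df, scheme)
            df_tot = df.copy()
            df_tot["S_over_S0"] = df_tot["S_total"]
            fit_dp = fit_from_frame(df_tot, scheme)
            fits.setdefault(kind, []).append((fit_d, fit_dp))
            log.info("%s replicate %d: MD_D=%.4f MD_D+P=%.4f", kind, rep, fit_d.md, fit_dp.md)

    signals = pd.concat(signal_frames, ignore_index=True)
    summary_rows = []
    for kind, pairs in fits.items():
        for label, idx in (("diffusion", 0), ("diffusion+perfusion", 1)):
            md = np.array([p[idx].md for p in pairs])
            fa = np.array([p[idx].fa for p in pairs])
            l1 = np.array([p[idx].eigenvalues[0] for p in pairs])
            l2 = np.array([p[idx].eigenvalues[1] for p in pairs])
            l3 = np.array([p[idx].eigenvalues[2] for p in pairs])
            row = {"sequence": kind, "signal": label, "n_replicates": len(pairs)}
            for name, arr in (("MD", md), ("FA", fa), ("l1", l1), ("l2", l2), ("l3", l3)):
                row[name] = float(arr.mean())
                if len(pairs) > 1:
                    row[f"{name}_ci95"] = _ci95(arr)
            summary_rows.append(row)
    summary = pd.DataFrame(summary_rows)

    provenance = {
        "version": __version__,
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "config": asdict(cfg),
    }
    bundle = {"signals": signals, "summary": summary, "fits": fits, "provenance": provenance}
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        signals.to_csv(outdir / "signals.csv", index=False)
        summary.to_csv(outdir / "summary.csv", index=False)
        (outdir / "provenance.json").write_text(json.dumps(provenance, indent=2, default=str))
    return bundle
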