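"""Configuration-driven experiment runner and scaled-down figure-style
reproductions.

A config is a nested mapping (YAML/JSON-friendly) with blocks:

    network:  N, c, P, A, rule {bilinear | threshold}, x_f, x_g, q_f, q_g,
              z {kind: homogeneous|bimodal|uniform|two_pop, p}
    dynamics: tau, dt, T, theta, sigma, r_max
    protocol: I_a, I_s, noise_sd, noise_tau (0 disables noise)
    metrics:  theta_P, persistence_window
    seeds:    root

All times are ms; currents are dimensionless (relative to threshold).
Unknown keys are rejected with their field path.  Every result bundle
echoes the fully resolved config and derived seeds.
"""

from __future__ import annotations

import json
import os
from typing import Any, Mapping, Optional

import numpy as np

from .dynamics import NoiseSpec, TransferFunction, constant_protocol
from .metrics import summarize
from .network import (
    PlasticityRule,
    assign_symmetry,
    build_connectivity,
    build_connectivity_two_pop,
    generate_patterns,
)
from .presets import StandardParams, measure_speed, run_retrieval, two_pop_network
from .reward import LearnerConfig, learn_inputs, trials_to_frame
from .sweep import sweep_phase_diagram

__all__ = ["default_config", "validate_config", "run", "reproduce", "derive_seeds"]

_SCHEMA: dict[str, dict[str, type]] = {
    "network": {
        "N": int,
        "c": float,
        "P": int,
        "A": float,
        "rule": str,
        "x_f": float,
        "x_g": float,
        "q_f": float,
        "q_g": float,
        "z_kind": str,
        "z_p": float,
    },
    "dynamics": {
        "tau": float,
        "dt": float,
        "T": float,
        "theta": float,
        "sigma": float,
        "r_max": float,
    },
    "protocol": {"I_a": float, "I_s": float, "noise_sd": float, "noise_tau": float},
    "metrics": {"theta_P": float, "persistence_window": float},
    "seeds": {"root": int},
}


def default_config() -> dict:
    return {
        "network": {
            "N": 8000,
            "c": 0.05,
            "P": 16,
            "A": 2.0,
            "rule": "bilinear",
            "x_f": 1.5,
            "x_g": 1.5,
            "q_f": 0.8,
            "q_g": 0.8,
            "z_kind": "two_pop",
            "z_p": 0.5,
        },
        "dynamics": {"tau": 10.0, "dt": 0.5, "T": 1000.0, "theta": 0.0, "sigma": 0.1, "r_max": 1.0},
        "protocol": {"I_a": 0.0, "I_s": 0.0, "noise_sd": 0.0, "noise_tau": 4.0},
        "metrics": {"theta_P": 0.05, "persistence_window": 200.0},
        "seeds": {"root": 0},
    }


def validate_config(config: Mapping[str, Any]) -> dict:
    """Merge over defaults and reject unknown keys, naming field paths."""
    out = default_config()
    for block, vals in config.items():
        if block not in _SCHEMA:
            raise ValueError(f"unknown config block: {block!r}")
        if not isinstance(vals, Mapping):
            raise ValueError(f"config block {block!r} must be a mapping")
        for key, v in vals.items():
            if key not in _SCHEMA[block]:
                raise ValueError(f"unknown config field: {block}.{key}")
            if v is None:
                raise ValueError(f"missing config field: {block}.{key}")
            out[block][key] = _SCHEMA[block][key](v)
    for block, fields in _SCHEMA.items():
        for key in fields:
            if out[block].get(key) is None:
                raise ValueError(f"missing config field: {block}.{key}")
    return out


def derive_seeds(root: int) -> dict[str, int]:
    """Named independent streams from one root seed (all < 2^31)."""
    ss = np.random.SeedSequence(root)
    names = ["patterns", "mask", "z", "noise", "learner", "spiking"]
    children = ss.spawn(len(names))
    return {
        n: int(c.generate_state(1, dtype=np.uint32)[0] % (2**31))
        for n, c in zip(names, children)
    }


def _build_from_config(cfg: dict):
    net, dyn = cfg["network"], cfg["dynamics"]
    seeds = derive_seeds(cfg["seeds"]["root"])
    params = StandardParams(
        N=net["N"],
        c=net["c"],
        P=net["P"],
        A=net["A"],
        tau=dyn["tau"],
        dt=dyn["dt"],
        theta=dyn["theta"],
        sigma=dyn["sigma"],
        r_max=dyn["r_max"],
    )
    if net["rule"] == "bilinear":
        rule = PlasticityRule.bilinear()
    elif net["rule"] == "threshold":
        rule = PlasticityRule(
            kind="threshold", x_f=net["x_f"], x_g=net["x_g"], q_f=net["q_f"], q_g=net["q_g"]
        )
    else:
        raise ValueError(f"unknown rule kind: network.rule = {net['rule']!r}")
    patterns = generate_patterns(net["P"], net["N"], seed=seeds["patterns"])
    if net["z_kind"] == "two_pop":
        conn = build_connectivity_two_pop(
            patterns,
            rule,
            A=net["A"] / 2.0,
            c=net["c"],
            N_a=net["N"] // 2,
            N_s=net["N"] - net["N"] // 2,
            seed=seeds["mask"],
        )
    else:
        profile = assign_symmetry(net["N"], kind=net["z_kind"], p=net["z_p"], seed=seeds["z"])
        conn = build_connectivity(
            patterns, profile, rule, A=net["A"], c=net["c"], seed=seeds["mask"]
        )
    return patterns, conn, params, seeds


def run(config: Mapping[str, Any], outdir: Optional[str] = None) -> dict:
    """Build -> simulate -> metrics; returns (and optionally writes) a
    JSON-able summary with the resolved config and all seeds echoed."""
    cfg = validate_config(config)
    patterns, conn, params, seeds = _build_from_config(cfg)
    prot = cfg["protocol"]
    noise = (
        NoiseSpec(sd=prot["noise_sd"], tau_corr=prot["noise_tau"])
        if prot["noise_sd"] > 0
        else None
    )
    summary_obj = measure_speed(
        patterns,
        conn,
        params,
        prot["I_a"],
        prot["I_s"],
        T=cfg["dynamics"]["T"],
        seed=seeds["noise"],
        noise=noise,
        stop_after_final_peak=False,
        classify=True,
    )
    result = {
        "config": cfg,
        "seeds": seeds,
        "speed": summary_obj.speed,
        "quality": summary_obj.quality,
        "status": summary_obj.status,
        "n_excluded": summary_obj.n_excluded,
    }
    if outdir is not None:
        os.makedirs(outdir, exist_ok=True)
        with open(os.path.join(outdir, "summary.json"), "w") as f:
            json.dump(result, f, indent=2, default=float)
    return result


def reproduce(figure: str, outdir: Optional[str] = None, seed: int = 0, scale: float = 1.0) -> dict:
    """Scaled-down reproduction of a reference experiment.

    ``figure`` is one of: speed_vs_z (speed–symmetry law), phase_diagram
    (input plane, bilinear), nonlinear_phase (threshold rule),
    prep_exec (preparatory/execution protocol), continuum (uniform-z
    network), learning (reward-driven input search), spiking (LIF
    fast/slow comparison).  ``scale`` multiplies the standard network
    size.  Returns the result dict; writes CSV/JSON artifacts to
    ``outdir`` when given.
    """
    known = {
        "speed_vs_z": _repro_speed_vs_z,
        "phase_diagram": _repro_phase,
        "nonlinear_phase": _repro_nonlinear,
        "prep_exec": _repro_prep_exec,
        "continuum": _repro_continuum,
        "learning": _repro_learning,
        "spiking": _repro_spiking,
    }
    if figure not in known:
        raise ValueError(f"unknown figure id {figure!r}; options: {sorted(known)}")
    result = known[figure](seed=seed, scale=scale)
    result["figure"] = figure
    result["seed"] = seed
    if outdir is not None:
        os.makedirs(outdir, exist_ok=True)
        with open(os.path.join(outdir, f"{figure}.json"), "w") as f:
            json.dump(result, f, indent=2, default=float)
    return result


def _scaled_params(scale: float, **over) -> StandardParams:
    base = StandardParams(**over)
    N = max(500, int(round(base.N * scale)))
    # keep the mean in-degree (N c) fixed as N shrinks
    c = min(1.0, base.c * base.N / N)
    return StandardParams(**{**base.__dict__, "N": N, "c": c})


def _repro_speed_vs_z(seed: int, scale: float) -> dict:
    from .presets import homogeneous_network

    p = _scaled_params(scale)
    out = []
    for z in (0.0, 0.25, 0.5, 0.75):
        patterns, conn, _ = homogeneous_network(z, seed=seed, params=p)
        s = measure_speed(patterns, conn, p, 0.0, 0.0, T=1500.0)
        out.append({"z": z, "speed": s.speed, "mft": 1.0 - z, "quality": s.quality})
    return {"points": out}


def _repro_phase(seed: int, scale: float) -> dict:
    p = _scaled_params(scale)
    patterns, conn, _ = two_pop_network(seed=seed, params=p)
    grid = np.linspace(-1.0, 0.0, 5)
    pd = sweep_phase_diagram(patterns, conn, p, grid, grid, T=1200.0)
    return {"table": pd.to_frame().to_dict(orient="records")}


def _repro_nonlinear(seed: int, scale: float) -> dict:
    from .presets import nonlinear_two_pop_network

    p = _scaled_params(scale, A=20.0, sigma=0.05)
    patterns, conn, _ = nonlinear_two_pop_network(seed=seed, params=p)
    grid_a = np.linspace(-2.0, 0.0, 5)
    grid_s = np.linspace(-1.0, 0.0, 3)
    pd = sweep_phase_diagram(patterns, conn, p, grid_a, grid_s, T=1200.0, classify=True)
    return {"table": pd.to_frame().to_dict(orient="records")}


def _repro_prep_exec(seed: int, scale: float) -> dict:
    from .dynamics import make_prep_exec_protocol
    from .presets import nonlinear_two_pop_network
    from .protocols_presets import PREP_EXEC_DEFAULTS

    p = _scaled_params(scale, A=20.0, sigma=0.05, theta=0.07)
    patterns, conn, _ = nonlinear_two_pop_network(seed=seed, params=p)
    d = PREP_EXEC_DEFAULTS
    protocol = make_prep_exec_protocol(
        prep_duration=d["prep_duration"],
        cue_duration=d["cue_duration"],
        cue_amplitude=d["cue_amplitude"],
        prep_inputs=d["prep_inputs"],
        exec_inputs=d["exec_inputs"],
        cue_binarize_at=d["cue_binarize_at"],
    )
    overlaps = run_retrieval(
        patterns, conn, p, protocol, T=1000.0, seed=seed, init_mode="zero"
    )
    summ = summarize(overlaps, p.tau, burn_in=d["prep_duration"])
    prep_idx = overlaps.times <= d["prep_duration"]
    m1_prep_min = float(np.nanmin(overlaps.m[0, prep_idx][overlaps.times[prep_idx] > 50.0]))
    return {
        "m1_prep_min": m1_prep_min,
        "exec_speed": summ.speed,
        "exec_quality": summ.quality,
        "status": summ.status,
    }


def _repro_continuum(seed: int, scale: float) -> dict:
    from .presets import homogeneous_network

    from .dynamics import constant_protocol
    from .metrics import summarize as _summarize

    p = _scaled_params(scale, A=10.0, sigma=0.05)
    rule = PlasticityRule.threshold(x_f=1.5, x_g=1.5, q_f=0.8)  # zero-mean g
    patterns = generate_patterns(p.P, p.N, seed=seed)
    profile = assign_symmetry(p.N, kind="uniform", seed=seed + 1)
    conn = build_connectivity(patterns, profile, rule, A=p.A, c=p.c, seed=seed + 2)
    out = []
    for I_a, I_s in [(-0.2, -0.2), (0.0, 0.0), (-0.3, 0.1)]:
        ov = run_retrieval(
            patterns,
            conn,
            p,
            constant_protocol(I_a, I_s),
            T=1500.0,
            single_precision=True,
            stop_after_final_peak=True,
            init_mode="binary-clamp",
        )
        s = _summarize(ov, p.tau, classify=False)
        out.append({"I_a": I_a, "I_s": I_s, "speed": s.speed, "quality": s.quality})
    return {"points": out}


def _repro_learning(seed: int, scale: float) -> dict:
    p = _scaled_params(scale * 0.5, dt=1.0)
    patterns, conn, _ = two_pop_network(seed=seed, params=p)

    def evaluator(I_a, I_s):
        s = measure_speed(patterns, conn, p, I_a, I_s, T=800.0, aggregate="soft")
        return s.speed, s.quality

    out = {}
    for target in (0.8, 0.3):
        res = learn_inputs(
            LearnerConfig(v_target=target, seed=seed, accept_slack=0.05), evaluator
        )
        out[str(target)] = {
            "converged": res.converged,
            "speed": res.speed,
            "inputs": list(res.inputs),
            "n_trials": len(res.trials),
            "trajectory": trials_to_frame(res.trials).to_dict(orient="records"),
        }
    return out


def _repro_spiking(seed: int, scale: float) -> dict:
    from .spiking import (
        SpikingParams,
        build_spiking_connectivity,
        simulate_lif,
        spiking_overlaps,
    )
    from .metrics import retrieval_speed

    p = SpikingParams()
    patterns = generate_patterns(16, p.N_E, seed=seed)
    conn = build_spiking_connectivity(patterns, p, seed=seed + 1)
    out = {}
    for label, (I_a, I_s), T in [("fast", (0.75, -0.75), 400.0), ("slow", (-1.5, 0.5), 700.0)]:
        spikes, _ = simulate_lif(conn, I_a, I_s, T=T, seed=seed + 2, patterns=patterns)
        ov = spiking_overlaps(spikes, patterns)
        peaks = ov.times[np.nanargmax(np.where(np.isnan(ov.m), -np.inf, ov.m), axis=1)]
        out[label] = {"I_a": I_a, "I_s": I_s, "peak_span_ms": float(peaks[-1] - peaks[0])}
    out["slow_over_fast"] = out["slow"]["peak_span_ms"] / max(out["fast"]["peak_span_ms"], 1e-9)
    return out
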