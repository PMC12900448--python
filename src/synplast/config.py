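"""Configuration parsing, experiment dispatch and output writers.

Experiments are configured with YAML files whose keys mirror the model
parameter tables; units are part of the key names (``tau_pre_ms``,
``theta_pro_mv``) to prevent silent unit drift.  Unknown keys are rejected
with a nearest-match suggestion.  Every run writes a manifest (config
hash, seed, output list), and reruns with equal manifest inputs produce
byte-identical numeric outputs.
"""

from __future__ import annotations

import difflib
import hashlib
import importlib.resources as resources
import json
import time
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .plasticity.stdp import StdpParams, StdpSynapse, stdp_window
from .plasticity.homeostasis import (HomeoParams, run_homeostasis_experiment)
from .plasticity.calcium import GbParams, gb_dp_curve
from .plasticity.hetero import HeteroParams, run_hetero_experiment
from .plasticity.stc import StcParams, stc_protocol, run_stc_synapse
from .network import (NetworkRecipe, StimulusProtocol, MorphoCellSpec,
                      recall_experiment, MORPHO_PRESETS)
from .busyring import BusyringParams, BusyringNetwork, busyring_run
from .events import poisson_spikes
from .rng import NoiseStream

__all__ = ["ExperimentConfig", "RunManifest", "parse_config",
           "run_experiment", "load_preset", "EXPERIMENTS"]

_PRESET_FILES = {
    "stdp-single": "stdp.yaml",
    "stdp-curve": "stdp.yaml",
    "homeostasis": "homeostasis.yaml",
    "gb-curve": "gb.yaml",
    "hetero": "hetero.yaml",
    "stc-single": "stc.yaml",
    "stc-protocols": "stc.yaml",
    "stc-network": "network.yaml",
    "morpho-network": "morpho.yaml",
    "busyring": "busyring.yaml",
}
EXPERIMENTS = tuple(_PRESET_FILES)


class ConfigError(ValueError):
    pass


@dataclass
class ExperimentConfig:
    experiment: str
    seed: int
    data: dict

    def hash(self) -> str:
        blob = json.dumps({"experiment": self.experiment, "seed": self.seed,
                           "data": self.data}, sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class RunManifest:
    experiment: str
    config_hash: str
    seed: int
    start_time: str
    version: str
    outputs: list


def load_preset(experiment: str) -> dict:
    if experiment not in _PRESET_FILES:
        raise ConfigError(
            f"unknown experiment {experiment!r}; available: "
            + ", ".join(EXPERIMENTS))
    ref = resources.files("synplast.presets") / _PRESET_FILES[experiment]
    return yaml.safe_load(ref.read_text())


def _check_keys(data, template, path=""):
    if not isinstance(data, dict):
        return
    if not isinstance(template, dict):
        raise ConfigError(f"config key {path or '<root>'}: expected a "
                          f"scalar or list, got a mapping")
    for key, val in data.items():
        if key not in template:
            hint = difflib.get_close_matches(key, template.keys(), n=1)
            msg = f"unknown config key {path + key!r}"
            if hint:
                msg += f"; did you mean {path + hint[0]!r}?"
            raise ConfigError(msg)
        if isinstance(template[key], dict):
            _check_keys(val, template[key], path + key + ".")
        elif isinstance(val, dict):
            raise ConfigError(f"config key {path + key!r} should be a "
                              f"scalar or list")


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(base.get(k), dict):
            out[k] = _merge(base[k], v)
        else:
            out[k] = v
    return out


def parse_config(path=None, experiment: str | None = None,
                 seed: int | None = None) -> ExperimentConfig:
    """Load and validate a config file (or a bundled preset).

    User files may override any subset of the preset keys of their
    experiment; unknown keys raise :class:`ConfigError` naming the key and
    the nearest valid one.
    """
    user: dict = {}
    if path is not None:
        p = Path(path)
        if not p.exists():
            raise ConfigError(f"config file not found: {path}")
        user = yaml.safe_load(p.read_text()) or {}
    name = experiment or user.get("experiment")
    if name is None:
        raise ConfigError("no experiment given (neither in the config file "
                          "nor on the command line)")
    preset = load_preset(name)
    preset["experiment"] = name
    _check_keys(user, preset)
    data = _merge(preset, user)
    data["experiment"] = name
    if seed is not None:
        data["seed"] = int(seed)
    return ExperimentConfig(experiment=name, seed=int(data.get("seed", 1)),
                            data=data)


def write_config(config: ExperimentConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(config.data, sort_keys=True))


# ---------------------------------------------------------------------------
# parameter-object builders

def stdp_params(cfg: dict) -> StdpParams:
    c = cfg["stdp"]
    return StdpParams(a_pre=c["a_pre_us"], a_post=c["a_post_us"],
                      tau_pre=c["tau_pre_ms"], tau_post=c["tau_post_ms"],
                      w0=c["w0_us"], w_max=c["w_max_us"])


def gb_params(cfg: dict) -> GbParams:
    c = cfg["gb"]
    return GbParams(w_star=c["w_star"], tc_delay=c["tc_delay_ms"],
                    c_pre=c["c_pre"], c_post=c["c_post"],
                    tau_c=c["tau_c_ms"], tau_w=c["tau_w_s"] * 1e3,
                    gamma_p=c["gamma_p"], gamma_d=c["gamma_d"],
                    theta_p=c["theta_p"], theta_d=c["theta_d"],
                    sigma_pl=c["sigma_pl"])


def hetero_params(cfg: dict) -> HeteroParams:
    c = cfg["hetero"]
    return HeteroParams(
        gamma_p=c["gamma_p_per_s"], gamma_d=c["gamma_d_per_s"],
        theta_p=c["theta_p_umol_l"], theta_d=c["theta_d_umol_l"],
        r_head=c["r_head_um"], l_head=c["l_head_um"],
        r_dendrite=c["r_dendrite_um"], l_dendrite=c["l_dendrite_um"],
        dl_comp=c["dl_comp_um"], tau_ca=c["tau_ca_ms"], tau_i=c["tau_i_ms"],
        ca_fraction=c["ca_fraction"], i0_pa=c["i0_pa"],
        diffusivity=c["diffusivity_m2_s"], w_init=c["w_init"],
        stim_interval=c["stim_interval_ms"])


def stc_params(cfg: dict) -> StcParams:
    c = cfg["stc"]
    return StcParams(
        h0=c["h0_mv"], tc_delay=c["tc_delay_s"] * 1e3, c_pre=c["c_pre"],
        c_post=c["c_post"], in_vivo_factor=c["in_vivo_factor"],
        tau_c=c["tau_c_s"] * 1e3, tau_h=c["tau_h_s"] * 1e3,
        tau_p=c["tau_p_min"] * 60e3, tau_z=c["tau_z_min"] * 60e3,
        gamma_p=c["gamma_p"], gamma_d=c["gamma_d"], theta_p=c["theta_p"],
        theta_d=c["theta_d"], sigma_pl=c["sigma_pl_mv"],
        p_max=c["p_max_umol_l"], theta_pro=c["theta_pro_mv"],
        theta_tag=c["theta_tag_mv"], f_int=c["f_int_l_umol"],
        r_comp=c["r_comp_um"], l_cell=c["l_cell_um"])


def network_recipe(cfg: dict, seed: int,
                   cell: MorphoCellSpec | None = None) -> NetworkRecipe:
    c = cfg["network"]
    return NetworkRecipe(
        n=c["n"], n_exc=c["n_exc"], p_conn=c["p_conn"], seed=seed,
        v_rest=c["v_rest_mv"], v_reset=c["v_reset_mv"],
        v_thresh=c["v_thresh_mv"], tau_m=c["tau_m_ms"], t_ref=c["t_ref_ms"],
        bg_mean=c["bg_mean_mv"], bg_sigma=c["bg_sigma_mv_sqrt_ms"],
        w_ei=c["w_ei_mv"], w_ie=c["w_ie_mv"], w_ii=c["w_ii_mv"],
        delay=c["delay_ms"], weight_scale=c["weight_scale"],
        syn_gain=c["syn_gain"], cell=cell)


def stimulus_protocol(cfg: dict) -> StimulusProtocol:
    c = cfg["stimulus"]
    return StimulusProtocol(
        n_assembly=c["n_assembly"], t_learn=c["t_learn_ms"],
        learn_dur=c["learn_dur_ms"], learn_rate=c["learn_rate_hz"],
        learn_kick=c["learn_kick_mv"], t_recall=c["t_recall_ms"],
        recall_dur=c["recall_dur_ms"], recall_rate=c["recall_rate_hz"],
        recall_kick=c["recall_kick_mv"], window=c["window_ms"])


# ---------------------------------------------------------------------------
# output writers

def write_raster(path, times, gids, seed, config_hash) -> None:
    """Two-column text raster (time_ms, gid) with a provenance header."""
    with open(path, "w") as fh:
        fh.write(f"# seed={seed} config={config_hash}\n")
        for t, g in zip(times, gids):
            fh.write(f"{t:.6f} {int(g)}\n")


def write_trace_csv(path, columns: dict) -> None:
    keys = list(columns)
    arrays = [np.asarray(columns[k]) for k in keys]
    with open(path, "w") as fh:
        fh.write(",".join(keys) + "\n")
        for row in zip(*arrays):
            fh.write(",".join(f"{x:.9g}" for x in row) + "\n")


def _json_default(o):
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    raise TypeError(type(o))


def write_summary(path, summary: dict) -> None:
    Path(path).write_text(json.dumps(summary, indent=2, sort_keys=True,
                                     default=_json_default) + "\n")


# ---------------------------------------------------------------------------
# experiment runners

def _run_stdp_single(cfg, seed, trials, outdir):
    params = stdp_params(cfg)
    syn = StdpSynapse(params)
    pre_stream = NoiseStream((seed % 2**32, 0, 0, 0))
    post_stream = NoiseStream((seed % 2**32, 0, 1, 0))
    pre = poisson_spikes(20.0, 0.0, 10e3, pre_stream)
    post = poisson_spikes(20.0, 0.0, 10e3, post_stream)
    events = sorted([(t, "pre") for t in pre] + [(t, "post") for t in post])
    ts, ws = [0.0], [syn.w]
    for t, kind in events:
        (syn.on_pre_spike if kind == "pre" else syn.on_post_spike)(t)
        ts.append(t)
        ws.append(syn.w)
    write_trace_csv(outdir / "stdp_single_trace.csv", {"t_ms": ts, "w_us": ws})
    return {"w_end_us": ws[-1], "n_pre": len(pre), "n_post": len(post)}, [
        "stdp_single_trace.csv"]


def _run_stdp_curve(cfg, seed, trials, outdir):
    params = stdp_params(cfg)
    c = cfg["curve"]
    dts = np.linspace(c["dt_min_ms"], c["dt_max_ms"], int(c["n_points"]))
    dws = [stdp_window(d, params) for d in dts]
    write_trace_csv(outdir / "stdp_curve.csv",
                    {"delta_t_ms": dts, "delta_w_us": dws})
    return {"delta_t_ms": dts, "delta_w_us": dws}, ["stdp_curve.csv"]


def _run_homeostasis(cfg, seed, trials, outdir):
    c = cfg["homeostasis"]
    params = HomeoParams(dw_plus=c["dw_plus_na"], dw_minus=c["dw_minus_na"],
                         w_init=c["w_init_na"], w_max=c["w_max_na"])
    res = run_homeostasis_experiment(
        n_trials=trials, seed=seed, params=params,
        fixed_rate=c["fixed_rate_hz"], w_static=c["w_varying_na"],
        schedule=[tuple(s) for s in cfg["schedule"]],
        kick_mv_per_na=c["kick_mv_per_na"], plastic=c["plastic"])
    write_trace_csv(outdir / "homeostasis_rates.csv", {
        "segment": np.arange(len(res["segment_rates_mean"])),
        "rate_hz": res["segment_rates_mean"],
        "input_rate_hz": [r for _, r in res["schedule"]]})
    return {"mean_rate_nonsilent_hz": res["mean_rate_nonsilent"],
            "segment_rates_hz": res["segment_rates_mean"]}, [
        "homeostasis_rates.csv"]


def _run_gb_curve(cfg, seed, trials, outdir):
    params = gb_params(cfg)
    c = cfg["protocol"]
    res = gb_dp_curve(c["dt_grid_ms"], n_pairs=c["n_pairs"],
                      pair_rate=c["pair_rate_hz"], n_trials=trials,
                      seed=seed, params=params)
    write_trace_csv(outdir / "gb_dp_curve.csv", {
        "delta_t_ms": res["delta_t"], "mean_change": res["mean_change"],
        "ci95": res["ci95"]})
    return {"delta_t_ms": res["delta_t"],
            "mean_change": res["mean_change"]}, ["gb_dp_curve.csv"]


def _run_hetero(cfg, seed, trials, outdir):
    params = hetero_params(cfg)
    c = cfg["run"]
    res = run_hetero_experiment(params, t_stim=c["t_stim_ms"],
                                t_relax=c["t_relax_ms"], dt=c["dt_ms"])
    cols = {"t_ms": res["t"]}
    for i in range(res["weights"].shape[1]):
        cols[f"w_spine{i + 1}"] = res["weights"][:, i]
        cols[f"ca_spine{i + 1}_umol_l"] = res["ca_spines"][:, i]
    write_trace_csv(outdir / "hetero_traces.csv", cols)
    return {"w_end": res["weights"][-1], "w_init": res["w_init"]}, [
        "hetero_traces.csv"]


def _run_stc_single(cfg, seed, trials, outdir):
    params = stc_params(cfg)
    # basic early-phase paradigm: a few strong presynaptic bursts
    pre = np.concatenate([np.arange(0, 100, 10) + t0
                          for t0 in (1000.0, 4000.0, 7000.0)])
    trace = {"t": [], "h": [], "z": [], "p": []}

    def rec(t, h, z, p):
        trace["t"].append(t)
        trace["h"].append(h)
        trace["z"].append(z)
        trace["p"].append(p)

    stream = NoiseStream((seed % 2**32, 0, 1, 0))
    res = run_stc_synapse(pre, np.empty(0), params, stream, 10e3,
                          record=rec)
    write_trace_csv(outdir / "stc_single_trace.csv", {
        "t_ms": trace["t"], "h_mv": trace["h"], "z": trace["z"],
        "p_umol_l": trace["p"]})
    return {"h_end_mv": res["h"], "z_end": res["z"],
            "w_end_mv": res["w"]}, ["stc_single_trace.csv"]


def _run_stc_protocols(cfg, seed, trials, outdir):
    params = stc_params(cfg)
    summary = {}
    outputs = []
    for name in cfg["protocols"]:
        res = stc_protocol(name, seed=seed, n_trials=trials, params=params,
                           post_rate_hz=cfg["post_rate_hz"])
        fname = f"stc_protocol_{name}.csv"
        write_trace_csv(outdir / fname, {
            "t_ms": res["trace"]["t"], "h_mv": res["trace"]["h"],
            "z": res["trace"]["z"], "p_umol_l": res["trace"]["p"]})
        outputs.append(fname)
        summary[name] = {
            "h_end_mv": float(res["h"].mean()),
            "z_end": float(res["z"].mean()),
            "w_end_mv": float(res["w"].mean()),
            "tag_crossed_frac": float(res["tag_crossed"].mean()),
            "pro_crossed_frac": float(res["pro_crossed"].mean()),
        }
    return summary, outputs


def _run_stc_network(cfg, seed, trials, outdir):
    recipe = network_recipe(cfg, seed)
    stim = stimulus_protocol(cfg)
    seeds = [seed + i for i in range(trials)]
    res = recall_experiment(seeds, recipe, stim, dt=cfg["dt_ms"])
    write_trace_csv(outdir / "recall_Q.csv",
                    {"seed": np.asarray(seeds, dtype=float), "Q": res["Q"]})
    return {"mean_Q": res["mean_Q"], "Q": res["Q"],
            "rates_hz": res["rates"]}, ["recall_Q.csv"]


def _run_morpho_network(cfg, seed, trials, outdir):
    key = (cfg["cell_size"], cfg["dendrites"])
    if key not in MORPHO_PRESETS:
        raise ConfigError(f"unknown cell variant {key!r}")
    m = cfg["morphology"]
    base = MORPHO_PRESETS[key]
    cell = MorphoCellSpec(
        r_comp=base.r_comp, l_soma=base.l_soma, l_apical=base.l_apical,
        l_basal=base.l_basal, dl_comp=m["dl_comp_um"], l_prp=m["l_prp_um"],
        c_morpho=m["c_morpho"][f"{key[0]}_{key[1]}"],
        d_sps=m["d_sps_m2_s"], d_p=m["d_p_m2_s"])
    recipe = network_recipe(cfg, seed, cell=cell)
    stim = stimulus_protocol(cfg)
    seeds = [seed + i for i in range(trials)]
    res = recall_experiment(seeds, recipe, stim, dt=cfg["dt_ms"])
    write_trace_csv(outdir / "recall_Q.csv",
                    {"seed": np.asarray(seeds, dtype=float), "Q": res["Q"]})
    return {"mean_Q": res["mean_Q"], "Q": res["Q"],
            "n_compartments": cell.build_grid().n}, ["recall_Q.csv"]


def _run_busyring(cfg, seed, trials, outdir):
    c = cfg["busyring"]
    s = cfg["stdp"]
    stdp = StdpParams(a_pre=s["a_pre_us"], a_post=s["a_post_us"],
                      tau_pre=s["tau_pre_ms"], tau_post=s["tau_post_ms"],
                      w0=0.0, w_max=s["w_max_us"])
    params = BusyringParams(
        n_cells=c["n_cells"], k=c["k"], s=c["s"], t_delay=c["t_delay_ms"],
        dt=c["dt_ms"], t_end=c["t_duration_ms"],
        stdp_on_random=c["stdp_on_random"], stdp=stdp, seed=seed)
    net = BusyringNetwork(params)
    res = busyring_run(net)
    return ({"rate_per_neuron_hz": res["rate_per_neuron"],
             "n_spikes": int(res["times"].size),
             "delivered_events": res["delivered_events"]},
            [], res)


_RUNNERS = {
    "stdp-single": _run_stdp_single,
    "stdp-curve": _run_stdp_curve,
    "homeostasis": _run_homeostasis,
    "gb-curve": _run_gb_curve,
    "hetero": _run_hetero,
    "stc-single": _run_stc_single,
    "stc-protocols": _run_stc_protocols,
    "stc-network": _run_stc_network,
    "morpho-network": _run_morpho_network,
    "busyring": _run_busyring,
}


def run_experiment(config: ExperimentConfig, outdir,
                   trials: int | None = None) -> RunManifest:
    """Dispatch to the named experiment, write outputs and a manifest."""
    if config.experiment not in _RUNNERS:
        raise ConfigError(
            f"unknown experiment {config.experiment!r}; available: "
            + ", ".join(EXPERIMENTS))
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    trials = trials if trials is not None else int(
        config.data.get("trials", 1))
    result = _RUNNERS[config.experiment](config.data, config.seed, trials,
                                         outdir)
    if len(result) == 3:
        summary, outputs, raster = result
        write_raster(outdir / "raster.txt", raster["times"], raster["gids"],
                     config.seed, config.hash())
        outputs = list(outputs) + ["raster.txt"]
    else:
        summary, outputs = result
    write_summary(outdir / "summary.json",
                  {"experiment": config.experiment, "seed": config.seed,
                   **summary})
    outputs = list(outputs) + ["summary.json"]
    manifest = RunManifest(
        experiment=config.experiment, config_hash=config.hash(),
        seed=config.seed,
        start_time=time.strftime("%Y-%m-%dT%H:%M:%S"),
        version=__version__, outputs=outputs)
    (outdir / "manifest.json").write_text(
        json.dumps(asdict(manifest), indent=2) + "\n")
    return manifest
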