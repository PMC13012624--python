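"""Executable experiment protocols.

Each protocol reproduces one of the in-silico fear-conditioning experiments:
engram formation, coordinated sleep replay, multi-day recall curves, fear
acquisition/extinction, generalisation gradients, ABA/ABC/AAB renewal,
time-dependent generalisation, multi-context extinction, pre/post-sleep
afferent-weight histograms, chronic sleep deprivation, and stress-enhanced
fear learning (SEFL).

A protocol is a function ``(model: FearModel, rng, **params) -> (traces,
summary)`` registered under a short name; :func:`run_protocol` executes it
over one or several seeds and returns a :class:`ProtocolResult` whose traces
and per-seed summaries are tidy pandas DataFrames, reproducible bit-exactly
from (config, seed).  :func:`sweep` runs a protocol over a parameter grid.

Phase durations below are this package's reconstruction of the experimental
schedules; they are deliberately modest so that full Monte-Carlo repetitions
remain cheap, and every one of them can be overridden per call.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Callable

import numpy as np
import pandas as pd

from .config import ModelConfig
from .context import ContextSpec, USSchedule, encode_sc, make_similar, sample_context
from .hippocampus import Route
from .metrics import encoding_strength, f1_score, pattern_distance
from .model import FearModel

ProtocolFn = Callable[..., tuple[pd.DataFrame, dict[str, Any]]]
PROTOCOLS: dict[str, ProtocolFn] = {}


def register(name: str) -> Callable[[ProtocolFn], ProtocolFn]:
    def deco(fn: ProtocolFn) -> ProtocolFn:
        PROTOCOLS[name] = fn
        return fn
    return deco


@dataclass
class ProtocolConfig:
    """A protocol run request: name, seeds, and parameter overrides."""

    name: str
    seeds: list[int] = field(default_factory=lambda: [0])
    model: dict[str, Any] = field(default_factory=dict)   # ModelConfig overrides
    params: dict[str, Any] = field(default_factory=dict)  # protocol kwargs

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "ProtocolConfig":
        return cls(
            name=data["name"],
            seeds=list(data.get("seeds", [0])),
            model=dict(data.get("model", {})),
            params=dict(data.get("params", {})),
        )


@dataclass
class ProtocolResult:
    """Traces and per-seed summaries of one protocol run."""

    config: ProtocolConfig
    traces: pd.DataFrame
    summaries: pd.DataFrame  # one row per seed

    def save(self, out_dir: str | Path) -> Path:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.traces.to_csv(out / "traces.csv", index=False)
        self.summaries.to_csv(out / "summary.csv", index=False)
        meta = {
            "protocol": self.config.name,
            "seeds": self.config.seeds,
            "model_overrides": self.config.model,
            "params": self.config.params,
        }
        (out / "config.json").write_text(json.dumps(meta, indent=2))
        return out


def run_protocol(config: ProtocolConfig) -> ProtocolResult:
    """Execute a registered protocol for every configured seed."""
    if config.name not in PROTOCOLS:
        raise KeyError(
            f"unknown protocol {config.name!r}; available: {sorted(PROTOCOLS)}"
        )
    fn = PROTOCOLS[config.name]
    all_traces, all_summaries = [], []
    for seed in config.seeds:
        cfg = ModelConfig().override(config.model) if config.model else ModelConfig()
        model = FearModel(cfg, seed=seed)
        rng = np.random.default_rng(int(seed) + 10_000)
        traces, summary = fn(model, rng, **config.params)
        traces = traces.assign(seed=seed)
        summary = {"seed": seed, **summary}
        all_traces.append(traces)
        all_summaries.append(summary)
    return ProtocolResult(
        config,
        pd.concat(all_traces, ignore_index=True) if all_traces else pd.DataFrame(),
        pd.DataFrame(all_summaries),
    )


def sweep(config: ProtocolConfig, grid: dict[str, list[Any]]) -> pd.DataFrame:
    """Cross-product parameter sweep; returns long-format per-seed summaries.

    Grid keys prefixed ``model.`` address model parameters (dotted paths into
    :class:`ModelConfig`); all other keys are protocol parameters.  An empty
    grid degenerates to a single :func:`run_protocol` call.
    """
    if not grid:
        res = run_protocol(config)
        return res.summaries
    keys = list(grid)
    rows = []
    for combo in itertools.product(*(grid[k] for k in keys)):
        cfg = ProtocolConfig(
            config.name, list(config.seeds), dict(config.model), dict(config.params)
        )
        for key, value in zip(keys, combo):
            if key.startswith("model."):
                cfg.model[key[len("model."):]] = value
            else:
                cfg.params[key] = value
        res = run_protocol(cfg)
        summ = res.summaries
        for key, value in zip(keys, combo):
            summ[key] = value
        rows.append(summ)
    return pd.concat(rows, ignore_index=True)


# --------------------------------------------------------------- utilities

def _records_df(records, **extra) -> pd.DataFrame:
    df = pd.DataFrame(
        [
            {"t": r.t, "day": r.day, "mode": r.mode, "us": r.us,
             "n_p": r.n_p, "n_i": r.n_i, "cea": r.cea, "error": r.error}
            for r in records
        ]
    )
    for k, v in extra.items():
        df[k] = v
    return df


def _onset(records, n: int = 5) -> float:
    return float(np.mean([r.cea for r in records[:n]]))


def _steps_to_half(records, onset: float) -> int:
    for i, r in enumerate(records):
        if r.cea <= onset / 2:
            return i
    return len(records)


# --------------------------------------------------------------- protocols

@register("engram_formation")
def engram_formation(
    model: FearModel, rng, steps: int = 50, us_amp: float = 0.6, us_from: int = 20
):
    """Encoding-strength build-up in HIP, CTX and BA_N for one novel context.

    The context is presented for ``steps`` time steps with the US delivered
    on the final ``steps - us_from``; HIP binds fast, CTX slowly, BA_N only
    once a surprising US opens its error gate.
    """
    context = sample_context(rng, model.cfg.n_features, model.cfg.n_values)
    sc = encode_sc(context)
    us = USSchedule.window(steps, us_amp, us_from, steps)
    rows = []
    for step, amp in enumerate(us.amplitude):
        rec = model.perceive_step(sc, float(amp))
        rows.append(
            {"t": rec.t, "step": step, "us": rec.us, "cea": rec.cea,
             "enc_hip": encoding_strength(model.hip.W_rec, model.hip.act),
             "enc_ctx": encoding_strength(model.ctx.W_rec, model.ctx.act),
             "enc_ban": encoding_strength(model.ba.W_rec, model.ba.act)}
        )
    df = pd.DataFrame(rows)
    summary = {
        "enc_hip_final": df.enc_hip.iloc[-1],
        "enc_ctx_final": df.enc_ctx.iloc[-1],
        "enc_ban_final": df.enc_ban.iloc[-1],
        "enc_ban_pre_us": df.enc_ban.iloc[us_from - 1],
    }
    return df, summary


@register("replay_demo")
def replay_demo(
    model: FearModel, rng, n_contexts: int = 10, n_us: int = 5,
    steps: int = 30, us_amp: float = 0.6, match_margin: float = 0.25,
):
    """Coordinated Sleep replay after sequential exposure to several contexts.

    US signals accompany the last ``n_us`` contexts only; BA_N co-replay is
    expected to be restricted to those.  The trace records, per Sleep step
    and region, the nearest stored engram and its distance.
    """
    stored: list[dict[str, np.ndarray]] = []
    for i in range(n_contexts):
        c = sample_context(rng, model.cfg.n_features, model.cfg.n_values)
        us = (USSchedule.window(steps, us_amp, steps - 10, steps)
              if i >= n_contexts - n_us else USSchedule.none(steps))
        model.perceive_episode(c, us)
        stored.append({"hip": model.hip.act.copy(), "ctx": model.ctx.act.copy(),
                       "ban": model.ba.act.copy()})
    sleep_trace = model.run_sleep(record=True)
    rows = []
    for entry in sleep_trace:
        for region in ("hip", "ctx", "ban"):
            act = entry[region]
            if act.any():
                dists = [pattern_distance(act, s[region]) for s in stored]
                nearest = int(np.argmin(dists))
                dist = float(dists[nearest])
            else:
                nearest, dist = -1, np.nan
            rows.append({"step": entry["step"], "region": region,
                         "nearest": nearest, "distance": dist})
    df = pd.DataFrame(rows)
    summary = {}
    for region in ("hip", "ctx", "ban"):
        sub = df[(df.region == region) & (df.distance <= match_margin)]
        replayed = sorted(sub.nearest.unique().tolist())
        summary[f"replayed_{region}"] = json.dumps(replayed)
        summary[f"n_replayed_{region}"] = len(replayed)
    summary["n_us_contexts"] = n_us
    return df, summary


@register("recall_curve")
def recall_curve(
    model: FearModel, rng, days: int = 15, per_day: int = 2,
    steps: int = 20, light_us: float = 0.2, blur: float = 0.1,
):
    """Recall success vs memory age for HIP, CTX and BA_N.

    New contexts are perceived daily with a light US (final 10 steps; just
    enough to open BA_N plasticity), nights interleave Sleep; on the final
    day every stored context is probed with a partially masked cue.
    """
    stored = []
    for day in range(days):
        for _ in range(per_day):
            c = sample_context(rng, model.cfg.n_features, model.cfg.n_values)
            model.perceive_episode(
                c, USSchedule.window(steps, light_us, steps - 10, steps)
            )
            stored.append((day, model.hip.act.copy(), model.ctx.act.copy(),
                           model.ba.act.copy(), c))
        model.run_sleep()
    rows = []
    for day, hip, ctx, ban, c in stored:
        res = model.recall_probe(c, blur=blur, rng=rng)
        rows.append(
            {"age": days - day,
             "hip_ok": f1_score(res.hip_act, hip) >= model.cfg.recall_margin,
             "ctx_ok": f1_score(res.ctx_act, ctx) >= model.cfg.recall_margin,
             "ban_ok": f1_score(res.ban_converged, ban) >= model.cfg.recall_margin,
             "route": res.route.value}
        )
    df = pd.DataFrame(rows)
    by_age = df.groupby("age")[["hip_ok", "ctx_ok", "ban_ok"]].mean()
    hip_pos = by_age.index[by_age.hip_ok > 0]
    ctx_peak = (by_age.ctx_ok.idxmax() if by_age.ctx_ok.max() > 0 else -1)
    summary = {
        "hip_max_age": int(hip_pos.max()) if len(hip_pos) else 0,
        "ctx_peak_age": int(ctx_peak),
        "ctx_peak_rate": float(by_age.ctx_ok.max()),
        "hip_rate_age1": float(by_age.hip_ok.get(1, np.nan)),
    }
    return df, summary


@register("acq_ext")
def acq_ext(
    model: FearModel, rng, steps: int = 70, us_amp: float = 1.0, us_until: int = 20
):
    """Fear acquisition then extinction within a single episode."""
    context = sample_context(rng, model.cfg.n_features, model.cfg.n_values)
    us = USSchedule.window(steps, us_amp, 0, us_until)
    records = model.perceive_episode(context, us)
    df = _records_df(records)
    ceas = df.cea.to_numpy()
    first_p = next((i for i, r in enumerate(records) if r.n_p), -1)
    first_i = next((i for i, r in enumerate(records) if r.n_i), -1)
    summary = {
        "peak_cea": float(ceas.max()),
        "final_cea": float(ceas[-1]),
        "first_p_step": first_p,
        "first_i_step": first_i,
    }
    return df, summary


def _train_acq_ext(
    model: FearModel, rng, acq_steps: int, ext_steps: int, us_amp: float
) -> ContextSpec:
    """Acquisition then extinction in a fresh context A; returns A."""
    A = sample_context(rng, model.cfg.n_features, model.cfg.n_values)
    model.perceive_episode(A, USSchedule.constant(acq_steps, us_amp))
    model.perceive_episode(A, USSchedule.none(ext_steps))
    return A


@register("gradient")
def gradient(
    model: FearModel, rng, acq_steps: int = 150, ext_steps: int = 400,
    us_amp: float = 1.0, levels: tuple[float, ...] = tuple(
        round(0.1 * i, 1) for i in range(1, 11)),
):
    """Generalisation gradients of P-cells, I-cells and CeA after
    acquisition + extinction in a reference context."""
    A = _train_acq_ext(model, rng, acq_steps, ext_steps, us_amp)
    rows = []
    for lvl in levels:
        probe = make_similar(A, lvl, rng) if lvl < 1.0 else A
        res = model.recall_probe(probe)
        rows.append({"level": lvl, "n_p": res.n_p, "n_i": res.n_i,
                     "cea": res.cea, "route": res.route.value})
    df = pd.DataFrame(rows)
    p_lv = df.level[df.n_p > 0]
    i_lv = df.level[df.n_i > 0]
    summary = {
        "first_p_level": float(p_lv.min()) if len(p_lv) else np.nan,
        "first_i_level": float(i_lv.min()) if len(i_lv) else np.nan,
    }
    return df, summary


@register("renewal")
def renewal(
    model: FearModel, rng, paradigm: str = "ABA", overlap: float = 0.8,
    acq_steps: int = 30, ext_steps: int = 300, test_steps: int = 60,
    us_amp: float = 1.0, onset_steps: int = 5,
):
    """ABA / ABC / AAB renewal: acquire in A, extinguish, test.

    Onset fear is the mean CeA output over the first test steps; savings are
    measured as steps-to-half-fear during initial vs renewal extinction.
    """
    if paradigm not in ("ABA", "ABC", "AAB"):
        raise ValueError(f"paradigm must be ABA, ABC or AAB, got {paradigm!r}")
    A = sample_context(rng, model.cfg.n_features, model.cfg.n_values)
    B = make_similar(A, overlap, rng)
    C = make_similar(A, overlap, rng)
    ext_ctx = {"ABA": B, "ABC": B, "AAB": A}[paradigm]
    test_ctx = {"ABA": A, "ABC": C, "AAB": B}[paradigm]
    acq = model.perceive_episode(A, USSchedule.constant(acq_steps, us_amp))
    ext = model.perceive_episode(ext_ctx, USSchedule.none(ext_steps))
    test = model.perceive_episode(test_ctx, USSchedule.none(test_steps))
    df = pd.concat(
        [_records_df(acq, phase="acq"), _records_df(ext, phase="ext"),
         _records_df(test, phase="test")], ignore_index=True,
    )
    ext_onset = _onset(ext, onset_steps)
    test_onset = _onset(test, onset_steps)
    summary = {
        "paradigm": paradigm,
        "onset_fear": test_onset,
        "ext_half_steps": _steps_to_half(ext, ext_onset),
        "reext_half_steps": _steps_to_half(test, test_onset),
    }
    return df, summary


@register("generalisation_over_time")
def generalisation_over_time(
    model: FearModel, rng, days: int = 16, b_overlap: float = 0.5,
    c_overlap: float = 0.1, acq_steps: int = 30, us_amp: float = 1.0,
):
    """Time-dependent fear generalisation and the HIP→CTX recall handover.

    Fear is conditioned in A; a similar harmless context B (and a dissimilar
    control C) are probed daily.  As the hippocampal trace fades and recall
    of B shifts to the cortical route, partial reactivation of A's amygdala
    engram raises fear in B; C stays fear-free.
    """
    A = sample_context(rng, model.cfg.n_features, model.cfg.n_values)
    B = make_similar(A, b_overlap, rng)
    C = make_similar(A, c_overlap, rng)
    model.perceive_episode(A, USSchedule.constant(acq_steps, us_amp))
    model.run_sleep()
    # B becomes familiar only after the first night: post-homeostasis no
    # fear generalizes to B, so its exposure carries no prediction error
    model.perceive_episode(B, USSchedule.none(10))
    rows = [{"day": 1, "cea_b": model.recall_probe(B).cea,
             "cea_c": model.recall_probe(C).cea,
             "route_b": "hip", "recall_score_b": 1.0}]
    for day in range(2, days + 1):
        model.run_sleep()
        res_b = model.recall_probe(B)
        res_c = model.recall_probe(C)
        rows.append(
            {"day": day, "cea_b": res_b.cea, "cea_c": res_c.cea,
             "route_b": res_b.route.value, "recall_score_b": res_b.f1_gate}
        )
    df = pd.DataFrame(rows)
    early = df.head(3)
    late = df.tail(3)
    summary = {
        "cea_b_early": float(early.cea_b.mean()),
        "cea_b_late": float(late.cea_b.mean()),
        "cea_c_late": float(late.cea_c.mean()),
        "ctx_route_frac_early": float((early.route_b == "ctx").mean()),
        "ctx_route_frac_late": float((late.route_b == "ctx").mean()),
    }
    return df, summary


@register("multi_context_extinction")
def multi_context_extinction(
    model: FearModel, rng, n_ext_contexts: int = 4, ab_overlap: float = 0.8,
    ac_overlap: float = 0.8, acq_steps: int = 30, ext_total: int = 400,
    test_steps: int = 40, us_amp: float = 1.0, onset_steps: int = 5,
):
    """ABC renewal with extinction distributed over several similar contexts.

    Total extinction duration is matched between conditions; with
    ``n_ext_contexts=1`` this is the single-context control.
    """
    A = sample_context(rng, model.cfg.n_features, model.cfg.n_values)
    Bs = [make_similar(A, ab_overlap, rng) for _ in range(n_ext_contexts)]
    C = make_similar(A, ac_overlap, rng)
    acq = model.perceive_episode(A, USSchedule.constant(acq_steps, us_amp))
    per = ext_total // n_ext_contexts
    ext_records = []
    for B in Bs:
        ext_records.extend(model.perceive_episode(B, USSchedule.none(per)))
    test = model.perceive_episode(C, USSchedule.none(test_steps))
    df = pd.concat(
        [_records_df(acq, phase="acq"), _records_df(ext_records, phase="ext"),
         _records_df(test, phase="test")], ignore_index=True,
    )
    summary = {
        "n_ext_contexts": n_ext_contexts,
        "renewal_onset": _onset(test, onset_steps),
    }
    return df, summary


@register("weight_histograms")
def weight_histograms(
    model: FearModel, rng, b_overlap: float = 0.5, acq_steps: int = 30,
    us_amp: float = 1.0,
):
    """Per-P-cell summed afferent strength before and after Sleep.

    Reported for the conditioned context A and an unconditioned, vaguely
    similar context B; Sleep homeostasis should preserve fear in A while
    abolishing generalized fear in B.
    """
    A = sample_context(rng, model.cfg.n_features, model.cfg.n_values)
    B = make_similar(A, b_overlap, rng)
    model.perceive_episode(A, USSchedule.constant(acq_steps, us_amp))

    def snapshot(tag):
        out = {}
        for name, ctx in (("A", A), ("B", B)):
            res = model.recall_probe(ctx)
            drive = model.ba.W_np.drive(res.ban_act)
            out[f"drive_{name}_{tag}"] = drive
            out[f"cea_{name}_{tag}"] = res.cea
            out[f"np_{name}_{tag}"] = res.n_p
        return out

    pre = snapshot("pre")
    model.run_sleep()
    post = snapshot("post")
    rows = []
    for tag, snap in (("pre", pre), ("post", post)):
        for name in ("A", "B"):
            for cell, drive in enumerate(snap[f"drive_{name}_{tag}"]):
                rows.append({"phase": tag, "context": name, "p_cell": cell,
                             "afferent_sum": float(drive)})
    df = pd.DataFrame(rows)
    theta = model.cfg.theta_p
    summary = {
        "cea_A_pre": pre["cea_A_pre"], "cea_B_pre": pre["cea_B_pre"],
        "cea_A_post": post["cea_A_post"], "cea_B_post": post["cea_B_post"],
        "np_A_pre": pre["np_A_pre"], "np_B_pre": pre["np_B_pre"],
        "np_A_post": post["np_A_post"], "np_B_post": post["np_B_post"],
        "max_excess_pre": float(pre["drive_A_pre"].max() / theta),
        "max_excess_post": float(post["drive_A_post"].max() / theta),
    }
    return df, summary


@register("sleep_deprivation")
def sleep_deprivation(
    model: FearModel, rng, sleep_cut: float = 0.0, days: int = 7,
    per_day: int = 3, steps: int = 30, test_us: float = 0.6,
    test_us_steps: int = 3, test_obs_steps: int = 10,
):
    """Chronic sleep restriction followed by a brief fear-acquisition test.

    Daily exposures are paired with US amplitudes of generally low strength
    (0.9 * Beta(1, 2.5)); nightly Sleep is shortened by ``sleep_cut``.  On
    the final day a novel context receives a brief moderate US and the fear
    response over the following steps is recorded, along with the net
    context→fear synaptic strength.
    """
    for _ in range(days):
        for _ in range(per_day):
            c = sample_context(rng, model.cfg.n_features, model.cfg.n_values)
            amp = 0.9 * rng.beta(1.0, 2.5)
            model.perceive_episode(c, USSchedule.window(steps, amp, steps - 10, steps))
        model.run_sleep(int(round(model.cfg.sleep_steps * (1.0 - sleep_cut))))
    test = sample_context(rng, model.cfg.n_features, model.cfg.n_values)
    amps = np.zeros(test_us_steps + test_obs_steps)
    amps[:test_us_steps] = test_us
    records = model.perceive_episode(test, USSchedule(amps))
    df = _records_df(records, phase="test", sleep_cut=sleep_cut)
    summary = {
        "sleep_cut": sleep_cut,
        "test_fear": float(np.mean([r.cea for r in records[test_us_steps:]])),
        "sum_w_np": model.total_w_np(),
    }
    return df, summary


@register("sefl")
def sefl(
    model: FearModel, rng, group: str = "trauma", order: str = "before",
    delay_cycles: int = 0, trauma_amp: float = 1.3, trauma_steps: int = 30,
    cond_us: float = 0.6, cond_us_steps: int = 3, test_steps: int = 5,
):
    """Stress-enhanced fear learning.

    ``group``: 'trauma' (intense prolonged US in context A) or 'control'
    (same exposure without US).  ``order``: 'before' (trauma precedes the
    moderate conditioning of context B) or 'after'.  ``delay_cycles``
    interposes additional Perception–Sleep cycles with weak random US
    between trauma and conditioning (persistence variant).  The summary
    tracks test fear in B and the net BA_N→BA_P strength trajectory.
    """
    if group not in ("trauma", "control"):
        raise ValueError(f"group must be 'trauma' or 'control', got {group!r}")
    if order not in ("before", "after"):
        raise ValueError(f"order must be 'before' or 'after', got {order!r}")
    A = sample_context(rng, model.cfg.n_features, model.cfg.n_values)
    B = sample_context(rng, model.cfg.n_features, model.cfg.n_values)
    w_np_0 = model.total_w_np()
    w_trace = []

    def note(phase):
        w_trace.append({"phase": phase, "day": model.day,
                        "d_sum_w_np": model.total_w_np() - w_np_0})

    def trauma_day():
        us = (USSchedule.constant(trauma_steps, trauma_amp) if group == "trauma"
              else USSchedule.none(trauma_steps))
        model.perceive_episode(A, us)
        note("trauma_perception")
        model.run_sleep()
        note("trauma_sleep")

    def filler_day():
        c = sample_context(rng, model.cfg.n_features, model.cfg.n_values)
        amp = 0.9 * rng.beta(1.0, 2.5)
        model.perceive_episode(c, USSchedule.window(30, amp, 20, 30))
        note("filler_perception")
        model.run_sleep()
        note("filler_sleep")

    def cond_day():
        amps = np.zeros(10)
        amps[:cond_us_steps] = cond_us
        model.perceive_episode(B, USSchedule(amps))
        note("cond_perception")
        model.run_sleep()
        note("cond_sleep")

    if order == "before":
        trauma_day()
        for _ in range(delay_cycles):
            filler_day()
        cond_day()
    else:
        cond_day()
        trauma_day()
    test = model.perceive_episode(B, USSchedule.none(test_steps))
    df = pd.DataFrame(w_trace)
    summary = {
        "group": group,
        "order": order,
        "delay_cycles": delay_cycles,
        "test_fear": float(np.mean([r.cea for r in test])),
        "d_sum_w_np_final": float(model.total_w_np() - w_np_0),
    }
    return df, summary
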