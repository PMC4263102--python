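"""End-to-end orchestration: configuration, seeding, recovery experiments.

Two composite experiments tie the modules together:

* :func:`run_recovery_experiment` — generate a synthetic mini train from a
  generative decay mixture, detect the events, fit their decays, decompose
  the recovered decay-constant distribution and report biases against the
  generative truth;
* :func:`run_markov_population` — simulate populations of stochastic
  miniature IPSCs from fast- and slow-calibrated gating schemes, fit every
  decay and summarize the resulting decay-constant distributions.

A single global seed is expanded into independent per-module child seeds
through ``numpy.random.SeedSequence(seed, spawn_key=(index,))`` with a
fixed module -> index map, so any stage can be re-run in isolation and a
run is reproducible from its config alone.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import asdict, dataclass, field
from typing import Dict, List, Optional

import numpy as np
import yaml

from . import params as p
from .detect import detect_events, events_to_frame
from .fitting import fit_exponential
from .mixture import MixtureSpec, fit_mixture_cdf
from .scheme import AgonistPulse, default_scheme
from .synth import (
    MiniTrainSpec,
    add_noise,
    calibrate_scheme,
    generate_mini_train,
    simulate_channels_mc,
    simulate_macroscopic,
)

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "child_seed", "run_recovery_experiment", "run_markov_population"]

_MODULE_KEYS = {"synth": 0, "detect": 1, "fit": 2, "mixture": 3,
                "charge": 4, "cable": 5, "markov": 6}


def child_seed(seed: int, module: str) -> int:
    """Deterministic per-module child seed below 2^31."""
    ss = np.random.SeedSequence(seed, spawn_key=(_MODULE_KEYS[module],))
    return int(ss.generate_state(1, dtype=np.uint32)[0] % (2 ** 31))


@dataclass
class RunConfig:
    """Serializable description of a full synthetic run."""

    seed: int = 0
    # mini-train block
    duration_s: float = 600.0
    event_rate_hz: float = 0.15
    amplitude_mean_pa: float = 19.5
    amplitude_sd_pa: float = 6.0
    noise_sd_pa: float = 2.0
    rise_tau_ms: float = 0.5
    dt_ms: float = 0.1
    mixture_weights: List[float] = field(default_factory=lambda: list(p.MIXTURE_EGFP_NEG.weights))
    mixture_means: List[float] = field(default_factory=lambda: list(p.MIXTURE_EGFP_NEG.means))
    mixture_sds: List[float] = field(default_factory=lambda: list(p.MIXTURE_EGFP_NEG.sds))
    # mixture-fit block
    n_components: int = 3
    n_restarts: int = 10
    # markov-population block
    n_sweeps_per_class: int = 100
    n_channels: int = 20
    mc_duration_ms: float = 1500.0
    mc_noise_sd_open_frac: float = 0.03
    fast_target_ms: float = p.FAST_DECAY_TARGET_MS
    slow_target_ms: float = p.SLOW_DECAY_TARGET_MS

    def mixture_spec(self) -> MixtureSpec:
        return MixtureSpec(tuple(self.mixture_weights), tuple(self.mixture_means),
                           tuple(self.mixture_sds))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        names = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - names
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def _fit_event_taus(trace, events, next_onset_limit_ms: float = 1500.0):
    """Monoexponential decay constants for non-compound detected events."""
    x = -trace.samples if trace.samples.min() < -trace.samples.max() else trace.samples
    taus = []
    kept = []
    peaks = [ev.peak_time for ev in events]
    for i, ev in enumerate(events):
        if ev.compound:
            continue
        i_pk = trace.index_at(ev.peak_time)
        t_stop = ev.peak_time + next_onset_limit_ms
        if i + 1 < len(events):
            t_stop = min(t_stop, events[i + 1].onset)
        i_stop = trace.index_at(t_stop)
        if i_stop - i_pk < 20:
            continue
        seg = x[i_pk:i_stop]
        try:
            fit = fit_exponential(seg, n=1, dt=trace.dt)
        except Exception:
            log.debug("decay fit failed for event at %.1f ms", ev.onset)
            continue
        if "tau_at_bound" in fit.flags:
            continue
        ev.decay_fit = fit
        taus.append(fit.components[0][1])
        kept.append(ev)
    return np.asarray(taus), kept


def _match_truth(events, truth, tol_ms: float = 10.0):
    """Greedy onset matching of detections to ground truth."""
    used = np.zeros(len(truth), dtype=bool)
    onsets = truth["onset_ms"].to_numpy()
    tp = 0
    for ev in events:
        d = np.abs(onsets - ev.onset)
        d[used] = np.inf
        j = int(np.argmin(d)) if len(d) else -1
        if j >= 0 and d[j] <= tol_ms:
            used[j] = True
            tp += 1
    fp = len(events) - tp
    fn = len(truth) - tp
    return tp, fp, fn


def run_recovery_experiment(config: RunConfig) -> Dict:
    """Mini train -> detection -> decay fits -> mixture decomposition.

    Returns a machine-readable report: detection recall/precision, the
    recovered mixture parameters, and their relative errors against the
    generative spec.  Identical configs give identical reports.
    """
    spec = MiniTrainSpec(
        duration=config.duration_s,
        event_rate=config.event_rate_hz,
        amplitude_mean=config.amplitude_mean_pa,
        amplitude_sd=config.amplitude_sd_pa,
        decay_mixture=config.mixture_spec(),
        rise_tau=config.rise_tau_ms,
        noise_sd=config.noise_sd_pa,
        dt=config.dt_ms,
        seed=child_seed(config.seed, "synth"),
    )
    trace, truth = generate_mini_train(spec)
    events = detect_events(trace, polarity="inward")
    tp, fp, fn = _match_truth(events, truth)
    taus, kept = _fit_event_taus(trace, events)

    report: Dict = {
        "n_true": int(len(truth)),
        "n_detected": int(len(events)),
        "recall": tp / max(1, len(truth)),
        "precision": tp / max(1, len(events)),
        "n_fitted": int(taus.size),
    }
    gen = config.mixture_spec()
    n_params = 3 * config.n_components - 1
    if taus.size > 10 * n_params:
        model = fit_mixture_cdf(taus, config.n_components,
                                seed=child_seed(config.seed, "mixture"),
                                n_restarts=config.n_restarts)
        report["recovered_weights"] = model.weights.tolist()
        report["recovered_means"] = model.means.tolist()
        report["recovered_sds"] = model.sds.tolist()
        report["flags"] = model.flags
        if model.n == gen.n:
            report["mean_rel_errors"] = [
                abs(m - g) / g for m, g in zip(model.means, gen.means)
            ]
            report["weight_abs_errors"] = [
                abs(w - g) for w, g in zip(model.weights, gen.weights)
            ]
    else:
        report["recovered_weights"] = None
        report["note"] = "too few fitted events for the requested mixture order"
    return report


def run_markov_population(config: RunConfig) -> Dict:
    """Stochastic mIPSC populations from fast/slow calibrated schemes.

    Calibrates the default gating scheme to the fast target (all rates) and
    re-calibrates only binding/unbinding to the slow target, simulates
    ``n_sweeps_per_class`` miniature events from stochastic opening of
    ``n_channels`` channels each, adds band-limited noise, fits each decay
    with a single exponential, and reports the per-class decay-constant
    populations plus a pooled histogram table (20-ms bins).
    """
    base = default_scheme()
    fast = calibrate_scheme(base, config.fast_target_ms, vary="all")
    slow = calibrate_scheme(fast, config.slow_target_ms, vary="binding_unbinding_only")
    pulse = AgonistPulse()
    rng = np.random.default_rng(child_seed(config.seed, "markov"))

    out: Dict = {"fast_target_ms": config.fast_target_ms,
                 "slow_target_ms": config.slow_target_ms}
    for name, scheme in (("fast", fast), ("slow", slow)):
        # every sweep is fitted from the ensemble (macroscopic) peak time:
        # picking each sweep's own noisy argmax selects momentary spikes of
        # the few-channel open count and biases the fitted decays fast
        macro = simulate_macroscopic(scheme, pulse, duration=config.mc_duration_ms, dt=0.1)
        i_pk = int(np.argmax(np.abs(macro.trace.samples)))
        taus = []
        for _ in range(config.n_sweeps_per_class):
            tr = simulate_channels_mc(scheme, config.n_channels, pulse,
                                      duration=config.mc_duration_ms, dt=0.1,
                                      seed=rng)
            noise_sd = config.mc_noise_sd_open_frac * abs(scheme.unitary_current) * config.n_channels
            tr = add_noise(tr, noise_sd, seed=rng)
            sign = -1.0 if scheme.unitary_current < 0 else 1.0
            y = sign * tr.samples
            if y[i_pk:].max() <= 0 or y.size - i_pk < 20:
                continue
            try:
                fit = fit_exponential(y[i_pk:], n=1, dt=tr.dt)
            except Exception:
                continue
            if "tau_at_bound" in fit.flags:
                continue
            taus.append(fit.components[0][1])
        taus = np.asarray(taus)
        out[f"{name}_taus_ms"] = taus.tolist()
        out[f"{name}_median_ms"] = float(np.median(taus)) if taus.size else None
    all_taus = np.asarray(out["fast_taus_ms"] + out["slow_taus_ms"])
    if all_taus.size:
        hi = 20.0 * np.ceil(all_taus.max() / 20.0)
        edges = np.arange(0.0, hi + 20.0, 20.0)
        counts, _ = np.histogram(all_taus, bins=edges)
        out["histogram"] = {"bin_edges_ms": edges.tolist(), "counts": counts.tolist()}
    return out
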