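"""Generative model of odor ON/OFF population dynamics.

The generator is phenomenological: it reproduces the population statistics
the analyses assume -- nearly mutually exclusive ON and OFF ensembles whose
patterns are anticorrelated, OFF activity decaying over tens of seconds,
history-dependent suppression of sequentially presented odors, and
odor-specific hysteresis that accumulates over repeated presentations --
without modelling antennal-lobe or olfactory-bulb biophysics.

Each odor ``o`` has a sparse non-negative ON pattern ``a_o``, an OFF pattern
``c_o = (1 - gamma) * g_o + gamma * complement(a_o)`` (``g_o`` independent,
``complement`` loading the units least driven by ``a_o``), and a hysteresis
pattern ``a'_o``.  The firing rate of unit ``u`` at time ``t`` is

    rate_u(t) = max(0, b_u
        + on_amp  * [a_ou - gamma * c_ou]               during odor
        + off_amp * [c_ou - gamma * a_ou] * D(t)        after odor offset
        + h_o * a'_ou * H(t))                           hysteresis

with ``D`` an exponential decay with constant ``tau_off_s`` and ``H`` a slow
decay with constant ``tau_hysteresis_s``; ``h_o`` is updated at every
presentation of ``o`` (h <- lambda * h + eta).  ``gamma`` (inversion
strength) is the single knob controlling ON/OFF anticorrelation: at 0 the
ON and OFF ensembles are independent and nothing is cross-suppressed, at 1
the OFF pattern is the complement of the ON pattern and active units are
fully suppressed in the opposite period.  In sequential trials the first
odor's post-offset terms superpose on the second odor's ON response, which
is what suppresses shared ensembles and enhances contrast.

Rates are rendered as spike times (inhomogeneous Poisson via thinning) or as
GCaMP-like fluorescence (rate convolved with a difference-of-exponentials
kernel, scaled onto a per-ROI F0, plus Gaussian noise).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .session import RecordingSession, TrialRecord

__all__ = [
    "SyntheticConfig",
    "OdorPatterns",
    "TrialPlan",
    "make_patterns",
    "simulate_rates",
    "sample_spikes",
    "render_calcium",
    "generate_session",
    "locust_like",
    "mouse_like",
]

BLANK = "blank"


@dataclass
class SyntheticConfig:
    """Full parameterization of the generative ON/OFF model.

    Rates are in Hz, times in seconds.  Defaults are locust-like: 66 units,
    4 s odor pulses in blocks of ten trials with 60 s intertrial intervals.
    """

    n_units: int = 66
    odors: tuple[str, ...] = ("bza", "vny", "oct", "nen")
    paradigm: str = "solitary_blocks"  # | sequential_pairs | random_order
    trials_per_block: int = 10
    iti_s: float = 60.0  # odor offset to next odor onset
    block_gap_s: float = 900.0  # no-odor interval between blocks
    on_s: float = 4.0
    gap_s: float = 0.5  # within-pair gap, sequential paradigm
    pre_s: float = 2.0  # recorded pre-odor baseline per trial
    baseline_rate: float = 6.0  # mean spontaneous rate (per-unit Gamma draw)
    on_amplitude: float = 50.0
    off_amplitude: float = 25.0
    inversion_gamma: float = 0.5
    tau_off_s: float = 8.0
    hysteresis_lambda: float = 0.85
    hysteresis_eta: float = 1.5
    tau_hysteresis_s: float = 120.0
    noise: float = 0.5  # per-trial per-unit rate jitter SD (Hz)
    frac_active: float = 0.2  # sparseness of each pattern
    shared_rho: float = 0.4  # cross-odor shared weight in ON patterns
    sequential_carryover: bool = True
    reference_odor: str | None = None  # sequential paradigm; default last odor
    n_random_trials: int = 480
    include_blank: bool = True  # random paradigm: mineral-oil trials
    modality: str = "spikes"  # | traces
    sample_rate_hz: float = 16.0
    tau_rise_s: float = 0.08
    tau_decay_s: float = 0.5
    dff_gain: float = 0.02  # dF/F per Hz at kernel peak
    trace_noise_sd: float = 4.0  # fluorescence units per frame (F0 ~ 100)
    seed: int = 0

    def validate(self) -> None:
        if self.n_units < 4:
            raise ValueError("n_units must be >= 4")
        if not 0 <= self.inversion_gamma <= 1:
            raise ValueError("inversion_gamma must lie in [0, 1]")
        if self.tau_off_s <= 0:
            raise ValueError("tau_off_s must be positive")
        if not 0 <= self.hysteresis_lambda < 1:
            raise ValueError("hysteresis_lambda must lie in [0, 1)")
        for name in ("baseline_rate", "on_amplitude", "off_amplitude",
                     "hysteresis_eta", "noise", "on_s", "iti_s"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.modality == "traces" and self.tau_rise_s >= self.tau_decay_s:
            raise ValueError("tau_rise_s must be < tau_decay_s")
        if self.paradigm not in ("solitary_blocks", "sequential_pairs",
                                 "random_order"):
            raise ValueError(f"unknown paradigm {self.paradigm!r}")
        if self.pre_s >= self.iti_s:
            raise ValueError("pre_s must be shorter than iti_s")


def locust_like(**overrides) -> SyntheticConfig:
    """Spike session emulating locust AL recordings (66 PNs, 4 s pulses,
    blocks of ten trials, 60 s ITIs)."""
    return SyntheticConfig(**overrides)


def mouse_like(**overrides) -> SyntheticConfig:
    """Calcium session emulating mouse OB glomerular imaging (5 s pulses,
    55 s ITIs, ~16 Hz frame rate, GCaMP6f-like kinetics)."""
    defaults = dict(
        n_units=200,
        odors=("ace", "msc", "eug", "als"),
        on_s=5.0,
        iti_s=55.0,
        gap_s=1.0,
        tau_off_s=10.0,
        inversion_gamma=0.8,
        trace_noise_sd=16.0,
        modality="traces",
    )
    defaults.update(overrides)
    return SyntheticConfig(**defaults)


@dataclass
class OdorPatterns:
    """Unit-normalized ON (a), OFF (c) and hysteresis (h) weight vectors."""

    a: np.ndarray
    c: np.ndarray
    h: np.ndarray


def _sparse_pattern(n_units: int, frac_active: float,
                    rng: np.random.Generator) -> np.ndarray:
    n_active = max(2, int(round(frac_active * n_units)))
    idx = rng.choice(n_units, size=n_active, replace=False)
    w = np.zeros(n_units)
    w[idx] = np.abs(rng.standard_normal(n_active))
    return w / np.linalg.norm(w)


def _complement_pattern(a: np.ndarray, frac_active: float,
                        rng: np.random.Generator) -> np.ndarray:
    """Sparse pattern loading the units least driven by ``a``."""
    n_units = a.size
    n_active = max(2, int(round(frac_active * n_units)))
    order = np.argsort(a + 1e-12 * rng.random(n_units))  # random tie-break
    idx = order[:n_active]
    w = np.zeros(n_units)
    w[idx] = np.abs(rng.standard_normal(n_active))
    return w / np.linalg.norm(w)


def make_patterns(config: SyntheticConfig,
                  rng: np.random.Generator) -> dict[str, OdorPatterns]:
    """Draw per-odor ON/OFF/hysteresis patterns.

    ``c_o`` interpolates between an independent pattern (gamma = 0) and the
    complement of ``a_o`` (gamma = 1); at gamma = 1 the centered patterns are
    anticorrelated by construction.
    """
    gamma = config.inversion_gamma
    rho = config.shared_rho
    # odors recruit partially overlapping ON ensembles: each a_o mixes an
    # odor-specific pattern with one session-wide shared pattern, emulating
    # the modest cross-odor ON correlations seen in real panels
    shared = _sparse_pattern(config.n_units, config.frac_active, rng)
    out: dict[str, OdorPatterns] = {}
    for odor in config.odors:
        own = _sparse_pattern(config.n_units, config.frac_active, rng)
        a = (1 - rho) * own + rho * shared
        a = a / np.linalg.norm(a)
        g = _sparse_pattern(config.n_units, config.frac_active, rng)
        comp = _complement_pattern(a, config.frac_active, rng)
        c = (1 - gamma) * g + gamma * comp
        c = c / np.linalg.norm(c)
        h = _sparse_pattern(config.n_units, config.frac_active, rng)
        out[odor] = OdorPatterns(a=a, c=c, h=h)
    if config.paradigm == "random_order" and config.include_blank:
        z = np.zeros(config.n_units)
        out[BLANK] = OdorPatterns(a=z, c=z, h=z)
    return out


@dataclass
class TrialPlan:
    """One trial's rate model: base rates plus weighted time profiles.

    ``terms`` is a list of (weights, profile) with ``weights`` an
    (n_units,) coefficient vector and ``profile`` a vectorized function of
    absolute session time; the rate matrix at times ``t`` is
    ``max(0, base + sum_k profile_k(t)[:, None] * weights_k)``.
    """

    trial_id: str
    odor: str
    t_start_s: float
    t_end_s: float
    odor_sequence: list[tuple[str, float, float]]
    base: np.ndarray
    terms: list[tuple[np.ndarray, Callable[[np.ndarray], np.ndarray]]]
    block_id: int = 0
    trial_index_in_block: int = 0
    hysteresis_state: dict[str, float] = field(default_factory=dict)

    def rate(self, times: np.ndarray) -> np.ndarray:
        """(n_times, n_units) firing rates, rectified at zero."""
        times = np.asarray(times, float)
        r = np.broadcast_to(self.base, (times.size, self.base.size)).copy()
        for w, profile in self.terms:
            r += profile(times)[:, None] * w[None, :]
        return np.maximum(r, 0.0)

    def rate_bound(self) -> np.ndarray:
        """Per-unit upper bound on the rate (for Poisson thinning)."""
        bound = self.base.copy()
        for w, _ in self.terms:
            bound += np.maximum(w, 0.0)
        return bound


def _box(t0: float, t1: float):
    return lambda t: ((t >= t0) & (t < t1)).astype(float)


def _decay(t0: float, tau: float, t1: float = np.inf):
    return lambda t: np.exp(-(t - t0) / tau) * ((t >= t0) & (t < t1))


@dataclass
class _Schedule:
    """Odor sequence of one trial plus bookkeeping labels."""

    trial_id: str
    odor: str
    onset_s: float  # first odor onset, session clock
    events: list[tuple[str, float, float]]  # (odor, onset, offset)
    block_id: int
    trial_index_in_block: int


def _build_schedule(config: SyntheticConfig,
                    rng: np.random.Generator) -> list[_Schedule]:
    sched: list[_Schedule] = []
    t = config.pre_s
    counter = 0

    def solitary_block(odor: str, block_id: int, start: float) -> float:
        nonlocal counter
        tt = start
        for k in range(config.trials_per_block):
            onset = tt
            offset = onset + config.on_s
            sched.append(_Schedule(f"t{counter:04d}", odor, onset,
                                   [(odor, onset, offset)], block_id, k))
            counter += 1
            tt = offset + config.iti_s
        return tt

    if config.paradigm == "solitary_blocks":
        for b, odor in enumerate(config.odors):
            t = solitary_block(odor, b, t) + config.block_gap_s
    elif config.paradigm == "sequential_pairs":
        ref = config.reference_odor or config.odors[-1]
        contexts = [o for o in config.odors if o != ref]
        block = 0
        for odor in config.odors:
            t = solitary_block(odor, block, t) + config.block_gap_s
            block += 1
        for ctx in contexts:
            for k in range(config.trials_per_block):
                onset_a = t
                offset_a = onset_a + config.on_s
                onset_b = offset_a + config.gap_s
                offset_b = onset_b + config.on_s
                sched.append(_Schedule(
                    f"t{counter:04d}", f"({ctx}){ref}", onset_a,
                    [(ctx, onset_a, offset_a), (ref, onset_b, offset_b)],
                    block, k))
                counter += 1
                t = offset_b + config.iti_s
            t += config.block_gap_s
            block += 1
    else:  # random_order
        labels = list(config.odors) + ([BLANK] if config.include_blank else [])
        draws = rng.integers(0, len(labels), size=config.n_random_trials)
        for k, di in enumerate(draws):
            odor = labels[di]
            onset = t
            offset = onset + config.on_s
            sched.append(_Schedule(f"t{counter:04d}", odor, onset,
                                   [(odor, onset, offset)], 0, k))
            counter += 1
            t = offset + config.iti_s
    return sched


def simulate_rates(
    config: SyntheticConfig,
    patterns: dict[str, OdorPatterns],
    schedule: list[_Schedule],
    rng: np.random.Generator,
) -> list[TrialPlan]:
    """Turn a trial schedule into per-trial rate models.

    Maintains the per-odor hysteresis state across the whole session
    (h <- lambda * h + eta at each presentation, decaying between
    presentations with ``tau_hysteresis_s``).
    """
    base_rates = rng.gamma(shape=2.0, scale=config.baseline_rate / 2.0,
                           size=config.n_units)
    gamma = config.inversion_gamma
    # (value at last update, time of last update) per odor
    hstate: dict[str, tuple[float, float]] = {o: (0.0, 0.0) for o in patterns}
    plans: list[TrialPlan] = []
    for sc in schedule:
        t_start = sc.onset_s - config.pre_s
        t_end = sc.events[-1][2] + config.iti_s - config.pre_s
        jitter = rng.normal(0.0, config.noise, size=config.n_units)
        terms: list[tuple[np.ndarray, Callable]] = []
        for j, (odor, onset, offset) in enumerate(sc.events):
            p = patterns[odor]
            w_on = config.on_amplitude * (p.a - gamma * p.c)
            w_off = config.off_amplitude * (p.c - gamma * p.a)
            terms.append((w_on, _box(onset, offset)))
            off_until = np.inf
            if not config.sequential_carryover and j + 1 < len(sc.events):
                off_until = sc.events[j + 1][1]
            terms.append((w_off, _decay(offset, config.tau_off_s, off_until)))
        # hysteresis is odor-specific persistent post-odor activity: the
        # state carried in from previous presentations runs across the whole
        # trial, and each presentation in this trial bumps it at its offset
        snapshot: dict[str, float] = {}
        for odor, p in patterns.items():
            h_val, t_upd = hstate[odor]
            if h_val > 0:
                seg_stops = [offset for o, _, offset in sc.events if o == odor]
                t_stop = seg_stops[0] if seg_stops else np.inf
                # active from the update itself so trace rendering can look
                # slightly before the record start without a discontinuity
                terms.append((h_val * p.h,
                              _decay_from(t_upd, config.tau_hysteresis_s,
                                          t_upd, t_stop)))
            snapshot[odor] = h_val * np.exp(
                -(sc.onset_s - t_upd) / config.tau_hysteresis_s) if h_val else 0.0
        for odor, _, offset in sc.events:
            h_val, t_upd = hstate[odor]
            carried = h_val * np.exp(-(offset - t_upd) / config.tau_hysteresis_s)
            h_new = config.hysteresis_lambda * carried + config.hysteresis_eta
            hstate[odor] = (h_new, offset)
            if h_new > 0:
                terms.append((h_new * patterns[odor].h,
                              _decay(offset, config.tau_hysteresis_s)))
        plans.append(TrialPlan(
            trial_id=sc.trial_id, odor=sc.odor, t_start_s=t_start,
            t_end_s=t_end, odor_sequence=list(sc.events),
            base=np.maximum(base_rates + jitter, 0.0), terms=terms,
            block_id=sc.block_id, trial_index_in_block=sc.trial_index_in_block,
            hysteresis_state=snapshot))
    return plans


def _decay_from(t_ref: float, tau: float, t_from: float, t_to: float):
    """Exponential decay anchored at t_ref, active only on [t_from, t_to)."""
    return lambda t: np.exp(-(t - t_ref) / tau) * ((t >= t_from) & (t < t_to))


def sample_spikes(plans: list[TrialPlan],
                  rng: np.random.Generator) -> list[TrialRecord]:
    """Render rate models as spike times (inhomogeneous Poisson, thinning).

    Candidates are drawn per unit from a homogeneous process at that unit's
    rate bound and accepted with probability rate(t)/bound.
    """
    records = []
    for plan in plans:
        duration = plan.t_end_s - plan.t_start_s
        bound = plan.rate_bound()
        n_cand = rng.poisson(bound * duration)
        total = int(n_cand.sum())
        unit_idx = np.repeat(np.arange(bound.size), n_cand)
        times = plan.t_start_s + rng.random(total) * duration
        # evaluate each profile once over all candidates, then pick the
        # candidate's own unit weight
        rates = plan.base[unit_idx].astype(float)
        for w, profile in plan.terms:
            rates += profile(times) * w[unit_idx]
        np.maximum(rates, 0.0, out=rates)
        accept = rng.random(total) * bound[unit_idx] < rates
        activity = {}
        for u in range(bound.size):
            sel = accept & (unit_idx == u)
            activity[f"u{u:03d}"] = np.sort(times[sel])
        records.append(_to_record(plan, activity))
    return records


def render_calcium(plans: list[TrialPlan], config: SyntheticConfig,
                   rng: np.random.Generator,
                   f0: np.ndarray | None = None) -> list[TrialRecord]:
    """Render rate models as GCaMP-like fluorescence traces.

    F(t) = F0 * (1 + gain * (rate (*) kappa)(t)) + Gaussian noise, with
    ``kappa`` a peak-normalized difference of exponentials
    (tau_rise_s, tau_decay_s), computed on a 4x-oversampled grid and
    subsampled to the session frame rate.
    """
    from scipy.signal import fftconvolve

    if config.tau_rise_s >= config.tau_decay_s:
        raise ValueError("tau_rise_s must be < tau_decay_s")
    n_units = plans[0].base.size
    if f0 is None:
        f0 = rng.uniform(80.0, 120.0, size=n_units)
    oversample = 4
    dt = 1.0 / (config.sample_rate_hz * oversample)
    kern_len = int(np.ceil(6 * config.tau_decay_s / dt))
    tk = dt * np.arange(kern_len)
    kappa = np.exp(-tk / config.tau_decay_s) - np.exp(-tk / config.tau_rise_s)
    kappa /= kappa.max()
    records = []
    for plan in plans:
        n_frames = int(np.floor((plan.t_end_s - plan.t_start_s)
                                * config.sample_rate_hz))
        n_fine = n_frames * oversample
        # include kern_len samples of pre-trial history so the first frames
        # see a fully covered kernel (no onset edge transient)
        tt = plan.t_start_s - kern_len * dt + dt * np.arange(n_fine + kern_len)
        rates = plan.rate(tt)
        conv = fftconvolve(rates, kappa[:, None] * (dt / config.tau_decay_s),
                           axes=0)[kern_len:kern_len + n_fine]
        frames = conv[::oversample][:n_frames]
        F = f0[None, :] * (1.0 + config.dff_gain * frames)
        F = F + rng.normal(0.0, config.trace_noise_sd, size=F.shape)
        activity = {f"u{u:03d}": F[:, u].copy() for u in range(n_units)}
        records.append(_to_record(plan, activity))
    return records


def _to_record(plan: TrialPlan, activity: dict[str, np.ndarray]) -> TrialRecord:
    return TrialRecord(
        trial_id=plan.trial_id, odor=plan.odor, t_start_s=plan.t_start_s,
        t_end_s=plan.t_end_s, odor_sequence=list(plan.odor_sequence),
        activity=activity, block_id=plan.block_id,
        trial_index_in_block=plan.trial_index_in_block)


def generate_session(
    config: SyntheticConfig,
) -> tuple[RecordingSession, dict]:
    """Build a full session under the configured paradigm.

    Returns the session together with a ground-truth record (patterns,
    schedule, per-trial hysteresis states) for recovery tests.  One global
    seed fans out to independent substreams for patterns, schedule, rate
    jitter and spike/noise rendering.
    """
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    rng_pat, rng_sched, rng_rates, rng_render = (
        np.random.default_rng(s) for s in ss.spawn(4))
    patterns = make_patterns(config, rng_pat)
    schedule = _build_schedule(config, rng_sched)
    plans = simulate_rates(config, patterns, schedule, rng_rates)
    if config.modality == "spikes":
        trials = sample_spikes(plans, rng_render)
        session = RecordingSession("spikes",
                                   [f"u{u:03d}" for u in range(config.n_units)],
                                   trials, meta={"generator": "afterimage"})
    else:
        trials = render_calcium(plans, config, rng_render)
        session = RecordingSession("traces",
                                   [f"u{u:03d}" for u in range(config.n_units)],
                                   trials, sample_rate_hz=config.sample_rate_hz,
                                   meta={"generator": "afterimage"})
    session.validate()
    truth = {
        "patterns": patterns,
        "schedule": schedule,
        "plans": plans,
        "hysteresis_by_trial": {p.trial_id: p.hysteresis_state for p in plans},
        "config": config,
    }
    return session, truth
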