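"""Stochastic vesicle-release simulator for the larval NMJ.

The generative model mirrors the statistical structure quantal analysis
assumes. Each NMJ carries a readily releasable pool (RRP) of ``n_rrp``
vesicles. A nerve stimulus releases each available vesicle independently
with probability ``p``, so the release count is Binomial(``n_rrp``, ``p``)
and the mean evoked current is I = N * Pvr * q. The release probability
depends cooperatively on external calcium through a Hill function. Each
released vesicle contributes a quantal current drawn from a Gamma
distribution with mean ``q_mean`` and coefficient of variation ``q_cv``
(strictly positive and right-skewed, like measured mini distributions);
measured amplitudes additionally carry Gaussian instrumentation noise.
Spontaneous miniature events (minis) occur as a Poisson process and sample
the same quantal distribution. Between-NMJ heterogeneity is a lognormal
multiplier (CV ``nmj_cv``) applied to ``n_rrp`` and ``q_mean``.

High-frequency trains deplete the pool; between stimuli a fraction
``replenish_frac`` of the deficit is refilled. Rendered sweeps convolve the
event train with a biexponential quantal waveform, add Gaussian baseline
noise and apply the 1 kHz low-pass acquisition filter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import signal

from .errors import ValidationError
from .qtrc import EVENT_COLUMNS, TraceSweep

__all__ = [
    "GroundTruth",
    "Protocol",
    "QuantalKernel",
    "AmplitudeDataset",
    "TrainSimulation",
    "p_release",
    "calibrate_ca_half",
    "simulate_cohort",
    "simulate_train",
    "render_sweep",
]


@dataclass(frozen=True)
class GroundTruth:
    """Simulator ground truth for one genotype.

    Parameters
    ----------
    n_rrp
        Readily releasable pool size N (vesicles).
    q_mean, q_cv
        Mean and coefficient of variation of the quantal amplitude q (nA).
    p_max, ca_half, hill
        Hill parameterization of the calcium dependence of the vesicular
        release probability Pvr: maximal probability, half-activation
        calcium (mM) and cooperativity.
    mini_rate
        Spontaneous event rate (Hz).
    noise_sd
        Gaussian baseline/measurement noise s.d. (nA).
    replenish_frac
        Fraction of the pool deficit refilled per interstimulus interval
        during high-frequency trains.
    nmj_cv
        CV of the lognormal between-NMJ multiplier on n_rrp and q_mean.
    """

    n_rrp: int = 300
    q_mean: float = 0.8
    q_cv: float = 0.3
    p_max: float = 0.7
    ca_half: float = 1.5
    hill: float = 3.0
    mini_rate: float = 2.0
    noise_sd: float = 0.1
    replenish_frac: float = 0.05
    nmj_cv: float = 0.2

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not np.isfinite(v):
                raise ValidationError(f"{f.name} must be finite, got {v!r}")
        if self.n_rrp < 1:
            raise ValidationError("n_rrp must be >= 1")
        if self.q_mean <= 0:
            raise ValidationError("q_mean must be positive")
        if not 0 <= self.q_cv < 1:
            raise ValidationError("q_cv must be in [0, 1)")
        if not 0 < self.p_max <= 1:
            raise ValidationError("p_max must be in (0, 1]")
        if self.ca_half <= 0 or self.hill <= 0:
            raise ValidationError("ca_half and hill must be positive")
        if self.mini_rate < 0 or self.noise_sd < 0:
            raise ValidationError("mini_rate and noise_sd must be non-negative")
        if not 0 <= self.replenish_frac <= 1:
            raise ValidationError("replenish_frac must be in [0, 1]")
        if self.nmj_cv < 0:
            raise ValidationError("nmj_cv must be non-negative")


@dataclass(frozen=True)
class Protocol:
    """A stimulation/recording protocol.

    Defaults mirror standard practice: quantal-content recordings at 0.2 Hz
    with >=20 stimuli; failure analysis at 1 Hz with 300 stimuli in 0.25 mM
    calcium; RRP trains at 60 Hz with 30 stimuli in 3 mM calcium.
    """

    kind: str
    ca_mm: float = 0.5
    stim_freq_hz: float = 0.2
    n_stim: int = 20
    duration_s: float = 60.0

    KINDS = ("low_freq_evoked", "failure", "train", "spontaneous")

    def __post_init__(self) -> None:
        if self.kind not in self.KINDS:
            raise ValidationError(f"unknown protocol kind {self.kind!r}")
        if self.kind != "spontaneous":
            if not self.ca_mm > 0:
                raise ValidationError("evoked protocols require ca_mm > 0")
            if self.n_stim < 1:
                raise ValidationError("evoked protocols require n_stim >= 1")
            if not self.stim_freq_hz > 0:
                raise ValidationError("stim_freq_hz must be positive")
        elif not self.duration_s > 0:
            raise ValidationError("spontaneous protocols require duration_s > 0")

    @classmethod
    def low_freq_evoked(cls, ca_mm: float = 0.5, n_stim: int = 20) -> "Protocol":
        return cls(kind="low_freq_evoked", ca_mm=ca_mm, stim_freq_hz=0.2, n_stim=n_stim)

    @classmethod
    def failure(cls, ca_mm: float = 0.25, n_stim: int = 300) -> "Protocol":
        return cls(kind="failure", ca_mm=ca_mm, stim_freq_hz=1.0, n_stim=n_stim)

    @classmethod
    def train(cls, ca_mm: float = 3.0, n_stim: int = 30) -> "Protocol":
        return cls(kind="train", ca_mm=ca_mm, stim_freq_hz=60.0, n_stim=n_stim)

    @classmethod
    def spontaneous(cls, duration_s: float = 60.0) -> "Protocol":
        return cls(kind="spontaneous", ca_mm=0.5, duration_s=duration_s)

    @property
    def stim_times_s(self) -> np.ndarray:
        if self.kind == "spontaneous":
            return np.array([])
        return np.arange(self.n_stim) / self.stim_freq_hz


@dataclass(frozen=True)
class QuantalKernel:
    """Biexponential unitary-event time course for trace rendering.

    Kinetics default to typical larval-muscle mEJC shape: ~1 ms rise,
    ~6 ms decay, 1.5 ms stimulus-to-response latency with small jitter.
    """

    tau_rise_ms: float = 1.0
    tau_decay_ms: float = 6.0
    latency_ms: float = 1.5
    jitter_ms: float = 0.2

    def __post_init__(self) -> None:
        if not 0 < self.tau_rise_ms < self.tau_decay_ms:
            raise ValidationError("need 0 < tau_rise_ms < tau_decay_ms")
        if self.jitter_ms < 0 or self.latency_ms < 0:
            raise ValidationError("latency_ms and jitter_ms must be non-negative")


@dataclass
class AmplitudeDataset:
    """Simulated amplitude-level recordings for a cohort of NMJs.

    ``events`` uses the shared amplitude-table columns. ``nmj_meta`` holds
    per-NMJ metadata (holding current, seed, and the per-NMJ ground truth —
    an oracle channel never read by estimators). ``oracle_counts`` holds the
    true per-stimulus release counts, likewise estimator-hidden.
    """

    events: pd.DataFrame
    nmj_meta: pd.DataFrame
    oracle_counts: pd.DataFrame

    def for_nmj(self, nmj_id: str) -> pd.DataFrame:
        return self.events[self.events["nmj_id"] == nmj_id]

    @staticmethod
    def concat(datasets: Sequence["AmplitudeDataset"]) -> "AmplitudeDataset":
        return AmplitudeDataset(
            events=pd.concat([d.events for d in datasets], ignore_index=True),
            nmj_meta=pd.concat([d.nmj_meta for d in datasets], ignore_index=True),
            oracle_counts=pd.concat([d.oracle_counts for d in datasets], ignore_index=True),
        )


@dataclass
class TrainSimulation:
    """Outcome of one 60 Hz depletion train."""

    release_counts: np.ndarray
    amplitudes_na: np.ndarray
    pool_before: np.ndarray
    replenished: np.ndarray
    p: float
    mode: str


def p_release(ca_mm: float, truth: GroundTruth) -> float:
    """Vesicular release probability at external calcium ``ca_mm`` (mM).

    Hill function p_max * ca^h / (ca_half^h + ca^h): monotone in calcium,
    zero at zero calcium, saturating below ``p_max``.
    """
    ca = float(ca_mm)
    if not np.isfinite(ca) or ca < 0:
        raise ValidationError(f"ca_mm must be a non-negative number, got {ca_mm!r}")
    if ca == 0.0:
        return 0.0
    c = (ca / truth.ca_half) ** truth.hill
    return truth.p_max * c / (1.0 + c)


def calibrate_ca_half(truth: GroundTruth, ca_mm: float, p_target: float) -> GroundTruth:
    """Return a copy of ``truth`` whose ``ca_half`` makes
    ``p_release(ca_mm) == p_target`` (useful to pin N*p in a protocol)."""
    if not 0 < p_target < truth.p_max:
        raise ValidationError("p_target must lie in (0, p_max)")
    c = p_target / (truth.p_max - p_target)
    return replace(truth, ca_half=ca_mm / c ** (1.0 / truth.hill))


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    if seed is None:
        raise ValidationError("a seed is required for reproducible simulation")
    return np.random.default_rng(seed)


def _nmj_multipliers(rng: np.random.Generator, cv: float, n: int) -> np.ndarray:
    """Lognormal multipliers with mean 1 and coefficient of variation cv."""
    if cv == 0:
        return np.ones(n)
    sigma2 = math.log1p(cv * cv)
    return rng.lognormal(mean=-sigma2 / 2.0, sigma=math.sqrt(sigma2), size=n)


def _quantal_sum(rng: np.random.Generator, counts: np.ndarray, q_mean: float, q_cv: float) -> np.ndarray:
    """Summed quantal current for each release count.

    A sum of k iid Gamma(shape, scale) variables is Gamma(k*shape, scale),
    so the per-stimulus sum is drawn in one shot.
    """
    counts = np.asarray(counts)
    if q_cv == 0:
        return counts * q_mean
    shape = 1.0 / (q_cv * q_cv)
    scale = q_mean * q_cv * q_cv
    out = np.zeros(counts.shape, dtype=float)
    nz = counts > 0
    if np.any(nz):
        out[nz] = rng.gamma(shape * counts[nz], scale)
    return out


def _quantal_draws(rng: np.random.Generator, n: int, q_mean: float, q_cv: float) -> np.ndarray:
    if q_cv == 0:
        return np.full(n, q_mean)
    shape = 1.0 / (q_cv * q_cv)
    return rng.gamma(shape, q_mean / shape, size=n)


def simulate_cohort(
    truth: GroundTruth,
    protocols: Protocol | Iterable[Protocol],
    n_nmjs: int,
    seed,
    genotype: str = "control",
) -> AmplitudeDataset:
    """Simulate ``n_nmjs`` NMJs of one genotype under one or more protocols.

    The per-NMJ lognormal multipliers on ``n_rrp`` and ``q_mean`` are drawn
    once per NMJ and shared across all protocols, as they would be across
    recordings from one physical junction. Identical ``seed`` reproduces the
    dataset bit-for-bit.
    """
    if n_nmjs < 1:
        raise ValidationError("n_nmjs must be >= 1")
    if isinstance(protocols, Protocol):
        protocols = [protocols]
    protocols = list(protocols)
    master = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    children = master.spawn(n_nmjs)

    event_frames: list[pd.DataFrame] = []
    meta_rows: list[dict] = []
    oracle_rows: list[pd.DataFrame] = []
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        nmj_id = f"{genotype}-{i:03d}"
        mult_n, mult_q = _nmj_multipliers(rng, truth.nmj_cv, 2)
        n_rrp_i = max(1, int(round(truth.n_rrp * mult_n)))
        q_mean_i = truth.q_mean * mult_q
        holding = abs(rng.normal(3.0, 1.5))
        meta_rows.append(
            dict(
                nmj_id=nmj_id,
                genotype=genotype,
                holding_current_na=holding,
                seed=int(child.generate_state(1)[0] % (2**31)),
                true_n_rrp=n_rrp_i,
                true_q_mean=q_mean_i,
            )
        )
        for proto in protocols:
            if proto.kind == "spontaneous":
                n_minis = rng.poisson(truth.mini_rate * proto.duration_s)
                times = np.sort(rng.uniform(0.0, proto.duration_s, size=n_minis))
                amps = _quantal_draws(rng, n_minis, q_mean_i, truth.q_cv)
                event_frames.append(
                    pd.DataFrame(
                        {
                            "nmj_id": nmj_id,
                            "genotype": genotype,
                            "protocol": proto.kind,
                            "ca_mm": proto.ca_mm,
                            "stim_index": -1,
                            "event_time_s": times,
                            "kind": "mejc",
                            "amplitude_na": amps,
                        }
                    )
                )
                continue
            if proto.kind == "train":
                sim = _simulate_train_for_nmj(
                    rng, proto, n_rrp_i, q_mean_i, truth, mode="stochastic", p=None
                )
                counts, amps = sim.release_counts, sim.amplitudes_na
            else:
                p = p_release(proto.ca_mm, truth)
                counts = rng.binomial(n_rrp_i, p, size=proto.n_stim)
                amps = _quantal_sum(rng, counts, q_mean_i, truth.q_cv)
                if truth.noise_sd > 0:
                    amps = amps + rng.normal(0.0, truth.noise_sd, size=proto.n_stim)
                amps = np.maximum(amps, 0.0)
            stim_idx = np.arange(proto.n_stim)
            event_frames.append(
                pd.DataFrame(
                    {
                        "nmj_id": nmj_id,
                        "genotype": genotype,
                        "protocol": proto.kind,
                        "ca_mm": proto.ca_mm,
                        "stim_index": stim_idx,
                        "event_time_s": proto.stim_times_s,
                        "kind": "ejc",
                        "amplitude_na": amps,
                    }
                )
            )
            oracle_rows.append(
                pd.DataFrame(
                    {
                        "nmj_id": nmj_id,
                        "protocol": proto.kind,
                        "ca_mm": proto.ca_mm,
                        "stim_index": stim_idx,
                        "n_released": counts,
                    }
                )
            )

    events = (
        pd.concat(event_frames, ignore_index=True)
        if event_frames
        else pd.DataFrame(columns=EVENT_COLUMNS)
    )
    oracle = (
        pd.concat(oracle_rows, ignore_index=True)
        if oracle_rows
        else pd.DataFrame(columns=["nmj_id", "protocol", "ca_mm", "stim_index", "n_released"])
    )
    return AmplitudeDataset(events=events, nmj_meta=pd.DataFrame(meta_rows), oracle_counts=oracle)


def _simulate_train_for_nmj(
    rng: np.random.Generator,
    protocol: Protocol,
    n_rrp: int,
    q_mean: float,
    truth: GroundTruth,
    mode: str,
    p: float | None,
) -> TrainSimulation:
    if p is None:
        p = p_release(protocol.ca_mm, truth)
    n_stim = protocol.n_stim
    pool = float(n_rrp)
    counts = np.zeros(n_stim)
    pools = np.zeros(n_stim)
    repl = np.zeros(n_stim)
    for t in range(n_stim):
        pools[t] = pool
        if mode == "expectation":
            released = pool * p
        else:
            released = float(rng.binomial(int(math.floor(pool)), p))
        counts[t] = released
        pool -= released
        if t < n_stim - 1:
            add = truth.replenish_frac * (n_rrp - pool)
            repl[t] = add
            pool = min(float(n_rrp), pool + add)
    if mode == "expectation":
        amps = counts * q_mean
    else:
        amps = _quantal_sum(rng, counts.astype(int), q_mean, truth.q_cv)
        if truth.noise_sd > 0:
            amps = amps + rng.normal(0.0, truth.noise_sd, size=n_stim)
        amps = np.maximum(amps, 0.0)
    return TrainSimulation(
        release_counts=counts,
        amplitudes_na=amps,
        pool_before=pools,
        replenished=repl,
        p=p,
        mode=mode,
    )


def simulate_train(
    truth: GroundTruth,
    protocol: Protocol,
    mode: str = "stochastic",
    seed=None,
    p: float | None = None,
) -> TrainSimulation:
    """Simulate one high-frequency depletion train.

    Pool recursion: the pool starts full at ``n_rrp``; each stimulus
    releases Binomial(available, p) vesicles (``available * p`` in
    expectation mode); between stimuli a fraction ``replenish_frac`` of the
    deficit is refilled. The pool never goes negative and never exceeds
    ``n_rrp``. ``p`` overrides the Hill-derived release probability.
    """
    if protocol.kind != "train":
        raise ValidationError("simulate_train requires a protocol of kind 'train'")
    if mode not in ("stochastic", "expectation"):
        raise ValidationError(f"unknown train mode {mode!r}")
    if p is not None and not 0 <= p <= 1:
        raise ValidationError("p override must lie in [0, 1]")
    rng = _rng(seed) if mode == "stochastic" else np.random.default_rng(0)
    return _simulate_train_for_nmj(rng, protocol, truth.n_rrp, truth.q_mean, truth, mode, p)


# ---------------------------------------------------------------------------
# Trace rendering


def lowpass_ba(sample_rate_hz: float, cutoff_hz: float = 1000.0):
    """4-pole Butterworth low-pass (applied forward only), the acquisition
    filter model."""
    return signal.butter(4, cutoff_hz, fs=sample_rate_hz)


def unit_waveform(kernel: QuantalKernel, sample_rate_hz: float) -> np.ndarray:
    """Unnormalized biexponential exp(-t/tau_d) - exp(-t/tau_r)."""
    tau_r = kernel.tau_rise_ms / 1000.0
    tau_d = kernel.tau_decay_ms / 1000.0
    t = np.arange(0.0, 10.0 * tau_d, 1.0 / sample_rate_hz)
    return np.exp(-t / tau_d) - np.exp(-t / tau_r)


def render_sweep(
    kernel: QuantalKernel,
    sample_rate_hz: float,
    duration_s: float,
    seed,
    stim_times_s: Sequence[float] = (),
    evoked_amplitudes_na: Sequence[float] = (),
    mini_times_s: Sequence[float] = (),
    mini_amplitudes_na: Sequence[float] = (),
    noise_sd_na: float = 0.0,
    lowpass_hz: float = 1000.0,
    meta: dict | None = None,
) -> TraceSweep:
    """Render events of one NMJ into a continuous current sweep.

    Each event contributes an inward (negative-going) biexponential
    transient scaled so that its low-pass-filtered peak magnitude equals the
    requested amplitude; evoked events start ``latency_ms`` (+/- Gaussian
    jitter) after their stimulus. Gaussian noise of s.d. ``noise_sd_na`` is
    added, then the whole trace passes the 1 kHz acquisition filter.
    """
    if sample_rate_hz < 5000:
        raise ValidationError("sample_rate_hz must be >= 5000 for faithful rendering")
    stim_times_s = np.asarray(stim_times_s, dtype=float)
    evoked_amps = np.asarray(evoked_amplitudes_na, dtype=float)
    mini_times = np.asarray(mini_times_s, dtype=float)
    mini_amps = np.asarray(mini_amplitudes_na, dtype=float)
    if stim_times_s.size != evoked_amps.size:
        raise ValidationError("stim_times_s and evoked_amplitudes_na must align")
    if mini_times.size != mini_amps.size:
        raise ValidationError("mini_times_s and mini_amplitudes_na must align")
    for times, label in ((stim_times_s, "stimulus"), (mini_times, "mini")):
        if times.size and (times.min() < 0 or times.max() >= duration_s):
            raise ValidationError(f"{label} times fall outside the sweep duration")

    rng = _rng(seed)
    n = int(round(duration_s * sample_rate_hz))
    b, a = lowpass_ba(sample_rate_hz, lowpass_hz)
    u = unit_waveform(kernel, sample_rate_hz)
    # calibration: the filter is linear, so scaling by the filtered unit peak
    # makes each event's filtered peak magnitude equal its amplitude.
    peak = np.abs(signal.lfilter(b, a, u)).max()
    trace = np.zeros(n)

    latency = kernel.latency_ms / 1000.0
    jitter = kernel.jitter_ms / 1000.0
    onsets = []
    amps = []
    for t0, amp in zip(stim_times_s, evoked_amps):
        if amp <= 0:
            continue
        dt = latency + (rng.normal(0.0, jitter) if jitter > 0 else 0.0)
        onsets.append(t0 + max(dt, 0.0))
        amps.append(amp)
    onsets.extend(mini_times.tolist())
    amps.extend(mini_amps.tolist())
    for t0, amp in zip(onsets, amps):
        i0 = int(round(t0 * sample_rate_hz))
        if i0 >= n:
            continue
        seg = u[: n - i0]
        trace[i0 : i0 + seg.size] -= (amp / peak) * seg
    if noise_sd_na > 0:
        trace = trace + rng.normal(0.0, noise_sd_na, size=n)
    trace = signal.lfilter(b, a, trace)
    full_meta = {"ca_mm": 0.5, "holding_current_na": 3.0}
    if meta:
        full_meta.update(meta)
    return TraceSweep(
        sample_rate_hz=sample_rate_hz,
        current_na=trace,
        stim_times_s=stim_times_s,
        meta=full_meta,
    )
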