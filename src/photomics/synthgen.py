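"""Seeded synthetic-data generators with known ground truth.

Every generator is a pure function of its parameters and seed (one
``numpy.random.default_rng`` per call, no global state), so downstream
stages can be tested without any external recordings or omics data.

Simulated photometry model
--------------------------
``control(t) = baseline_f * bleach_c(t) * (1 + artifact(t)) + noise``
``signal(t)  = baseline_f * bleach_s(t) * (1 + artifact(t)) * (1 + transients(t)) + noise``

The artifact is a low-pass-filtered Gaussian random walk shared by both
channels before channel-specific noise — the premise that makes isosbestic
correction work. Transients rise linearly over ``rise_time`` then decay as
a single exponential; overlapping transients sum additively.

Defaults (sampling rate 20 Hz, noise SD 1% of baseline) are package
choices, not measured values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy.signal import butter, filtfilt

from .errors import ParameterError
from .omics import AbundanceTable, InteractionNetwork
from .photometry import BoutAnnotation, PhotometryRecording

__all__ = [
    "PhotometrySimParams",
    "GroundTruthEvents",
    "OmicsSimParams",
    "simulate_photometry",
    "transient_waveform",
    "simulate_bouts",
    "simulate_abundance",
    "simulate_network",
]


@dataclass
class PhotometrySimParams:
    """Parameters of the dual-channel photometry simulator.

    Bleach taus may be ``math.inf`` (no bleaching). ``rise_time`` 0 means an
    instantaneous rise.
    """

    duration: float = 600.0  # s
    sampling_rate: float = 20.0  # Hz
    event_rate: float = 6.0  # events/min, Poisson intensity
    amplitude_mean: float = 0.05  # dff units
    amplitude_sd: float = 0.01
    decay_tau: float = 1.0  # s
    rise_time: float = 0.1  # s
    bleach_tau_signal: float = 1800.0  # s
    bleach_tau_control: float = 1800.0
    artifact_sd: float = 0.02  # relative amplitude of shared artifact
    artifact_cutoff_hz: float = 0.1  # low-pass cutoff of artifact process
    noise_sd: float = 1.0  # a.u., per channel
    baseline_f: float = 100.0  # a.u.
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("duration", "sampling_rate", "decay_tau", "baseline_f",
                     "bleach_tau_signal", "bleach_tau_control",
                     "artifact_cutoff_hz"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be > 0")
        for name in ("event_rate", "amplitude_sd", "artifact_sd", "noise_sd",
                     "rise_time"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")


@dataclass
class GroundTruthEvents:
    """Planted transients: strictly increasing onsets within the session."""

    onset_times: np.ndarray  # s, sorted
    amplitudes: np.ndarray  # dff units
    decay_tau: float  # s

    def __post_init__(self) -> None:
        self.onset_times = np.asarray(self.onset_times, dtype=float)
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        if len(self.onset_times) != len(self.amplitudes):
            raise ParameterError("onset_times and amplitudes length mismatch")
        if len(self.onset_times) > 1 and not np.all(
            np.diff(self.onset_times) > 0
        ):
            raise ParameterError("onset_times must be strictly increasing")

    @property
    def n_events(self) -> int:
        return len(self.onset_times)


@dataclass
class OmicsSimParams:
    """Two-group abundance-table simulator parameters.

    The planted-feature count is ``round(frac * n_features)``; planted
    features occupy the lowest feature indices (up before down).
    """

    n_features: int = 1000
    n_per_group: int = 3
    frac_up: float = 0.05
    frac_down: float = 0.05
    effect_fc: float = 2.0  # multiplicative, > 1
    noise_cv: float = 0.1  # CV of multiplicative log-normal noise
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_features < 1:
            raise ParameterError("n_features must be >= 1")
        if self.n_per_group < 2:
            raise ParameterError("n_per_group must be >= 2")
        if self.frac_up < 0 or self.frac_down < 0:
            raise ParameterError("fractions must be >= 0")
        if self.frac_up + self.frac_down > 1:
            raise ParameterError("frac_up + frac_down must be <= 1")
        if self.effect_fc <= 1:
            raise ParameterError("effect_fc must be > 1")
        if self.noise_cv < 0:
            raise ParameterError("noise_cv must be >= 0")


def transient_waveform(
    t: np.ndarray, events: GroundTruthEvents, rise_time: float = 0.0
) -> np.ndarray:
    """Sum of planted transient kernels evaluated on time axis ``t``.

    Each kernel rises linearly over ``rise_time`` to its amplitude, then
    decays as ``exp(-(t - t0 - rise_time) / decay_tau)``. Overlaps add.
    """
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    tau = events.decay_tau
    for t0, amp in zip(events.onset_times, events.amplitudes):
        rel = t - t0
        if rise_time > 0:
            rising = (rel >= 0) & (rel < rise_time)
            out[rising] += amp * rel[rising] / rise_time
            decaying = rel >= rise_time
            out[decaying] += amp * np.exp(-(rel[decaying] - rise_time) / tau)
        else:
            decaying = rel >= 0
            out[decaying] += amp * np.exp(-rel[decaying] / tau)
    return out


def _bleach(t: np.ndarray, tau: float) -> np.ndarray:
    if math.isinf(tau):
        return np.ones_like(t)
    return np.exp(-t / tau)


def _artifact(
    rng: np.random.Generator, n: int, fs: float, sd: float, cutoff: float
) -> np.ndarray:
    """Shared slow artifact: low-pass-filtered Gaussian walk, scaled to sd."""
    if sd == 0 or n < 16:
        return np.zeros(n)
    walk = np.cumsum(rng.standard_normal(n))
    wn = min(cutoff / (fs / 2.0), 0.99)
    b, a = butter(2, wn, btype="low")
    smooth = filtfilt(b, a, walk)
    smooth -= smooth.mean()
    s = smooth.std()
    return smooth * (sd / s) if s > 0 else np.zeros(n)


def simulate_photometry(
    params: PhotometrySimParams,
    events: GroundTruthEvents | None = None,
) -> tuple[PhotometryRecording, GroundTruthEvents]:
    """Simulate a dual-channel recording with known transient ground truth.

    Event onsets follow a homogeneous Poisson process at ``event_rate``
    (amplitudes Gaussian, clipped to a small positive floor) unless an
    explicit ``events`` ground truth is supplied, which is useful for
    planting transients at chosen times. Identical (params, seed) give
    bit-identical output.
    """
    rng = np.random.default_rng(params.seed)
    fs = params.sampling_rate
    n = int(round(params.duration * fs))
    if n < 2:
        raise ParameterError("duration * sampling_rate must give >= 2 samples")
    t = np.arange(n) / fs

    if events is None:
        lam = params.event_rate / 60.0 * params.duration
        k = int(rng.poisson(lam)) if lam > 0 else 0
        onsets = np.sort(rng.uniform(0.0, params.duration, size=k))
        # strictly increasing onsets: nudge exact ties apart
        for i in range(1, k):
            if onsets[i] <= onsets[i - 1]:
                onsets[i] = np.nextafter(onsets[i - 1], np.inf)
        amps = rng.normal(params.amplitude_mean, params.amplitude_sd, size=k)
        amps = np.clip(amps, 1e-4, None)
        events = GroundTruthEvents(onsets, amps, params.decay_tau)

    transients = transient_waveform(t, events, params.rise_time)
    artifact = _artifact(rng, n, fs, params.artifact_sd,
                         params.artifact_cutoff_hz)
    base = params.baseline_f
    control = base * _bleach(t, params.bleach_tau_control) * (1 + artifact)
    signal = (base * _bleach(t, params.bleach_tau_signal) * (1 + artifact)
              * (1 + transients))
    if params.noise_sd > 0:
        signal = signal + rng.normal(0, params.noise_sd, n)
        control = control + rng.normal(0, params.noise_sd, n)
    rec = PhotometryRecording(
        time=t, f_signal=signal, f_control=control, sampling_rate=fs,
        label=f"sim(seed={params.seed})",
    )
    return rec, events


def simulate_bouts(
    duration: float,
    mean_struggle: float,
    mean_immobile: float,
    seed: int = 0,
    first_label: str = "immobility",
) -> BoutAnnotation:
    """Alternating struggle/immobility bouts tiling [0, duration) exactly.

    Bout lengths are exponential with the given per-label means; the final
    bout is truncated at ``duration``. Sessions start immobile by default.
    """
    if duration <= 0:
        raise ParameterError("duration must be > 0")
    if mean_struggle <= 0 or mean_immobile <= 0:
        raise ParameterError("bout means must be > 0")
    if first_label not in ("struggle", "immobility"):
        raise ParameterError(f"unknown first_label {first_label!r}")
    rng = np.random.default_rng(seed)
    means = {"struggle": mean_struggle, "immobility": mean_immobile}
    other = {"struggle": "immobility", "immobility": "struggle"}
    intervals: list[tuple[float, float, str]] = []
    t, lab = 0.0, first_label
    while t < duration:
        length = float(rng.exponential(means[lab]))
        end = min(t + max(length, 1e-9), duration)
        intervals.append((t, end, lab))
        t, lab = end, other[lab]
    return BoutAnnotation(intervals=intervals, session_duration=duration)


def simulate_abundance(
    params: OmicsSimParams,
) -> tuple[AbundanceTable, dict[str, str]]:
    """Two-group abundance table with planted fold-change effects.

    Planted up features have expected treatment/control ratio ``effect_fc``,
    down features ``1/effect_fc``; log-normal noise is mean-corrected so the
    expected ratio is exact. Returns the table and a feature -> {"up",
    "down", "null"} truth map.
    """
    rng = np.random.default_rng(params.seed)
    nf, npg = params.n_features, params.n_per_group
    n_up = int(round(params.frac_up * nf))
    n_down = int(round(params.frac_down * nf))
    if n_up + n_down > nf:
        n_down = nf - n_up
    width = max(4, len(str(nf)))
    feature_ids = [f"F{i:0{width}d}" for i in range(nf)]
    labels = {fid: "null" for fid in feature_ids}
    effect = np.ones(nf)
    for i in range(n_up):
        labels[feature_ids[i]] = "up"
        effect[i] = params.effect_fc
    for i in range(n_up, n_up + n_down):
        labels[feature_ids[i]] = "down"
        effect[i] = 1.0 / params.effect_fc

    base = rng.lognormal(mean=math.log(1000.0), sigma=1.0, size=nf)
    # sigma chosen so the multiplicative noise has the requested CV, and
    # mean-corrected so E[noise] = 1 (expected FC stays exactly effect_fc)
    if params.noise_cv > 0:
        sigma = math.sqrt(math.log(1.0 + params.noise_cv**2))
        noise = rng.lognormal(-sigma**2 / 2.0, sigma, size=(nf, 2 * npg))
    else:
        noise = np.ones((nf, 2 * npg))
    values = np.empty((nf, 2 * npg))
    values[:, :npg] = base[:, None] * noise[:, :npg]
    values[:, npg:] = (base * effect)[:, None] * noise[:, npg:]

    sample_ids = [f"ctrl_{j + 1}" for j in range(npg)] + [
        f"trt_{j + 1}" for j in range(npg)
    ]
    groups = {s: ("control" if s.startswith("ctrl") else "treatment")
              for s in sample_ids}
    table = AbundanceTable(feature_ids, values, sample_ids, groups)
    return table, labels


def simulate_network(
    n_nodes: int,
    n_edges: int,
    planted_hubs: Mapping[str, int] | None = None,
    seed: int = 0,
) -> InteractionNetwork:
    """Random simple graph containing planted hubs with exact degrees.

    Hub nodes are connected only to non-hub nodes (so their degrees are
    exactly as requested and independent of each other); the remaining
    edges are drawn uniformly among non-hub pairs. Node ids are ``N0000``
    style; hub ids must name existing nodes.
    """
    if n_nodes < 1:
        raise ParameterError("n_nodes must be >= 1")
    max_edges = n_nodes * (n_nodes - 1) // 2
    if not (0 <= n_edges <= max_edges):
        raise ParameterError(
            f"n_edges must be in [0, {max_edges}] for {n_nodes} nodes"
        )
    rng = np.random.default_rng(seed)
    width = max(4, len(str(n_nodes)))
    nodes = [f"N{i:0{width}d}" for i in range(n_nodes)]
    node_set = set(nodes)
    hubs = dict(planted_hubs or {})
    for h, d in hubs.items():
        if h not in node_set:
            raise ParameterError(f"planted hub {h!r} is not a node id")
        if not (0 <= d <= n_nodes - 1):
            raise ParameterError(f"hub {h!r} degree {d} infeasible")

    non_hubs = [v for v in nodes if v not in hubs]
    edges: set[tuple[str, str]] = set()
    single_hub = len(hubs) == 1
    for h, d in hubs.items():
        # a lone hub may use any partner (allows a full star); with several
        # hubs partners are restricted to non-hubs to keep degrees exact
        pool = [v for v in nodes if v != h] if single_hub else non_hubs
        if d > len(pool):
            raise ParameterError(
                f"hub {h!r} degree {d} infeasible with {len(pool)} partners"
            )
        partners = rng.choice(len(pool), size=d, replace=False)
        for j in partners:
            v = pool[int(j)]
            edges.add((h, v) if h <= v else (v, h))
    if len(edges) > n_edges:
        raise ParameterError(
            f"planted hub edges ({len(edges)}) exceed n_edges ({n_edges})"
        )

    candidates = [
        (non_hubs[i], non_hubs[j])
        for i in range(len(non_hubs))
        for j in range(i + 1, len(non_hubs))
        if (non_hubs[i], non_hubs[j]) not in edges
    ]
    needed = n_edges - len(edges)
    if needed > len(candidates):
        raise ParameterError(
            f"cannot place {needed} extra edges among {len(non_hubs)} "
            "non-hub nodes without disturbing planted degrees"
        )
    if needed:
        chosen = rng.choice(len(candidates), size=needed, replace=False)
        for j in chosen:
            edges.add(candidates[int(j)])
    return InteractionNetwork(nodes=nodes, edges=sorted(edges))
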