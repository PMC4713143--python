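"""Synthetic EEG, behaviour and drug-concentration generator.

Emulates an eyes-closed resting EEG sedation study: 91-channel, 250 Hz
recordings in ~10 s epochs, with controllable alpha-band phase-coupling
topology (an occipital-like and a frontal-like module), slow-alpha
phase-amplitude coupling of chosen sign and depth, 1/f background noise,
and per-participant hit-rate / plasma-concentration covariates.  Every
output is deterministic given its seed, so each downstream estimator can be
validated against known ground truth.

The phase-coupling mechanism adds a shared narrowband alpha source to each
coupled channel pair with a fixed phase offset (default pi/2).  The debiased
weighted phase lag index is insensitive to lags near 0 or pi, so the
simulator defaults to the quarter-cycle lag it detects best; a zero-lag
shared component is available separately as a volume-conduction stand-in.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import butter, hilbert, sosfiltfilt

from .behaviour import DROWSY, RESPONSIVE, ParticipantRecord
from .containers import LEVELS, Recording

PAC_MODES = ("peak_max", "trough_max", "none")


def fibonacci_sphere(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit-sphere points (electrode stand-ins)."""
    i = np.arange(n, dtype=float)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    z = 1.0 - 2.0 * (i + 0.5) / n
    r = np.sqrt(1.0 - z * z)
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def powerlaw_noise(
    n_samples: int, exponent: float, fs: float, rng: np.random.Generator
) -> np.ndarray:
    """Gaussian 1/f**exponent noise, unit RMS."""
    white = rng.standard_normal(n_samples)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n_samples, 1.0 / fs)
    shaping = np.ones_like(freqs)
    shaping[1:] = freqs[1:] ** (-exponent / 2.0)
    shaping[0] = 0.0
    x = np.fft.irfft(spec * shaping, n=n_samples)
    return x / x.std()


def _narrowband_analytic(
    n_samples: int, band: tuple[float, float], fs: float, rng: np.random.Generator
) -> np.ndarray:
    """Analytic (complex) narrowband Gaussian source, real part unit RMS."""
    sos = butter(4, band, btype="bandpass", fs=fs, output="sos")
    x = sosfiltfilt(sos, rng.standard_normal(n_samples))
    z = hilbert(x)
    return z / np.real(z).std()


_EDGE_BW = 1.5  # Hz; sub-band width for per-edge coupling sources


def _edge_frequencies(band: tuple[float, float]) -> np.ndarray:
    """Sub-band centre frequencies tiling the interior of ``band``."""
    lo, hi = band
    centers = np.arange(lo + _EDGE_BW, hi - _EDGE_BW + 1e-9, _EDGE_BW)
    return centers if centers.size else np.array([(lo + hi) / 2])


@dataclass
class SimulationConfig:
    """Parameters of one synthetic recording.

    ``coupling_graph`` is a symmetric zero-diagonal matrix of target
    alpha-band coupling strengths in [0, 1]; each positive entry injects a
    shared narrowband source into that channel pair at phase offset
    ``coupling_phase_lag``, mixed at amplitude ``snr * weight`` relative to
    the unit-RMS 1/f background.
    """

    n_channels: int = 91
    fs: float = 250.0
    n_epochs: int = 40
    epoch_length: float = 10.0
    coupling_graph: np.ndarray | None = None
    coupling_phase_lag: float = np.pi / 2
    alpha_band: tuple[float, float] = (8.0, 15.0)
    slow_band: tuple[float, float] = (0.5, 1.5)
    pac_mode: str = "none"
    pac_depth: float = 0.0
    pac_channels: list[int] | None = None
    noise_exponent: float = 1.0
    snr: float = 1.0
    common_source_weight: float = 0.0  # zero-lag shared source (volume conduction stand-in)
    seed: int = 0

    def validate(self) -> None:
        if self.n_channels < 1 or self.n_epochs < 1:
            raise ValueError("n_channels and n_epochs must be positive")
        for band in (self.alpha_band, self.slow_band):
            if not 0 < band[0] < band[1]:
                raise ValueError(f"invalid band {band}")
            if self.fs <= 2 * band[1]:
                raise ValueError("sampling rate too low for requested band")
        if self.pac_mode not in PAC_MODES:
            raise ValueError(f"pac_mode must be one of {PAC_MODES}")
        if not 0.0 <= self.pac_depth <= 1.0:
            raise ValueError("pac_depth must lie in [0, 1]")
        if self.coupling_graph is not None:
            g = np.asarray(self.coupling_graph, dtype=float)
            if g.shape != (self.n_channels, self.n_channels):
                raise ValueError("coupling_graph shape must match n_channels")
            if not np.allclose(g, g.T):
                raise ValueError("coupling_graph must be symmetric")
            if np.any(np.diag(g) != 0):
                raise ValueError("coupling_graph diagonal must be zero")
            if g.min() < 0 or g.max() > 1:
                raise ValueError("coupling_graph entries must lie in [0, 1]")

    @property
    def n_samples(self) -> int:
        return int(round(self.fs * self.n_epochs * self.epoch_length))


def simulate_recording(config: SimulationConfig) -> Recording:
    """Generate a continuous multichannel recording per the configuration.

    Each channel carries independent 1/f**noise_exponent noise (unit RMS);
    coupled pairs additionally share a narrowband alpha source with a fixed
    phase lag.  Output is scaled to a nominal 10 uV RMS. Deterministic given
    ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n, c = config.n_samples, config.n_channels
    data = np.empty((c, n))
    for ch in range(c):
        data[ch] = powerlaw_noise(n, config.noise_exponent, config.fs, rng)

    if config.common_source_weight > 0:
        shared = powerlaw_noise(n, config.noise_exponent, config.fs, rng)
        data += config.common_source_weight * shared[None, :]

    if config.coupling_graph is not None:
        g = np.asarray(config.coupling_graph, dtype=float)
        rows, cols = np.nonzero(np.triu(g, k=1))
        phase = np.exp(-1j * config.coupling_phase_lag)
        centers = _edge_frequencies(config.alpha_band)
        for i, j in zip(rows, cols):
            # tile edges over sub-bands of the alpha band so sources
            # incident on one channel do not mask each other's phase lag
            fc = centers[(i + j) % len(centers)]
            band = (fc - _EDGE_BW / 2, fc + _EDGE_BW / 2)
            z = _narrowband_analytic(n, band, config.fs, rng)
            amp = config.snr * g[i, j]
            data[i] += amp * np.real(z)
            data[j] += amp * np.real(z * phase)

    data *= 10.0  # nominal uV scale
    labels = [f"E{k + 1:03d}" for k in range(c)]
    rec = Recording(
        data=data, fs=config.fs, labels=labels, positions=fibonacci_sphere(c)
    )
    if config.pac_mode != "none" and config.pac_depth > 0:
        channels = (
            list(range(c)) if config.pac_channels is None else config.pac_channels
        )
        rec = inject_pac(
            rec,
            channels,
            config.slow_band,
            config.alpha_band,
            config.pac_mode,
            config.pac_depth,
        )
    return rec


def inject_pac(
    recording: Recording,
    channels: list[int],
    slow_band: tuple[float, float],
    alpha_band: tuple[float, float],
    mode: str,
    depth: float,
) -> Recording:
    """Modulate the alpha envelope of selected channels by the slow phase.

    The alpha-band component ``x_a`` of each selected channel is replaced by
    ``x_a * (1 + s * depth * cos(phi_slow))`` with s = +1 for peak-max and
    s = -1 for trough-max coupling, leaving other channels untouched.
    """
    if not 0.0 <= depth <= 1.0:
        raise ValueError("depth must lie in [0, 1]")
    if mode not in ("peak_max", "trough_max"):
        raise ValueError("mode must be 'peak_max' or 'trough_max'")
    if slow_band[1] >= alpha_band[0] and alpha_band[1] >= slow_band[0]:
        if max(slow_band[0], alpha_band[0]) <= min(slow_band[1], alpha_band[1]):
            raise ValueError("slow and alpha bands must be disjoint")
    sign = 1.0 if mode == "peak_max" else -1.0
    out = recording.copy()
    sos_a = butter(4, alpha_band, btype="bandpass", fs=recording.fs, output="sos")
    sos_s = butter(4, slow_band, btype="bandpass", fs=recording.fs, output="sos")
    for ch in channels:
        x = out.data[ch]
        x_alpha = sosfiltfilt(sos_a, x)
        phi = np.angle(hilbert(sosfiltfilt(sos_s, x)))
        out.data[ch] = x + sign * depth * x_alpha * np.cos(phi)
    return out


_DEFAULT_RT = {
    "baseline": (0.35, 0.25),
    "mild": (0.40, 0.25),
    "moderate": (0.55, 0.30),
    "recovery": (0.40, 0.25),
}


def simulate_behaviour(
    p_hit,
    n_trials: int = 40,
    rt_params: dict | None = None,
    seed: int = 0,
    participant: str = "P00",
) -> ParticipantRecord:
    """Bernoulli hit sequences and lognormal reaction times per level.

    ``p_hit`` maps level -> probability of a correct response (or is a
    sequence in level order); reaction times (median, sigma of a lognormal)
    are drawn for correct trials only, with the moderate level slowed by
    default to mimic sedation.
    """
    if n_trials <= 0:
        raise ValueError("n_trials must be positive")
    if not isinstance(p_hit, dict):
        p_hit = dict(zip(LEVELS, p_hit))
    rt_params = rt_params or _DEFAULT_RT
    rng = np.random.default_rng(seed)
    rec = ParticipantRecord(participant=participant)
    for level in LEVELS:
        p = float(p_hit[level])
        if not 0.0 <= p <= 1.0:
            raise ValueError("hit probabilities must lie in [0, 1]")
        hits_seq = rng.random(n_trials) < p
        rec.hits[level] = int(hits_seq.sum())
        rec.trials[level] = n_trials
        median, sigma = rt_params.get(level, (0.4, 0.25))
        n_correct = rec.hits[level]
        rts = np.exp(rng.normal(np.log(median), sigma, size=n_correct))
        rec.reaction_times[level] = [float(t) for t in rts]
    return rec


def modular_coupling_graph(
    n_channels: int,
    intra_weight: float = 0.6,
    inter_weight: float = 0.6,
    neighbors: int = 4,
    hub_every: int = 4,
) -> tuple[np.ndarray, np.ndarray]:
    """Two-module alpha coupling topology (occipital-like and frontal-like)
    with inter-module hub nodes.

    Within each module channels form a ring lattice (each node linked to
    ``neighbors`` nearest neighbours at ``intra_weight``).  Every
    ``hub_every``-th node of the first module is a connector hub, bridged at
    ``inter_weight`` to nodes spread across the second module — hubs split
    their strength between modules (high participation) without letting
    community detection absorb them into either.  Returns the coupling
    matrix and a 0/1 module label per channel.
    """
    g = np.zeros((n_channels, n_channels))
    half = n_channels // 2
    modules = np.array([0] * half + [1] * (n_channels - half))
    for start, size in ((0, half), (half, n_channels - half)):
        for a in range(size):
            for step in range(1, neighbors // 2 + 1):
                b = (a + step) % size
                if b == a:
                    continue
                i, j = start + a, start + b
                g[i, j] = g[j, i] = intra_weight
    for a in range(0, half, hub_every):
        for off in range(0, half, hub_every):
            j = half + (a + off) % (n_channels - half)
            g[a, j] = g[j, a] = inter_weight
    return g, modules


def default_rois(n_channels: int) -> dict[str, list[int]]:
    """Occipital/frontal channel sets matching the two coupling modules."""
    half = n_channels // 2
    return {
        "occipital": list(range(half)),
        "frontal": list(range(half, n_channels)),
    }


def _default_group_effects() -> dict:
    # Study conditions: with sedation the drowsy group's alpha network loses
    # integration (inter-module bridges vanish), its intra-module coupling
    # weakens and thins (a fraction of links drops out, breaking local
    # triangles while the modules stay segregated), and its moderate hit
    # rate collapses; slow-alpha PAC deepens with drug level, flipping to
    # peak-max in the drowsy group at moderate sedation.
    return {
        RESPONSIVE: {
            "coupling_intra": dict(zip(LEVELS, (1.0, 1.0, 1.0, 1.0))),
            "intra_survival": dict(zip(LEVELS, (1.0, 1.0, 1.0, 1.0))),
            "coupling_inter": dict(zip(LEVELS, (1.0, 1.0, 1.0, 1.0))),
            "pac_depth": dict(zip(LEVELS, (0.1, 0.2, 0.4, 0.1))),
            "pac_mode": dict(
                zip(LEVELS, ("trough_max",) * 4)
            ),
            "p_hit": dict(zip(LEVELS, (0.97, 0.95, 0.90, 0.96))),
        },
        DROWSY: {
            "coupling_intra": dict(zip(LEVELS, (0.90, 0.80, 0.60, 1.0))),
            "intra_survival": dict(zip(LEVELS, (0.90, 0.70, 0.50, 1.0))),
            "coupling_inter": dict(zip(LEVELS, (0.70, 0.40, 0.03, 1.0))),
            "pac_depth": dict(zip(LEVELS, (0.1, 0.25, 0.55, 0.1))),
            "pac_mode": dict(
                zip(LEVELS, ("trough_max", "trough_max", "peak_max", "trough_max"))
            ),
            "p_hit": dict(zip(LEVELS, (0.97, 0.85, 0.20, 0.90))),
        },
    }


@dataclass
class CohortConfig:
    """Cohort-level study design.

    Defaults reproduce the study conditions: 13 responsive + 7 drowsy
    participants, plasma targets 0.6 ug/ml (mild) and 1.2 ug/ml (moderate)
    with lognormal scatter so the group distributions overlap, and
    group-by-level multipliers on coupling strength, PAC depth and hit
    probability.
    """

    n_per_group: dict[str, int] = field(
        default_factory=lambda: {RESPONSIVE: 13, DROWSY: 7}
    )
    group_effects: dict = field(default_factory=_default_group_effects)
    drug_targets: dict[str, float] = field(
        default_factory=lambda: {"mild": 0.6, "moderate": 1.2, "recovery": 0.1}
    )
    drug_cv: float = 0.25
    participant_cv: float = 0.2  # per-participant scatter on coupling strength
    n_trials: int = 40
    base: SimulationConfig = field(default_factory=SimulationConfig)
    intra_weight: float = 0.6
    inter_weight: float = 0.6
    seed: int = 0

    def validate(self) -> None:
        if any(n <= 0 for n in self.n_per_group.values()):
            raise ValueError("every group must have at least one participant")
        if any(t < 0 for t in self.drug_targets.values()):
            raise ValueError("drug targets must be non-negative")
        for effects in self.group_effects.values():
            for p in effects["p_hit"].values():
                if not 0.0 <= p <= 1.0:
                    raise ValueError("hit probabilities must lie in [0, 1]")


@dataclass
class CohortMember:
    participant: str
    true_group: str
    recordings: dict[str, Recording]
    record: ParticipantRecord
    pac_depths: dict[str, float]
    coupling_scale: float


def _lognormal_around(
    target: float, cv: float, rng: np.random.Generator
) -> float:
    """Lognormal draw with mean exactly ``target``; degenerate at cv = 0."""
    if cv <= 0 or target == 0:
        return target
    sigma = np.sqrt(np.log1p(cv**2))
    return float(target * np.exp(rng.normal(-(sigma**2) / 2, sigma)))


def simulate_cohort(
    config: CohortConfig, levels: tuple[str, ...] = LEVELS
) -> list[CohortMember]:
    """Simulate recordings, behaviour and drug levels for a whole cohort.

    Per participant and level: a recording whose coupling topology is the
    two-module graph scaled by the group's level multipliers (with
    per-participant lognormal scatter), PAC injected into the occipital
    module with depth scaled by that participant's drawn concentration
    relative to target, plus a behavioural table.  Deterministic given
    ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    base_graph, modules = modular_coupling_graph(
        config.base.n_channels, config.intra_weight, config.inter_weight
    )
    intra_mask = (modules[:, None] == modules[None, :]) & (base_graph > 0)
    inter_mask = (modules[:, None] != modules[None, :]) & (base_graph > 0)
    rois = default_rois(config.base.n_channels)

    members: list[CohortMember] = []
    idx = 0
    for group, n_members in config.n_per_group.items():
        effects = config.group_effects[group]
        for _ in range(n_members):
            idx += 1
            pid = f"P{idx:02d}"
            subj_scale = _lognormal_around(1.0, config.participant_cv, rng)
            behav_seed = int(rng.integers(2**31 - 1))
            record = simulate_behaviour(
                effects["p_hit"],
                n_trials=config.n_trials,
                seed=behav_seed,
                participant=pid,
            )
            recordings: dict[str, Recording] = {}
            pac_depths: dict[str, float] = {}
            for level in levels:
                target = config.drug_targets.get(level, 0.0)
                if target > 0:
                    conc = _lognormal_around(target, config.drug_cv, rng)
                    record.drug[level] = conc
                    conc_ratio = conc / target
                else:
                    conc_ratio = 1.0
                graph = np.where(
                    intra_mask,
                    base_graph * effects["coupling_intra"][level] * subj_scale,
                    np.where(
                        inter_mask,
                        base_graph * effects["coupling_inter"][level] * subj_scale,
                        0.0,
                    ),
                )
                survival = effects.get("intra_survival", {}).get(level, 1.0)
                if survival < 1.0:
                    # thin intra-module links symmetrically: segregation is
                    # kept but local triangles break
                    n_ch = graph.shape[0]
                    iu = np.triu_indices(n_ch, k=1)
                    drop = rng.random(iu[0].size) >= survival
                    kill = np.zeros_like(graph, dtype=bool)
                    kill[iu[0][drop], iu[1][drop]] = True
                    kill |= kill.T
                    graph = np.where(kill & intra_mask, 0.0, graph)
                depth = float(
                    np.clip(effects["pac_depth"][level] * conc_ratio, 0.0, 1.0)
                )
                pac_depths[level] = depth
                level_cfg = replace(
                    config.base,
                    coupling_graph=np.clip(graph, 0.0, 1.0),
                    pac_mode=effects["pac_mode"][level] if depth > 0 else "none",
                    pac_depth=depth,
                    pac_channels=rois["occipital"],
                    seed=int(rng.integers(2**31 - 1)),
                )
                recordings[level] = simulate_recording(level_cfg)
            members.append(
                CohortMember(
                    participant=pid,
                    true_group=group,
                    recordings=recordings,
                    record=record,
                    pac_depths=pac_depths,
                    coupling_scale=subj_scale,
                )
            )
    return members
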