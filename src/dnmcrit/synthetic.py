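"""Synthetic oddball-EEG cohorts with a planted near-critical subnetwork.

The generator emulates a multisubject auditory-oddball study: 64-channel
recordings at 500 Hz, 2000-stimulus sequences (90 % standard / 10 % deviant,
stimulus-onset asynchrony 500 ms), a group-dependent mismatch-negativity
(MMN) deflection on fronto-central channels, and — the scientific core — a
linear difference process

    z(t+1) = A z(t) + xi(t)

planted into deviant responses.  ``A`` contains a uniformly coupled
subnetwork (the dynamical-network-marker block) whose spectral radius
``gamma`` controls the distance to the codimension-one bifurcation at
``gamma = 1``: near-critical, healthy-control-like subjects use ``gamma``
close to 1, stable psychotic-disorder-like subjects use a small ``gamma``.

Group labels follow the clinical convention: HC (healthy controls), UHR
(ultra-high-risk individuals), PD (patients with psychotic disorder).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "LinearNetworkModel",
    "GroupSpec",
    "SimulationConfig",
    "OddballRecording",
    "make_linear_model",
    "simulate_difference_process",
    "simulate_oddball_recording",
    "generate_study",
    "iter_study",
]

#: default planted subnetwork: fronto-central channels (0-based indices of
#: 1-based montage numbers 3, 4, 5, 9, 17, 18, 30, 43)
DEFAULT_DNM_MEMBERS = (2, 3, 4, 8, 16, 17, 29, 42)

GROUPS = ("HC", "UHR", "PD")


def _spectral_radius(a: np.ndarray) -> float:
    return float(np.max(np.abs(np.linalg.eigvals(a))))


@dataclass(frozen=True)
class LinearNetworkModel:
    """Linear network dynamics ``z(t+1) = A z(t) + xi(t)``.

    ``A`` carries a uniformly coupled block over ``dnm_members`` rescaled so
    that the block's spectral radius equals ``gamma``; the remaining channels
    either decay independently with self-coupling ``offblock_coupling`` or,
    when ``direct_coupling > 0``, form a directed delay ring of that weight
    (strong pairwise propagation with zero instantaneous cross-correlation —
    the generator's stand-in for the strong direct causality seen in stable,
    non-critical recordings).
    """

    n_channels: int
    A: np.ndarray
    dnm_members: tuple[int, ...]
    gamma: float
    offblock_coupling: float
    noise_sd: float
    direct_coupling: float = 0.0

    def __post_init__(self) -> None:
        a = np.asarray(self.A, dtype=float)
        if a.shape != (self.n_channels, self.n_channels):
            raise ValueError("A must be square with side n_channels")
        members = tuple(int(m) for m in self.dnm_members)
        if len(members) == 0 or len(set(members)) != len(members):
            raise ValueError("dnm_members must be nonempty and unique")
        if len(members) >= self.n_channels:
            raise ValueError("dnm_members must be a strict subset of channels")
        if any(m < 0 or m >= self.n_channels for m in members):
            raise ValueError("dnm_members out of range")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        rho = _spectral_radius(a)
        if rho >= 1.0:
            raise ValueError(f"spectral radius of A must be < 1, got {rho:.6f}")
        block = a[np.ix_(members, members)]
        rho_block = _spectral_radius(block)
        if abs(rho_block - self.gamma) > 1e-9:
            raise ValueError(
                f"DNM-block spectral radius {rho_block:.12f} != gamma {self.gamma}"
            )
        object.__setattr__(self, "A", a)
        object.__setattr__(self, "dnm_members", members)


@dataclass(frozen=True)
class GroupSpec:
    """Per-group generator settings.

    gamma
        spectral radius of the planted subnetwork block, in (0, 1);
        the distance ``1 - gamma`` to the bifurcation.
    mmn_amplitude
        peak of the planted MMN deflection in µV (negative for the usual
        mismatch negativity).
    mmn_latency
        latency of the deflection peak in ms after stimulus onset.
    direct_coupling
        weight of the directed delay ring among non-subnetwork channels;
        zero disables the ring (independent weakly damped channels).
    """

    n_subjects: int
    gamma: float
    mmn_amplitude: float
    mmn_latency: float
    direct_coupling: float = 0.0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("each requested group needs at least one subject")
        if not (0.0 < self.gamma < 1.0):
            raise ValueError(f"gamma must lie in (0, 1), got {self.gamma}")
        if not (0.0 <= self.direct_coupling < 1.0):
            raise ValueError("direct_coupling must lie in [0, 1)")


def default_group_specs() -> dict[str, GroupSpec]:
    """Default cohort: 49 HC / 24 UHR / 29 PD.

    HC sits near the bifurcation (gamma 0.97), PD is well inside the stable
    regime (gamma 0.6) with strong direct propagation pathways, UHR is
    intermediate in criticality but HC-like in direct coupling.  MMN
    amplitude is graded HC > UHR > PD in magnitude, latency mildly delayed
    with illness.
    """
    return {
        "HC": GroupSpec(49, 0.97, -3.0, 170.0, 0.0),
        "UHR": GroupSpec(24, 0.80, -2.2, 175.0, 0.0),
        "PD": GroupSpec(29, 0.60, -1.5, 185.0, 0.9),
    }


@dataclass(frozen=True)
class SimulationConfig:
    """Study-level generator configuration (defaults mirror the emulated
    oddball protocol: 64 channels, 500 Hz, 2000 stimuli, 90/10 split,
    SOA 500 ms)."""

    n_channels: int = 64
    sampling_rate: float = 500.0
    n_stimuli: int = 2000
    deviant_fraction: float = 0.10
    soa: float = 500.0
    group_specs: dict[str, GroupSpec] = field(default_factory=default_group_specs)
    epoch_window: tuple[float, float] = (-100.0, 400.0)
    seed: int = 0
    dnm_members: tuple[int, ...] = DEFAULT_DNM_MEMBERS
    noise_sd: float = 1.0            # SD of the dynamics innovation xi, µV
    sensor_noise_sd: float = 2.0     # i.i.d. background sensor noise, µV
    offblock_coupling: float = 0.3   # self-decay of non-subnetwork channels
    standard_erp_amplitude: float = 1.5   # µV, obligatory response template
    standard_erp_latency: float = 100.0   # ms
    standard_erp_width: float = 20.0      # ms (Gaussian SD)
    mmn_width: float = 25.0               # ms (Gaussian SD)
    gamma_jitter_sd: float = 0.005        # between-subject spread of gamma
    amplitude_jitter_sd: float = 0.3      # between-subject spread of MMN, µV
    no_consecutive_deviants: bool = True
    burn_in: int = 150               # dynamics warm-up samples per epoch

    def __post_init__(self) -> None:
        if not (0.0 < self.deviant_fraction < 1.0):
            raise ValueError("deviant_fraction must lie in (0, 1)")
        soa_samples = self.soa * self.sampling_rate / 1000.0
        if abs(soa_samples - round(soa_samples)) > 1e-9:
            raise ValueError("soa must be an integer number of samples")
        for name, spec in self.group_specs.items():
            if name not in GROUPS:
                raise ValueError(f"unknown group label {name!r}")
        members = tuple(int(m) for m in self.dnm_members)
        if any(m < 0 or m >= self.n_channels for m in members):
            raise ValueError("dnm_members out of channel range")
        object.__setattr__(self, "dnm_members", members)

    @property
    def soa_samples(self) -> int:
        return int(round(self.soa * self.sampling_rate / 1000.0))


@dataclass(frozen=True)
class OddballRecording:
    """Continuous multichannel signal plus its stimulus-event stream."""

    subject_id: str
    group: str
    signal: np.ndarray          # channel x sample, µV
    sampling_rate: float
    events: list  # of (onset_sample, "standard" | "deviant")

    def __post_init__(self) -> None:
        sig = np.asarray(self.signal, dtype=float)
        if sig.ndim != 2:
            raise ValueError("signal must be channel x sample")
        onsets = [int(o) for o, _ in self.events]
        if any(o < 0 or o >= sig.shape[1] for o in onsets):
            raise ValueError("event onset outside the recording")
        if any(b < a for a, b in zip(onsets, onsets[1:])):
            raise ValueError("events must be sorted by onset")
        kinds = {k for _, k in self.events}
        if not kinds <= {"standard", "deviant"}:
            raise ValueError(f"unknown event kind(s) {kinds - {'standard', 'deviant'}}")
        object.__setattr__(self, "signal", sig)


def make_linear_model(
    config: SimulationConfig,
    group_gamma: float,
    seed: int = 0,
    direct_coupling: float = 0.0,
) -> LinearNetworkModel:
    """Build the dynamics matrix with the planted subnetwork at ``group_gamma``.

    The subnetwork block is the uniform coupling matrix J/m rescaled so its
    spectral radius equals ``group_gamma`` exactly (J/m has a single unit
    eigenvalue on the all-ones mode).  Non-member channels either decay
    independently (``config.offblock_coupling`` on the diagonal) or, for
    ``direct_coupling > 0``, form a directed delay ring of that weight.

    ``seed`` is accepted for interface symmetry; the construction is
    deterministic.
    """
    if not (0.0 < group_gamma < 1.0):
        raise ValueError(f"gamma must lie in (0, 1), got {group_gamma}")
    if not (0.0 <= direct_coupling < 1.0):
        raise ValueError("direct_coupling must lie in [0, 1)")
    n = config.n_channels
    members = list(config.dnm_members)
    m = len(members)
    a = np.zeros((n, n))
    a[np.ix_(members, members)] = group_gamma / m
    others = [i for i in range(n) if i not in set(members)]
    if direct_coupling > 0.0 and len(others) >= 2:
        for src, dst in zip(others, others[1:] + others[:1]):
            a[dst, src] = direct_coupling
    else:
        for i in others:
            a[i, i] = config.offblock_coupling
    return LinearNetworkModel(
        n_channels=n,
        A=a,
        dnm_members=tuple(members),
        gamma=group_gamma,
        offblock_coupling=config.offblock_coupling,
        noise_sd=config.noise_sd,
        direct_coupling=direct_coupling,
    )


def simulate_difference_process(
    model: LinearNetworkModel, n_samples: int, seed: int = 0
) -> np.ndarray:
    """Iterate ``z(t+1) = A z(t) + xi(t)`` from ``z(0) = 0``.

    Returns a channel x sample array; bitwise reproducible for a given seed.
    """
    if n_samples < 2:
        raise ValueError("n_samples must be at least 2")
    rng = np.random.default_rng(seed)
    n = model.n_channels
    z = np.zeros((n, n_samples))
    noise = rng.normal(0.0, model.noise_sd, size=(n_samples - 1, n))
    cur = np.zeros(n)
    at = model.A
    for t in range(1, n_samples):
        cur = at @ cur + noise[t - 1]
        z[:, t] = cur
    return z


def _simulate_epoch_dynamics(
    model: LinearNetworkModel, n_epochs: int, n_steps: int, burn_in: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Stationary difference-process segments, one per epoch (epoch x channel
    x step).  All epochs are iterated jointly for speed; a burn-in from the
    zero state brings each segment close to stationarity."""
    n = model.n_channels
    total = burn_in + n_steps
    at = model.A.T
    z = np.zeros((n_epochs, n))
    out = np.empty((n_epochs, n, n_steps))
    for t in range(total):
        z = z @ at + rng.normal(0.0, model.noise_sd, size=(n_epochs, n))
        if t >= burn_in:
            out[:, :, t - burn_in] = z
    return out


def _gaussian_bump(t_ms: np.ndarray, amp: float, latency: float, width: float) -> np.ndarray:
    return amp * np.exp(-0.5 * ((t_ms - latency) / width) ** 2)


def _event_kinds(config: SimulationConfig, rng: np.random.Generator) -> list[str]:
    kinds: list[str] = []
    prev_dev = False
    for _ in range(config.n_stimuli):
        if config.no_consecutive_deviants and prev_dev:
            dev = False
        else:
            dev = rng.random() < config.deviant_fraction
        kinds.append("deviant" if dev else "standard")
        prev_dev = dev
    return kinds


def simulate_oddball_recording(
    config: SimulationConfig,
    model: LinearNetworkModel,
    subject_id: str,
    seed: int = 0,
    group: str = "HC",
    mmn_amplitude: float = -3.0,
    mmn_latency: float = 170.0,
) -> OddballRecording:
    """Simulate one continuous oddball session.

    Every stimulus evokes a fixed obligatory response template; deviants
    additionally carry the MMN deflection (on the planted subnetwork
    channels) and one stationary segment of the difference process, so that
    corrected epochs (deviant minus mean standard) isolate MMN + dynamics.
    I.i.d. Gaussian sensor noise covers all samples.
    """
    if model.n_channels != config.n_channels:
        raise ValueError(
            f"model has {model.n_channels} channels, config expects {config.n_channels}"
        )
    rng = np.random.default_rng(seed)
    fs = config.sampling_rate
    soa_s = config.soa_samples
    post_ms = max(config.epoch_window[1], 0.0)
    pre_samples = int(round(abs(min(config.epoch_window[0], 0.0)) * fs / 1000.0))
    post_samples = int(round(post_ms * fs / 1000.0))
    lead_in = pre_samples + 8
    n_samples = lead_in + config.n_stimuli * soa_s + post_samples + 8

    signal = rng.normal(
        0.0, config.sensor_noise_sd, size=(config.n_channels, n_samples)
    )

    kinds = _event_kinds(config, rng)
    onsets = [lead_in + i * soa_s for i in range(config.n_stimuli)]
    events = list(zip(onsets, kinds))

    t_post = np.arange(post_samples) * 1000.0 / fs
    std_template = _gaussian_bump(
        t_post, config.standard_erp_amplitude,
        config.standard_erp_latency, config.standard_erp_width,
    )
    mmn_template = _gaussian_bump(t_post, mmn_amplitude, mmn_latency, config.mmn_width)
    members = list(model.dnm_members)

    dev_idx = [i for i, k in enumerate(kinds) if k == "deviant"]
    dyn = None
    if dev_idx and model.noise_sd > 0:
        dyn = _simulate_epoch_dynamics(
            model, len(dev_idx), post_samples, config.burn_in, rng
        )

    for i, (onset, kind) in enumerate(events):
        sl = slice(onset, onset + post_samples)
        signal[:, sl] += std_template[np.newaxis, :]
        if kind == "deviant":
            signal[members, sl] += mmn_template[np.newaxis, :]
    if dyn is not None:
        for j, i in enumerate(dev_idx):
            onset = onsets[i]
            signal[:, onset:onset + post_samples] += dyn[j]

    return OddballRecording(
        subject_id=subject_id,
        group=group,
        signal=signal,
        sampling_rate=fs,
        events=events,
    )


def subject_seed(study_seed: int, group_index: int, subject_index: int) -> int:
    """Deterministic per-subject seed derived from the study seed."""
    ss = np.random.SeedSequence((int(study_seed), int(group_index), int(subject_index)))
    return int(ss.generate_state(1)[0] % (2**31))


def generate_study(config: SimulationConfig) -> list[OddballRecording]:
    """Generate the full cohort as a list (see :func:`iter_study`)."""
    return list(iter_study(config))


def iter_study(config: SimulationConfig):
    """Yield one recording per subject, group labels and per-subject seeds
    derived deterministically from ``config.seed``.

    Between-subject heterogeneity: each subject's gamma and MMN amplitude
    are jittered around the group values (truncated to the valid range).
    Prefer this generator over :func:`generate_study` for large cohorts —
    continuous recordings are big and need not coexist in memory.
    """
    if not config.group_specs:
        raise ValueError("group_specs must request at least one group")
    for gi, group in enumerate(g for g in GROUPS if g in config.group_specs):
        spec = config.group_specs[group]
        for si in range(spec.n_subjects):
            seed = subject_seed(config.seed, gi, si)
            prng = np.random.default_rng(np.random.SeedSequence((seed, 7)))
            gamma = float(np.clip(
                spec.gamma + prng.normal(0.0, config.gamma_jitter_sd),
                0.01, 0.995,
            ))
            amp = spec.mmn_amplitude + prng.normal(0.0, config.amplitude_jitter_sd)
            model = make_linear_model(
                config, gamma, seed=seed, direct_coupling=spec.direct_coupling
            )
            yield simulate_oddball_recording(
                config, model, f"{group}{si + 1:03d}", seed=seed, group=group,
                mmn_amplitude=float(amp), mmn_latency=spec.mmn_latency,
            )


def scaled_config(
    n_per_group: dict[str, int] | None = None,
    n_channels: int = 64,
    n_stimuli: int = 500,
    seed: int = 0,
    **overrides,
) -> SimulationConfig:
    """Convenience constructor for reduced-size cohorts (fewer stimuli or
    channels, same physics); used by the analysis drivers and tests."""
    specs = default_group_specs()
    if n_per_group is not None:
        specs = {
            g: replace(specs[g], n_subjects=n)
            for g, n in n_per_group.items()
        }
    members = DEFAULT_DNM_MEMBERS
    if n_channels < 64:
        members = tuple(m for m in members if m < n_channels)
        if len(members) < len(DEFAULT_DNM_MEMBERS):
            # keep eight planted members by packing them into range
            members = tuple(range(2, 10))
    return SimulationConfig(
        n_channels=n_channels,
        n_stimuli=n_stimuli,
        group_specs=specs,
        seed=seed,
        dnm_members=members,
        **overrides,
    )
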