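"""Synthetic SEEG-like recordings with known directed nonlinear coupling.

The generator produces the statistical scaffold the analysis assumes —
band-limited stochastic signals per region, scheduled directed couplings
y(t) = (1-c) * noise + c * f(x(t - delay)) with known strength, lag and
direction, and a seizure-period structure: a baseline epoch, a discharge
epoch with weak mesial-to-mesial coupling, and a termination epoch that is
either a stable thalamus-led spike-and-wave drive of every cortical region
(pattern A, with gradually lengthening inter-spike intervals) or an
unstable, weaker thalamo-cortical coupling whose strength is resampled
every 2 s (pattern B).

Every output is a pure function of its scenario and seed. Coupling acts on
the raw source signal (an instantaneous nonlinear map plus lag — exactly
the class of dependence h2 can represent), and targets are re-standardized
after mixing so coupling strength is not confounded with amplitude.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal as spsig

from .config import DEFAULT_CONFIG
from .io import RegionRecording, SeizureAnnotation
from .regions import ROLE_ORDER, RegionRole

__all__ = [
    "CouplingSpec",
    "Epoch",
    "ScenarioSpec",
    "GroundTruth",
    "CohortDataset",
    "background_signal",
    "apply_coupling",
    "spike_wave_train",
    "generate_seizure",
    "generate_cohort",
    "pattern_a_scenario",
    "pattern_b_scenario",
]

#: Duration of one spike-plus-slow-wave kernel in seconds.
KERNEL_SUPPORT_S = 0.30

DEFAULT_BAND = (4.0, 30.0)


def _standardize(x: np.ndarray) -> np.ndarray:
    x = x - x.mean()
    sd = x.std()
    return x / sd if sd > 0 else x


def _f_linear(x: np.ndarray) -> np.ndarray:
    return x


def _f_tanh(x: np.ndarray) -> np.ndarray:
    return np.tanh(3.0 * x)


def _f_quadratic(x: np.ndarray) -> np.ndarray:
    return x * x


NONLINEARITIES = {"linear": _f_linear, "tanh": _f_tanh, "quadratic": _f_quadratic}


@dataclass(frozen=True)
class CouplingSpec:
    """A directed influence of one region on another."""

    source: RegionRole
    target: RegionRole
    strength: float
    delay_samples: int
    nonlinearity: str = "tanh"

    def __post_init__(self) -> None:
        if self.source == self.target:
            raise ValueError("coupling source and target must differ")
        if not 0.0 <= self.strength <= 1.0:
            raise ValueError("coupling strength must lie in [0, 1]")
        if self.delay_samples < 1:
            raise ValueError("coupling delay must be at least one sample")
        if self.nonlinearity not in NONLINEARITIES:
            raise ValueError(f"unknown nonlinearity {self.nonlinearity!r}")


@dataclass(frozen=True)
class Epoch:
    """A span of the scenario with a fixed set of active couplings.

    With ``resample_strength`` set, each coupling's strength is redrawn per
    2 s span from U(strength * (1 - spread), strength * (1 + spread)),
    clipped to [0, 1] — the stability contrast of pattern-B terminations.
    """

    duration_s: float
    couplings: tuple[CouplingSpec, ...] = ()
    swp_source: RegionRole | None = None
    resample_strength: bool = False
    strength_spread: float = 0.8

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("epoch duration must be positive")


@dataclass(frozen=True)
class ScenarioSpec:
    """A synthetic-seizure description.

    Epoch 0 is the pre-onset baseline (the tonic discharge appears at its
    end), the last epoch is the termination epoch, and ``post_s`` seconds
    of background follow the seizure end. Pattern-A terminations drive a
    spike-and-wave train from ``swp_source`` whose inter-spike intervals
    grow by ``isi_increment_s`` per cycle.
    """

    epochs: tuple[Epoch, ...]
    pattern: str
    seed: int
    roles: tuple[RegionRole, ...] = ROLE_ORDER
    rate: float = 256.0
    post_s: float = 5.0
    band: tuple[float, float] = DEFAULT_BAND
    base_isi_s: float = 0.5
    isi_increment_s: float = 0.05
    swp_noise: float = 0.3

    def __post_init__(self) -> None:
        if len(self.epochs) < 2:
            raise ValueError("a scenario needs at least baseline and termination epochs")
        if self.pattern not in ("A", "B"):
            raise ValueError("pattern must be 'A' or 'B'")
        if self.epochs[0].duration_s < 5.0:
            raise ValueError("baseline epoch must cover the 5 s pre-onset span")
        if self.epochs[-1].duration_s + 1e-9 < DEFAULT_CONFIG.period_len_s:
            raise ValueError("termination epoch must cover the 15 s end-of-seizure period")

    @property
    def t_onset(self) -> float:
        return self.epochs[0].duration_s

    @property
    def t_end(self) -> float:
        return float(sum(e.duration_s for e in self.epochs))


@dataclass
class GroundTruth:
    """What the generator actually injected, for recovery tests."""

    pattern: str
    annotation: SeizureAnnotation
    epochs: list[dict]
    seed: int


@dataclass
class CohortDataset:
    recordings: list[RegionRecording]
    annotations: list[SeizureAnnotation]
    truths: list[GroundTruth]
    manifest: pd.DataFrame


# ---------------------------------------------------------------------------
# primitives


def background_signal(rate: float, duration_s: float, band=DEFAULT_BAND, seed=0):
    """Zero-mean, unit-variance band-limited Gaussian noise.

    White noise filtered by a 4th-order zero-phase Butterworth bandpass and
    re-standardized; deterministic for a fixed seed.
    """
    lo, hi = band
    if not 0.0 < lo < hi < rate / 2.0:
        raise ValueError(f"band {band} must satisfy 0 < lo < hi < rate/2")
    n = int(round(duration_s * rate))
    if n < 32:
        raise ValueError("duration too short for a band-limited draw")
    rng = np.random.default_rng(seed)
    white = rng.standard_normal(n)
    sos = spsig.butter(4, [lo, hi], btype="bandpass", fs=rate, output="sos")
    return _standardize(spsig.sosfiltfilt(sos, white))


def _lag(x: np.ndarray, d: int) -> np.ndarray:
    """Shift x right by d samples, holding the first value (no wraparound)."""
    return np.concatenate([np.full(d, x[0]), x[:-d]]) if d else x


def apply_coupling(
    x: np.ndarray,
    spec: CouplingSpec,
    noise_seed=0,
    rate: float = 256.0,
    band=DEFAULT_BAND,
    strength: float | np.ndarray | None = None,
) -> np.ndarray:
    """Build a target driven by a lagged nonlinear map of the source.

    y(t) = (1 - c) * xi(t) + c * f(x(t - delay)), with xi fresh unit-variance
    background noise, re-standardized to unit variance. ``strength`` may
    override the spec's c, per-sample (used for unstable terminations).
    """
    x = np.asarray(x, dtype=float)
    if x.size <= spec.delay_samples:
        raise ValueError("source shorter than the coupling delay")
    c = spec.strength if strength is None else strength
    fx = NONLINEARITIES[spec.nonlinearity](_lag(x, spec.delay_samples))
    if np.ptp(fx) > 0:
        fx = _standardize(fx)
    if np.isscalar(c) and c == 1.0:
        return _standardize(fx)
    xi = background_signal(rate, x.size / rate, band, noise_seed)[: x.size]
    return _standardize((1.0 - c) * xi + c * fx)


def spike_wave_train(
    rate: float,
    duration_s: float,
    base_isi_s: float,
    isi_increment_s: float = 0.0,
    seed=0,
):
    """A train of stereotyped spike-plus-slow-wave kernels.

    The k-th inter-spike interval is base + k * increment (the gradually
    lengthening rhythm of a spike-and-wave termination); spike amplitudes
    jitter by ±10%. Returns the sample vector and the spike-time list (s).
    """
    if base_isi_s <= 0 or isi_increment_s < 0:
        raise ValueError("base ISI must be positive and the increment non-negative")
    if base_isi_s < KERNEL_SUPPORT_S:
        raise ValueError(
            f"base ISI {base_isi_s} s is shorter than the {KERNEL_SUPPORT_S} s kernel"
        )
    n = int(round(duration_s * rate))
    rng = np.random.default_rng(seed)
    # kernel: sharp positive spike at t=0, slower negative wave after it
    tk = np.arange(int(round(KERNEL_SUPPORT_S * rate))) / rate - 0.05
    kernel = np.exp(-(tk**2) / (2 * 0.008**2)) - 0.6 * np.exp(
        -((tk - 0.13) ** 2) / (2 * 0.05**2)
    )
    out = np.zeros(n)
    spike_times = []
    t = 0.1  # first spike
    k = 0
    while True:
        i0 = int(round((t - 0.05) * rate))
        if i0 + kernel.size > n:
            break
        out[i0 : i0 + kernel.size] += kernel * rng.uniform(0.9, 1.1)
        spike_times.append(t)
        t += base_isi_s + k * isi_increment_s
        k += 1
    return out, np.asarray(spike_times)


# ---------------------------------------------------------------------------
# scenario generation


def _epoch_signals(
    epoch: Epoch, spec: ScenarioSpec, ss: np.random.SeedSequence
) -> tuple[dict[RegionRole, np.ndarray], tuple[CouplingSpec, ...]]:
    """Signals for one epoch: backgrounds, optional SWP drive, couplings."""
    children = ss.spawn(len(spec.roles) + len(epoch.couplings) + 2)
    sigs = {
        role: background_signal(spec.rate, epoch.duration_s, spec.band, children[i])
        for i, role in enumerate(spec.roles)
    }
    if epoch.swp_source is not None and epoch.swp_source in sigs:
        swt, _ = spike_wave_train(
            spec.rate,
            epoch.duration_s,
            spec.base_isi_s,
            spec.isi_increment_s,
            children[len(spec.roles)],
        )
        sigs[epoch.swp_source] = _standardize(
            _standardize(swt) + spec.swp_noise * sigs[epoch.swp_source]
        )
    block = int(round(2.0 * spec.rate))  # strength resampled per 2 s span
    rng = np.random.default_rng(children[len(spec.roles) + 1])
    realized = []
    for j, cpl in enumerate(epoch.couplings):
        if cpl.source not in sigs or cpl.target not in sigs:
            continue
        strength: float | np.ndarray | None = None
        mean_c = cpl.strength
        if epoch.resample_strength:
            n = sigs[cpl.source].size
            n_blocks = int(np.ceil(n / block))
            lo = max(0.0, cpl.strength * (1 - epoch.strength_spread))
            hi = min(1.0, cpl.strength * (1 + epoch.strength_spread))
            per_block = rng.uniform(lo, hi, n_blocks)
            strength = np.repeat(per_block, block)[:n]
            mean_c = float(per_block.mean())
        sigs[cpl.target] = apply_coupling(
            sigs[cpl.source],
            cpl,
            noise_seed=children[len(spec.roles) + 2 + j],
            rate=spec.rate,
            band=spec.band,
            strength=strength,
        )
        realized.append(replace(cpl, strength=min(1.0, mean_c)))
    return sigs, tuple(realized)


def generate_seizure(spec: ScenarioSpec):
    """Generate one synthetic seizure.

    Returns ``(RegionRecording, SeizureAnnotation, GroundTruth)``; the
    annotation places the tonic discharge at the end of the baseline epoch
    and the seizure end at the end of the last epoch.
    """
    ss = np.random.SeedSequence(spec.seed)
    epoch_ss = ss.spawn(len(spec.epochs) + 1)
    chunks: list[dict[RegionRole, np.ndarray]] = []
    truth_epochs = []
    t = 0.0
    for epoch, child in zip(spec.epochs, epoch_ss[:-1]):
        sigs, realized = _epoch_signals(epoch, spec, child)
        chunks.append(sigs)
        truth_epochs.append(
            {
                "t_start": t,
                "t_end": t + epoch.duration_s,
                "couplings": realized,
                "swp_source": epoch.swp_source,
                "stable": not epoch.resample_strength,
            }
        )
        t += epoch.duration_s
    if spec.post_s > 0:
        post = Epoch(duration_s=spec.post_s)
        sigs, _ = _epoch_signals(post, spec, epoch_ss[-1])
        chunks.append(sigs)
    samples = np.asarray(
        [np.concatenate([c[role] for c in chunks]) for role in spec.roles]
    )
    rec = RegionRecording(samples, list(spec.roles), spec.rate)
    ann = SeizureAnnotation(
        seizure_id=f"synthetic-{spec.seed}",
        patient_id=f"sim-{spec.seed}",
        t_onset=spec.t_onset,
        t_end=spec.t_end,
        pattern=spec.pattern,
    )
    truth = GroundTruth(
        pattern=spec.pattern, annotation=ann, epochs=truth_epochs, seed=spec.seed
    )
    return rec, ann, truth


# default study-condition scenarios ----------------------------------------

#: Distinct thalamo-cortical lags (samples at 256 Hz) per cortical target.
LEAD_DELAYS = {
    RegionRole.A: 4,
    RegionRole.Hip: 6,
    RegionRole.EC: 8,
    RegionRole.STG: 10,
    RegionRole.MTG: 12,
    RegionRole.ITG: 14,
}


def _mesial_onset() -> tuple[CouplingSpec, ...]:
    # seizure onset in mesial structures: weak amygdala-led coupling
    return (
        CouplingSpec(RegionRole.A, RegionRole.Hip, 0.55, 5, "tanh"),
        CouplingSpec(RegionRole.A, RegionRole.EC, 0.55, 7, "tanh"),
    )


def _th_drive(strength: float, roles) -> tuple[CouplingSpec, ...]:
    return tuple(
        CouplingSpec(RegionRole.Th, r, strength, LEAD_DELAYS[r], "tanh")
        for r in roles
        if r is not RegionRole.Th
    )


def pattern_a_scenario(seed: int, roles=ROLE_ORDER) -> ScenarioSpec:
    """Stable thalamus-led spike-and-wave termination (pattern A)."""
    return ScenarioSpec(
        epochs=(
            Epoch(10.0),
            Epoch(30.0, couplings=_mesial_onset()),
            Epoch(
                15.0,
                couplings=_th_drive(0.9, roles),
                swp_source=RegionRole.Th,
            ),
        ),
        pattern="A",
        seed=seed,
        roles=tuple(roles),
    )


def pattern_b_scenario(seed: int, roles=ROLE_ORDER) -> ScenarioSpec:
    """Unstable, weaker thalamo-cortical termination (pattern B)."""
    return ScenarioSpec(
        epochs=(
            Epoch(10.0),
            Epoch(30.0, couplings=_mesial_onset()),
            Epoch(
                15.0,
                couplings=_th_drive(0.45, roles),
                resample_strength=True,
            ),
        ),
        pattern="B",
        seed=seed,
        roles=tuple(roles),
    )


def generate_cohort(
    n_seizures: int,
    pattern_mix: float = 6 / 22,
    seed: int = 0,
    roles=ROLE_ORDER,
) -> CohortDataset:
    """Independent synthetic seizures with per-seizure derived seeds.

    ``pattern_mix`` is the fraction of pattern-A seizures (the study's
    cohort is 6 A / 16 B out of 22). Fully reproducible from the master
    seed: per-seizure seeds come from a spawned seed sequence.
    """
    if n_seizures < 1:
        raise ValueError("need at least one seizure")
    if not 0.0 <= pattern_mix <= 1.0:
        raise ValueError("pattern_mix must lie in [0, 1]")
    n_a = int(round(pattern_mix * n_seizures))
    children = np.random.SeedSequence(seed).spawn(n_seizures)
    recordings, annotations, truths, rows = [], [], [], []
    for i, child in enumerate(children):
        sub_seed = int(child.generate_state(1)[0] % (2**31))
        pattern = "A" if i < n_a else "B"
        factory = pattern_a_scenario if pattern == "A" else pattern_b_scenario
        spec = factory(sub_seed, roles=roles)
        rec, ann, truth = generate_seizure(spec)
        ann = SeizureAnnotation(
            seizure_id=f"s{i + 1}",
            patient_id=f"p{i % 10 + 1}",
            t_onset=ann.t_onset,
            t_end=ann.t_end,
            pattern=ann.pattern,
        )
        truth.annotation = ann
        recordings.append(rec)
        annotations.append(ann)
        truths.append(truth)
        rows.append(
            (ann.seizure_id, ann.patient_id, pattern, sub_seed, ann.t_onset, ann.t_end)
        )
    manifest = pd.DataFrame(
        rows,
        columns=["seizure_id", "patient_id", "pattern", "seed", "t_onset_s", "t_end_s"],
    )
    return CohortDataset(recordings, annotations, truths, manifest)
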