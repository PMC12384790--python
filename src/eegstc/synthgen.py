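"""Microstate-structured synthetic EEG with known ground truth.

The generator mirrors the generative structure that microstate analysis
assumes: a small set of fixed scalp topographies, a first-order Markov
label sequence selecting the active topography (self-transition
probability controls dwell time; ~0.95 at 250 Hz gives the ~80 ms mean
dwell typical of real microstates), per-sample positive amplitudes, and
additive spatially independent 1/f^alpha background noise scaled to a
target SNR.  Multi-subject "studies" stack independently seeded epochs
over subjects x conditions x trials, with per-condition overrides of the
sequence parameters, and carry a ground-truth table.

All randomness flows from a single seed through named child streams
(templates / sequence / amplitudes / noise), so identical seeds give
bitwise-identical data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .io_preprocess import EEGRecording, Epoch, write_recording
from .microstate import LabelSequence, TemplateSet, spatial_correlation

__all__ = [
    "SynthConfig",
    "StudyDesign",
    "StudyEpoch",
    "generate_templates",
    "generate_label_sequence",
    "generate_eeg",
    "generate_study",
    "default_transition_matrix",
]


def default_transition_matrix(K: int, self_prob: float = 0.95) -> np.ndarray:
    """Uniform off-diagonal chain with a given self-transition probability.

    self_prob=0.95 at 250 Hz yields a geometric dwell with mean
    1/(1-0.95) = 20 samples = 80 ms.
    """
    if K == 1:
        return np.ones((1, 1))
    T = np.full((K, K), (1 - self_prob) / (K - 1))
    np.fill_diagonal(T, self_prob)
    return T


@dataclass
class SynthConfig:
    """Parameters of one synthetic recording.

    snr_db is the ratio of template-signal power to noise power in dB;
    noise_exponent is the alpha of the 1/f^alpha channel noise.
    """

    n_channels: int = 30
    K: int = 5
    transition_matrix: np.ndarray | None = None
    fs: float = 250.0
    duration: float = 3.0
    snr_db: float = 20.0
    noise_exponent: float = 1.0
    amplitude_mean: float = 1.0
    amplitude_sd: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if self.fs <= 0 or self.duration <= 0:
            raise ValueError("fs and duration must be positive")
        if self.noise_exponent < 0:
            raise ValueError("noise_exponent must be >= 0")
        if self.transition_matrix is None:
            self.transition_matrix = default_transition_matrix(self.K)
        self.transition_matrix = _validate_stochastic(self.transition_matrix, self.K)

    @property
    def n_samples(self) -> int:
        return int(round(self.fs * self.duration))


def _validate_stochastic(T, K: int) -> np.ndarray:
    T = np.asarray(T, dtype=float)
    if T.shape != (K, K):
        raise ValueError(f"transition matrix must be {K}x{K}, got {T.shape}")
    if np.any(T < 0) or np.any(np.abs(T.sum(axis=1) - 1.0) > 1e-12):
        raise ValueError("transition matrix rows must be non-negative and sum to 1")
    return T


def _streams(seed: int, *names: str) -> dict[str, np.random.Generator]:
    """Independent named generator streams derived from one seed."""
    root = np.random.SeedSequence(seed)
    children = root.spawn(len(names))
    return {n: np.random.default_rng(c) for n, c in zip(names, children)}


# ---------------------------------------------------------------------------
# templates
# ---------------------------------------------------------------------------

def generate_templates(
    n_channels: int, K: int, seed: int, max_abs_corr: float = 0.5, max_tries: int = 2000
) -> TemplateSet:
    """K random zero-mean unit-norm topographies with bounded similarity.

    Maps are drawn by rejection: each candidate is a zero-meaned,
    normalised Gaussian vector accepted when its absolute spatial
    correlation with every accepted map stays below ``max_abs_corr``.
    """
    if K > n_channels:
        raise ValueError(
            f"cannot place {K} quasi-orthogonal zero-mean maps on {n_channels} channels"
        )
    rng = _streams(seed, "templates")["templates"]
    maps: list[np.ndarray] = []
    tries = 0
    while len(maps) < K:
        tries += 1
        if tries > max_tries:
            raise ValueError(
                f"could not draw {K} maps with pairwise |corr| <= {max_abs_corr} "
                f"on {n_channels} channels"
            )
        v = rng.standard_normal(n_channels)
        v -= v.mean()
        norm = np.linalg.norm(v)
        if norm == 0:
            continue
        v /= norm
        if maps and np.abs(spatial_correlation(v[None, :], np.vstack(maps))).max() > max_abs_corr:
            continue
        maps.append(v)
    return TemplateSet(maps=np.vstack(maps))


# ---------------------------------------------------------------------------
# label sequence
# ---------------------------------------------------------------------------

def stationary_distribution(T: np.ndarray) -> np.ndarray:
    """Stationary vector of a row-stochastic matrix (left Perron vector)."""
    vals, vecs = np.linalg.eig(T.T)
    i = int(np.argmin(np.abs(vals - 1.0)))
    v = np.real(vecs[:, i])
    v = np.abs(v)
    return v / v.sum()


def generate_label_sequence(config: SynthConfig, start_state: int | None = None) -> LabelSequence:
    """Simulate the first-order Markov label chain of a recording.

    The start state is drawn from the chain's stationary distribution
    unless given explicitly (1-based).
    """
    T = config.transition_matrix
    rng = _streams(config.seed, "sequence")["sequence"]
    n = config.n_samples
    cdf = T.cumsum(axis=1)
    labels = np.empty(n, dtype=np.int64)
    if start_state is None:
        pi = stationary_distribution(T)
        state = int(rng.choice(config.K, p=pi))
    else:
        if not 1 <= start_state <= config.K:
            raise ValueError("start_state out of range")
        state = start_state - 1
    u = rng.random(n)
    for t in range(n):
        labels[t] = state + 1
        if t < n - 1:
            state = int(np.searchsorted(cdf[state], u[t + 1], side="right"))
            state = min(state, config.K - 1)  # guard FP roundoff
    return LabelSequence(labels=labels, fs=config.fs, K=config.K)


# ---------------------------------------------------------------------------
# EEG synthesis
# ---------------------------------------------------------------------------

def _one_over_f_noise(rng: np.random.Generator, n_channels: int, n: int, alpha: float) -> np.ndarray:
    """Spatially independent noise with a 1/f^alpha power spectrum, unit power."""
    white = rng.standard_normal((n_channels, n))
    if alpha == 0:
        noise = white
    else:
        spec = np.fft.rfft(white, axis=1)
        f = np.fft.rfftfreq(n)
        shaping = np.ones_like(f)
        shaping[1:] = f[1:] ** (-alpha / 2.0)
        shaping[0] = 0.0  # no DC drift
        noise = np.fft.irfft(spec * shaping, n=n, axis=1)
    power = np.mean(noise**2)
    return noise / np.sqrt(power)


def generate_eeg(
    templates: TemplateSet, label_sequence: LabelSequence, config: SynthConfig
) -> EEGRecording:
    """Render a label sequence into a noisy multichannel recording.

    Sample t is amplitude_t x map(label_t) plus 1/f^alpha noise scaled so
    that the realised signal-to-noise power ratio equals snr_db exactly.
    """
    if templates.n_channels != config.n_channels:
        raise ValueError("template channel count does not match config")
    labels = label_sequence.labels
    if labels.min() < 1 or labels.max() > templates.K:
        raise ValueError("label outside template range")
    rngs = _streams(config.seed, "amplitudes", "noise")
    n = labels.size
    amps = np.abs(rngs["amplitudes"].normal(config.amplitude_mean, config.amplitude_sd, size=n))
    sig = templates.maps[labels - 1].T * amps  # (n_channels, n)
    sig_power = np.mean(sig**2)
    noise = _one_over_f_noise(rngs["noise"], config.n_channels, n, config.noise_exponent)
    noise_power = sig_power / 10.0 ** (config.snr_db / 10.0)
    data = sig + noise * np.sqrt(noise_power)
    chans = [f"CH{i + 1}" for i in range(config.n_channels)]
    return EEGRecording(data=data, fs=config.fs, channel_labels=chans, reference="raw")


# ---------------------------------------------------------------------------
# study-level generation
# ---------------------------------------------------------------------------

@dataclass
class StudyDesign:
    """A multi-subject repeated-measures design.

    Each condition maps to a dict of :class:`SynthConfig` field overrides
    (e.g. a different transition matrix or dwell probability); every
    subject contributes ``trials_per_condition`` epochs per condition.
    """

    n_subjects: int = 30
    conditions: dict[str, dict] = field(
        default_factory=lambda: {"normal": {}, "low_light": {}, "noise": {}}
    )
    trials_per_condition: int = 30
    base_config: SynthConfig = field(default_factory=SynthConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("need at least 1 subject")
        if not self.conditions:
            raise ValueError("need at least 1 condition")
        if self.trials_per_condition < 1:
            raise ValueError("need at least 1 trial per condition")


@dataclass
class StudyEpoch:
    """One generated trial: the epoch, its true labels, and its config."""

    subject: int
    condition: str
    trial: int
    epoch: Epoch
    true_labels: LabelSequence
    config: SynthConfig


def generate_study(
    design: StudyDesign, include_eeg: bool = True
) -> tuple[list[StudyEpoch], TemplateSet, "pandas.DataFrame"]:
    """Generate every (subject, condition, trial) epoch plus ground truth.

    Returns (epochs, templates, truth_table).  The truth table records
    each condition's true sequence parameters (self-transition
    probability, stationary distribution, SNR).  ``include_eeg=False``
    skips EEG rendering (labels only), which is useful for large
    simulation studies of the downstream statistics.
    """
    import pandas as pd

    base = design.base_config
    templates = generate_templates(base.n_channels, base.K, seed=design.seed)
    epochs: list[StudyEpoch] = []
    truth_rows = []
    cond_list = list(design.conditions)
    for ci, cond in enumerate(cond_list):
        cfg_cond = replace(base, **design.conditions[cond])
        pi = stationary_distribution(cfg_cond.transition_matrix)
        truth_rows.append(
            {
                "condition": cond,
                "self_transition": float(np.diag(cfg_cond.transition_matrix).mean()),
                "stationary_max": float(pi.max()),
                "snr_db": cfg_cond.snr_db,
                "fs": cfg_cond.fs,
                "duration": cfg_cond.duration,
            }
        )
        for s in range(design.n_subjects):
            for tr in range(design.trials_per_condition):
                # deterministic per-trial seed below 2**31
                trial_seed = (
                    design.seed * 1_000_003 + s * 7919 + ci * 104_729 + tr * 13
                ) % (2**31 - 1)
                cfg = replace(cfg_cond, seed=trial_seed)
                seq = generate_label_sequence(cfg)
                if include_eeg:
                    rec = generate_eeg(templates, seq, cfg)
                    ep = Epoch(data=rec.data, fs=cfg.fs, t0_offset=-cfg.duration)
                else:
                    ep = None
                epochs.append(
                    StudyEpoch(
                        subject=s, condition=cond, trial=tr,
                        epoch=ep, true_labels=seq, config=cfg,
                    )
                )
    return epochs, templates, pd.DataFrame(truth_rows)


def write_study(epochs: list[StudyEpoch], templates: TemplateSet, out_dir) -> None:
    """Write each trial as a CSV matrix with a JSON ground-truth sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    np.savetxt(out / "templates.csv", templates.maps, delimiter=",")
    for se in epochs:
        stem = f"sub{se.subject:02d}_{se.condition}_trial{se.trial:03d}"
        if se.epoch is not None:
            rec = EEGRecording(
                data=se.epoch.data, fs=se.epoch.fs,
                channel_labels=[f"CH{i + 1}" for i in range(se.epoch.n_channels)],
            )
            write_recording(rec, out / f"{stem}.csv")
        sidecar = {
            "subject": se.subject,
            "condition": se.condition,
            "trial": se.trial,
            "fs": se.config.fs,
            "snr_db": se.config.snr_db,
            "labels": se.true_labels.labels.tolist(),
        }
        (out / f"{stem}.json").write_text(json.dumps(sidecar))
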