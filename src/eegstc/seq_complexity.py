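"""Complexity metrics of symbolic microstate sequences.

Six metrics characterise the dynamics of a microstate label sequence:

* Ms-LZC - Lempel-Ziv phrase-dictionary size of the sequence over its
  native K-letter alphabet, normalised by the mean dictionary size of
  random reorderings of the same sequence.
* Ms-MIG - mean information gain, -sum_ij p_ij log2 p_{i->j}: expected
  surprisal of the next state given the current one.  0 for constant or
  deterministic dynamics, log2 N in the i.i.d. uniform limit.
* Ms-FC - fluctuation complexity, sum_ij p_ij (log2 (p_i / p_j))^2: the
  mean squared net information gain across transitions; 0 whenever the
  stationary distribution is uniform.
* Ms-SE - Shannon entropy of the empirical state distribution.
* Ms-ER / Ms-EE - entropy rate and excess entropy: slope and intercept
  of the block entropy H_k fitted as H_k ~ h k + E over k = 1..k_max.

Probabilities are estimated by plug-in counts.  Transition counting is
sample-level by default (consecutive samples, self-transitions included),
which keeps the metrics sensitive to dwell time; ``include_self=False``
switches to run-level counting on the run-compressed sequence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from ._lz import lz76_phrase_count
from .microstate import LabelSequence

__all__ = [
    "TransitionModel",
    "transition_model",
    "ms_lzc",
    "ms_mig",
    "ms_fc",
    "ms_se",
    "ms_entropy_rate_excess",
    "sequence_metrics",
]


def _labels(seq) -> np.ndarray:
    if isinstance(seq, LabelSequence):
        return seq.labels
    arr = np.asarray(seq, dtype=np.int64)
    if arr.ndim != 1:
        raise ValueError("expected a 1-D label sequence")
    return arr


def _n_states(seq, labels: np.ndarray) -> int:
    return seq.K if isinstance(seq, LabelSequence) else int(labels.max())


@dataclass
class TransitionModel:
    """Empirical first-order statistics of a symbolic sequence.

    p : stationary (marginal) probability per state, length N.
    p_joint : probability of the consecutive pair (i, j), N x N.
    p_cond : p_{i->j} = p_joint / p_i with the 0/0 := 0 convention.
    """

    p: np.ndarray
    p_joint: np.ndarray
    p_cond: np.ndarray

    @property
    def n_states(self) -> int:
        return self.p.size


def transition_model(seq, include_self: bool = True) -> TransitionModel:
    """Estimate (p_i, p_ij, p_{i->j}) from a label sequence.

    ``include_self=False`` first collapses runs so that only segment-to-
    segment transitions are counted (marginals are then run frequencies).
    """
    labels = _labels(seq)
    n_states = _n_states(seq, labels)
    if not include_self:
        keep = np.concatenate(([True], np.diff(labels) != 0))
        labels = labels[keep]
    if labels.size < 2:
        raise ValueError("need at least 2 symbols to estimate transitions")
    idx = labels - 1
    p = np.bincount(idx, minlength=n_states) / labels.size
    joint = np.zeros((n_states, n_states))
    np.add.at(joint, (idx[:-1], idx[1:]), 1.0)
    joint /= idx.size - 1
    # conditional on the *pair-origin* marginal so rows normalise exactly
    row = joint.sum(axis=1, keepdims=True)
    cond = np.divide(joint, row, out=np.zeros_like(joint), where=row > 0)
    return TransitionModel(p=p, p_joint=joint, p_cond=cond)


def ms_lzc(seq, n_shuffles: int = 20, seed=None) -> float:
    """Lempel-Ziv complexity ratio of a label sequence.

    LZ76 phrase count of the sequence divided by the mean phrase count
    over ``n_shuffles`` uniform random permutations of the same symbols.
    Values below 1 indicate structure beyond the symbol frequencies; an
    i.i.d. sequence scores ~1.
    """
    labels = _labels(seq)
    if labels.size < 2:
        raise ValueError("sequence too short")
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    rng = np.random.default_rng(seed)
    c = lz76_phrase_count(labels)
    c_rand = np.mean([lz76_phrase_count(rng.permutation(labels)) for _ in range(n_shuffles)])
    return float(c / c_rand)


def ms_mig(model: TransitionModel) -> float:
    """Mean information gain in bits: -sum_ij p_ij log2 p_{i->j}."""
    mask = model.p_joint > 0
    return float(-(model.p_joint[mask] * np.log2(model.p_cond[mask])).sum()) + 0.0


def ms_fc(model: TransitionModel) -> float:
    """Fluctuation complexity in bits^2: sum_ij p_ij (log2(p_i/p_j))^2."""
    p = model.p
    mask = model.p_joint > 0
    i, j = np.nonzero(mask)
    terms = model.p_joint[mask] * (np.log2(p[i] / p[j])) ** 2
    return float(terms.sum())


def ms_se(seq) -> float:
    """Shannon entropy of the empirical state distribution, in bits."""
    labels = _labels(seq)
    p = np.bincount(labels - 1, minlength=_n_states(seq, labels)) / labels.size
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def block_entropies(seq, k_max: int) -> np.ndarray:
    """Plug-in joint entropy H_k of overlapping length-k blocks, k=1..k_max."""
    labels = _labels(seq)
    n_states = _n_states(seq, labels)
    n = labels.size
    out = np.empty(k_max)
    codes = (labels - 1).astype(np.int64)
    block = np.zeros(n, dtype=np.int64)
    for k in range(1, k_max + 1):
        m = n - k + 1
        if m < 1:
            raise ValueError(f"sequence of length {n} has no blocks of length {k}")
        # integer-encode blocks incrementally in base n_states
        block = block[:m] * n_states + codes[k - 1 : k - 1 + m]
        _, counts = np.unique(block, return_counts=True)
        p = counts / m
        out[k - 1] = -(p * np.log2(p)).sum()
    return out


def ms_entropy_rate_excess(seq, k_max: int = 6) -> tuple[float, float]:
    """Entropy rate h (bits/symbol) and excess entropy E (bits).

    Block entropies H_k are fitted by ordinary least squares as
    H_k ~ h k + E over k = 1..k_max.  k_max is capped adaptively so that
    the number of blocks stays at least 10x the alphabet-to-the-k block
    count (never below 2, so the line remains identifiable); a warning is
    emitted when capping occurs.  The slope is floored at 0.
    """
    labels = _labels(seq)
    n_states = _n_states(seq, labels)
    n = labels.size
    if n < 10 * k_max:
        raise ValueError(f"sequence of length {n} too short for k_max={k_max}")
    k_eff = k_max
    while k_eff > 2 and 10 * float(n_states) ** k_eff > n:
        k_eff -= 1
    if k_eff < k_max:
        warnings.warn(
            f"block-entropy support is thin; capping k_max {k_max} -> {k_eff}"
        )
    ks = np.arange(1, k_eff + 1)
    H = block_entropies(labels, k_eff)
    h, E = np.polyfit(ks, H, 1)
    if h < 0:
        h, E = 0.0, float(H.mean())
    return float(h), float(E)


def sequence_metrics(seq, n_shuffles: int = 20, seed=None, k_max: int = 6) -> dict[str, float]:
    """All six sequence metrics as a flat dict (Ms-ER/Ms-EE share one fit)."""
    model = transition_model(seq)
    h, E = ms_entropy_rate_excess(seq, k_max=k_max)
    return {
        "ms_lzc": ms_lzc(seq, n_shuffles=n_shuffles, seed=seed),
        "ms_mig": ms_mig(model),
        "ms_fc": ms_fc(model),
        "ms_se": ms_se(seq),
        "ms_er": h,
        "ms_ee": E,
    }
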