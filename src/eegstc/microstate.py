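"""EEG microstate segmentation.

Microstates are brief (~80 ms) periods during which the scalp potential
topography stays quasi-stable.  Segmentation proceeds in the classical
order: compute global field power (GFP), extract the topographies at GFP
local maxima, cluster them with polarity-invariant atomize-and-agglomerate
hierarchical clustering (AAHC), pick the number of templates K by the
elbow of the sum-of-squared-errors curve subject to a global-explained-
variance (GEV) floor, then back-fit the templates to every sample to
obtain a symbolic microstate sequence.

Topographies are plain 1-D arrays (one value per channel); all spatial
correlations are Pearson correlations across channels, and every
comparison is polarity-invariant (a map and its negation are the same
microstate).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "TemplateSet",
    "LabelSequence",
    "MicrostateParams",
    "gfp",
    "gfp_peaks",
    "spatial_correlation",
    "aahc_cluster",
    "gev",
    "sse",
    "select_k_elbow",
    "backfit",
    "microstate_params",
    "fit_microstates",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class TemplateSet:
    """K microstate template maps plus fit diagnostics.

    maps : (K, n_channels) array, each row zero-mean across channels and
        unit L2 norm.
    gev_total : fraction of GFP-weighted variance explained, in [0, 1];
        ``None`` until evaluated on data.
    gev_per_template : per-template share of the total GEV.
    sse : sum of squared residuals of the least-squares template fit.
    """

    maps: np.ndarray
    gev_total: float | None = None
    gev_per_template: np.ndarray | None = None
    sse: float | None = None

    def __post_init__(self) -> None:
        self.maps = np.atleast_2d(np.asarray(self.maps, dtype=float))
        if not np.all(np.isfinite(self.maps)):
            raise ValueError("template maps must be finite")

    @property
    def K(self) -> int:
        return self.maps.shape[0]

    @property
    def n_channels(self) -> int:
        return self.maps.shape[1]


@dataclass
class LabelSequence:
    """Per-sample microstate labels drawn from the alphabet {1..K}."""

    labels: np.ndarray
    fs: float
    K: int

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.labels.ndim != 1 or self.labels.size < 1:
            raise ValueError("labels must be a non-empty 1-D array")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.labels.min() < 1 or self.labels.max() > self.K:
            raise ValueError(f"labels must lie in 1..{self.K}")

    def __len__(self) -> int:
        return self.labels.size

    @property
    def duration(self) -> float:
        return self.labels.size / self.fs


@dataclass
class MicrostateParams:
    """Conventional microstate statistics of a label sequence.

    coverage : fraction of samples spent in each state (sums to 1).
    mean_duration_ms : mean contiguous-run length per state, in ms
        (NaN for states that never occur).
    occurrence : runs per second per state.
    transition_matrix : run-level (segment-to-segment) transition
        probabilities; row i sums to 1 when state i has outgoing
        transitions, and is all-zero otherwise.
    """

    coverage: np.ndarray
    mean_duration_ms: np.ndarray
    occurrence: np.ndarray
    transition_matrix: np.ndarray


# ---------------------------------------------------------------------------
# GFP and peak extraction
# ---------------------------------------------------------------------------

def gfp(data: np.ndarray) -> np.ndarray:
    """Global field power: spatial standard deviation per sample.

    GFP(t) = sqrt( sum_i (u_i(t) - ubar(t))^2 / N ) over the N channels.

    Parameters
    ----------
    data : (n_channels, n_samples) array.
    """
    data = np.atleast_2d(np.asarray(data, dtype=float))
    if data.shape[0] < 2:
        raise ValueError("GFP requires at least 2 channels")
    return data.std(axis=0, ddof=0)


def gfp_peaks(gfp_series: np.ndarray) -> np.ndarray:
    """Indices of strict local maxima of a GFP curve (endpoints excluded)."""
    g = np.asarray(gfp_series, dtype=float)
    if g.ndim != 1 or g.size < 3:
        raise ValueError("need a 1-D series of length >= 3")
    interior = (g[1:-1] > g[:-2]) & (g[1:-1] > g[2:])
    return np.flatnonzero(interior) + 1


# ---------------------------------------------------------------------------
# spatial correlation helpers
# ---------------------------------------------------------------------------

def _center_norm(maps: np.ndarray) -> np.ndarray:
    """Zero-mean each row across channels and scale to unit norm.

    Rows with zero spatial variance come back as all-zero (correlation 0
    with everything); callers decide how to treat them.
    """
    m = np.atleast_2d(np.asarray(maps, dtype=float))
    m = m - m.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(m, axis=1, keepdims=True)
    with np.errstate(invalid="ignore"):
        out = np.where(norms > 0, m / np.where(norms == 0, 1.0, norms), 0.0)
    return out


def spatial_correlation(maps_a: np.ndarray, maps_b: np.ndarray) -> np.ndarray:
    """Pearson correlation across channels between rows of two map sets.

    Returns an (n_a, n_b) matrix; signed (take ``abs`` for the
    polarity-invariant similarity used throughout microstate analysis).
    """
    a = _center_norm(maps_a)
    b = _center_norm(maps_b)
    return a @ b.T


# ---------------------------------------------------------------------------
# GEV and SSE
# ---------------------------------------------------------------------------

def gev(
    templates: TemplateSet | np.ndarray,
    maps: np.ndarray,
    gfp_values: np.ndarray,
    assignment: np.ndarray | None = None,
) -> tuple[float, np.ndarray]:
    """Global explained variance of a template fit.

    GEV = sum_n GFP_n^2 Corr(x_n, a_{l_n})^2 / sum_n GFP_n^2, where l_n is
    each map's assigned template (argmax |corr| if not supplied).

    Returns
    -------
    (gev_total, gev_per_template)
    """
    tmaps = templates.maps if isinstance(templates, TemplateSet) else np.atleast_2d(templates)
    maps = np.atleast_2d(maps)
    g2 = np.asarray(gfp_values, dtype=float) ** 2
    denom = g2.sum()
    if denom <= 0:
        raise ValueError("total GFP power is zero; GEV undefined")
    corr = np.abs(spatial_correlation(maps, tmaps))
    if assignment is None:
        assignment = corr.argmax(axis=1)
    else:
        assignment = np.asarray(assignment, dtype=int)
    c = corr[np.arange(maps.shape[0]), assignment]
    contrib = g2 * c**2
    per_t = np.bincount(assignment, weights=contrib, minlength=tmaps.shape[0]) / denom
    return float(per_t.sum()), per_t


def sse(templates: TemplateSet | np.ndarray, data: np.ndarray) -> float:
    """Sum of squared residuals of the best-template fit to each sample.

    Each sample map x is assigned to its max-|corr| template t and the
    residual is ||x - a t||^2 with the least-squares amplitude
    a = <x, t> / <t, t>.  The signed amplitude keeps the distance
    polarity-invariant, matching the clustering.
    """
    tmaps = templates.maps if isinstance(templates, TemplateSet) else np.atleast_2d(templates)
    x = np.atleast_2d(np.asarray(data, dtype=float))
    t = _center_norm(tmaps)  # unit-norm -> a = <x, t>
    xc = x - x.mean(axis=1, keepdims=True)
    corr = np.abs(spatial_correlation(xc, t))
    assign = corr.argmax(axis=1)
    a = np.einsum("ij,ij->i", xc, t[assign])
    resid = xc - a[:, None] * t[assign]
    return float(np.sum(resid**2))


# ---------------------------------------------------------------------------
# AAHC clustering
# ---------------------------------------------------------------------------

def _principal_map(members: np.ndarray) -> np.ndarray:
    """Polarity-invariant cluster centroid: leading right singular vector."""
    if members.shape[0] == 1:
        v = members[0]
        n = np.linalg.norm(v)
        return v / n if n > 0 else v
    # economy SVD of (m, n_ch); first right singular vector maximises
    # sum of squared projections regardless of each member's sign
    _, _, vt = np.linalg.svd(members, full_matrices=False)
    return vt[0]


def aahc_cluster(
    peak_maps: np.ndarray,
    k_range=range(1, 11),
    gfp_values: np.ndarray | None = None,
) -> dict[int, TemplateSet]:
    """Polarity-invariant AAHC over GFP-peak topographies.

    Every map starts as a singleton cluster; at each step the cluster
    contributing least to the total GEV is atomised and its members are
    re-assigned to the remaining clusters by maximal absolute spatial
    correlation.  A :class:`TemplateSet` (with GEV and SSE evaluated on
    the peak maps) is recorded whenever the cluster count hits a value in
    ``k_range``.

    Parameters
    ----------
    peak_maps : (n_maps, n_channels) topographies at GFP peaks.
    k_range : iterable of K values to report (need n_maps >= max K).
    gfp_values : per-map GFP used as GEV weights; computed from the maps
        themselves when omitted.
    """
    X = np.atleast_2d(np.asarray(peak_maps, dtype=float))
    ks = sorted(set(int(k) for k in k_range))
    if ks[0] < 1:
        raise ValueError("K values must be >= 1")
    n_maps = X.shape[0]
    if n_maps < ks[-1]:
        raise ValueError(f"{n_maps} maps cannot support K={ks[-1]}")
    if gfp_values is None:
        gfp_values = X.std(axis=1, ddof=0)
    w = np.asarray(gfp_values, dtype=float) ** 2
    total_w = w.sum()
    if total_w <= 0:
        raise ValueError("total GFP power is zero")

    Xn = _center_norm(X)  # normalised maps used for correlations
    # cluster bookkeeping
    members: list[list[int]] = [[i] for i in range(n_maps)]
    centroids = Xn.copy()
    corr2 = np.ones(n_maps)  # squared corr of each map with its centroid
    assign = np.arange(n_maps)

    results: dict[int, TemplateSet] = {}

    def snapshot(k: int) -> None:
        order = np.argsort([-w[m].sum() for m in members])  # heaviest first
        maps_k = np.vstack([centroids[i] for i in order])
        remap = {int(old): new for new, old in enumerate(order)}
        assign_k = np.array([remap[int(a)] for a in assign])
        total, per_t = gev(maps_k, X, gfp_values, assignment=assign_k)
        results[k] = TemplateSet(
            maps=maps_k, gev_total=total, gev_per_template=per_t, sse=sse(maps_k, X)
        )

    if n_maps in ks:
        snapshot(n_maps)

    n_clusters = n_maps
    while n_clusters > 1:
        # GEV contribution of each live cluster
        contribs = np.array([w[m] @ corr2[m] for m in members])
        worst = int(np.argmin(contribs))
        orphan = members.pop(worst)
        centroids = np.delete(centroids, worst, axis=0)
        n_clusters -= 1
        assign[assign > worst] -= 1
        # re-assign orphans by max |corr| with remaining centroids
        c = np.abs(Xn[orphan] @ centroids.T)
        new_home = c.argmax(axis=1)
        touched = set()
        for idx, home in zip(orphan, new_home):
            members[int(home)].append(int(idx))
            assign[idx] = int(home)
            touched.add(int(home))
        # refresh centroids (and member correlations) of clusters that grew
        for ci in touched:
            m = members[ci]
            centroids[ci] = _principal_map(Xn[m])
            corr2[m] = (Xn[m] @ centroids[ci]) ** 2
        if n_clusters in ks:
            snapshot(n_clusters)

    return results


# ---------------------------------------------------------------------------
# model-order selection
# ---------------------------------------------------------------------------

def select_k_elbow(
    sse_by_k: dict[int, float],
    gev_by_k: dict[int, float],
    gev_threshold: float = 0.65,
) -> int:
    """Pick K at the elbow of the SSE curve, subject to a GEV floor.

    The elbow is the K maximising the discrete second difference
    SSE(K-1) - 2 SSE(K) + SSE(K+1) over the interior of a contiguous K
    range, restricted to K whose GEV reaches ``gev_threshold``; ties go
    to the smallest K.  A flat (curvature-free) SSE curve falls back to
    the smallest admissible K with a warning.
    """
    ks = sorted(sse_by_k)
    if ks != list(range(ks[0], ks[-1] + 1)):
        raise ValueError("SSE must be given on a contiguous K range")
    admissible = [k for k in ks if gev_by_k.get(k, 0.0) >= gev_threshold]
    if not admissible:
        attained = {k: round(gev_by_k.get(k, 0.0), 4) for k in ks}
        raise ValueError(
            f"no K reaches GEV threshold {gev_threshold}; attained GEVs: {attained}"
        )
    sse_arr = np.array([sse_by_k[k] for k in ks], dtype=float)
    d2 = sse_arr[:-2] - 2 * sse_arr[1:-1] + sse_arr[2:]  # at ks[1:-1]
    interior = {ks[i + 1]: d2[i] for i in range(len(d2))}
    candidates = [k for k in admissible if k in interior]
    scale = max(abs(sse_arr).max(), 1.0)
    if not candidates or max(interior[k] for k in candidates) <= 1e-10 * scale:
        warnings.warn(
            "SSE curve has no elbow; falling back to smallest K passing the GEV threshold"
        )
        return admissible[0]
    best = max(interior[k] for k in candidates)
    return min(k for k in candidates if interior[k] == best)


def fit_microstates(
    data: np.ndarray,
    fs: float,
    k_range=range(1, 11),
    gev_threshold: float = 0.65,
    max_maps: int = 2000,
    seed: int | None = 0,
) -> tuple[TemplateSet, int, dict[int, TemplateSet]]:
    """End-to-end template fitting: GFP peaks -> AAHC -> elbow selection.

    When the recording yields more than ``max_maps`` GFP-peak maps, a
    seeded random subsample keeps the clustering tractable (standard
    practice; GFP peaks are highly redundant).

    Returns (selected TemplateSet, selected K, TemplateSet per K).
    """
    data = np.atleast_2d(np.asarray(data, dtype=float))
    g = gfp(data)
    peaks = gfp_peaks(g)
    if peaks.size > max_maps:
        rng = np.random.default_rng(seed)
        peaks = np.sort(rng.choice(peaks, size=max_maps, replace=False))
    maps = data[:, peaks].T
    sets = aahc_cluster(maps, k_range=k_range, gfp_values=g[peaks])
    k = select_k_elbow(
        {k: ts.sse for k, ts in sets.items()},
        {k: ts.gev_total for k, ts in sets.items()},
        gev_threshold=gev_threshold,
    )
    return sets[k], k, sets


# ---------------------------------------------------------------------------
# back-fitting and conventional parameters
# ---------------------------------------------------------------------------

def backfit(templates: TemplateSet | np.ndarray, data: np.ndarray, fs: float) -> LabelSequence:
    """Label every sample with its max-|corr| template (1-based labels).

    Ties go to the lowest template index.  Samples with zero spatial
    variance (undefined correlation) inherit the previous sample's label
    (label 1 at the start) and are logged.
    """
    tmaps = templates.maps if isinstance(templates, TemplateSet) else np.atleast_2d(templates)
    x = np.atleast_2d(np.asarray(data, dtype=float))
    if x.shape[0] != tmaps.shape[1]:
        raise ValueError(
            f"channel mismatch: data has {x.shape[0]}, templates expect {tmaps.shape[1]}"
        )
    samples = x.T  # (n_samples, n_channels)
    corr = np.abs(spatial_correlation(samples, tmaps))
    labels = corr.argmax(axis=1) + 1
    flat = samples.std(axis=1, ddof=0) == 0
    if flat.any():
        logger.warning("%d zero-variance samples inherited the previous label", flat.sum())
        labels = labels.astype(np.int64)
        prev = 1
        for i in range(labels.size):
            if flat[i]:
                labels[i] = prev
            else:
                prev = labels[i]
    return LabelSequence(labels=labels, fs=fs, K=tmaps.shape[0])


def microstate_params(seq: LabelSequence) -> MicrostateParams:
    """Coverage, mean duration, occurrence and run-level transitions."""
    labels = seq.labels
    K = seq.K
    n = labels.size
    coverage = np.bincount(labels - 1, minlength=K) / n
    # run-length encode
    change = np.flatnonzero(np.diff(labels)) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [n]))
    run_states = labels[starts] - 1
    run_lengths = ends - starts
    mean_dur = np.full(K, np.nan)
    occurrence = np.zeros(K)
    for k in range(K):
        mask = run_states == k
        if mask.any():
            mean_dur[k] = run_lengths[mask].mean() / seq.fs * 1000.0
            occurrence[k] = mask.sum() / (n / seq.fs)
    trans = np.zeros((K, K))
    if run_states.size > 1:
        np.add.at(trans, (run_states[:-1], run_states[1:]), 1.0)
        row = trans.sum(axis=1, keepdims=True)
        trans = np.divide(trans, row, out=np.zeros_like(trans), where=row > 0)
    return MicrostateParams(
        coverage=coverage,
        mean_duration_ms=mean_dur,
        occurrence=occurrence,
        transition_matrix=trans,
    )
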