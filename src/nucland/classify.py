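"""Voxel-intensity density classification.

Masked DAPI intensities are modeled as a K-component Gaussian mixture with a
single shared standard deviation ("equal intensity variance"). Classification
is threshold-independent: with spatial coupling ``beta = 0`` each voxel is
assigned the class maximizing its posterior; with ``beta > 0`` labels are the
ICM fixed point of the hidden-Markov-random-field posterior with a Potts
neighbor penalty. Class 1 is always the lowest-intensity class (near
background); class K the densest.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .model import NuclearMask, VoxelGrid

__all__ = [
    "MixtureParams",
    "ClassMap",
    "ClassDistribution",
    "fit_mixture",
    "classify_voxels",
    "class_distribution",
]

_LOG_2PI = float(np.log(2.0 * np.pi))


@dataclass
class MixtureParams:
    """Equal-variance Gaussian mixture with optional Potts coupling.

    ``means`` are strictly increasing so that class ``c`` (1-based) is the
    c-th lowest intensity band. ``beta`` is the Potts coupling (>= 0; the
    reference analysis uses 0). ``neighborhood`` selects 6/18/26-connectivity
    for the spatial term.
    """

    K: int
    means: np.ndarray
    shared_sd: float
    weights: np.ndarray
    beta: float = 0.0
    neighborhood: int = 26
    converged: bool = True
    log_likelihood: float = float("nan")
    n_iter: int = 0
    ll_traces: list = field(default_factory=list)  # per-EM-phase iteration traces

    def __post_init__(self) -> None:
        self.means = np.asarray(self.means, dtype=np.float64)
        self.weights = np.asarray(self.weights, dtype=np.float64)
        if self.means.shape != (self.K,) or self.weights.shape != (self.K,):
            raise ValueError("means/weights must have length K")
        if np.any(np.diff(self.means) < 0):
            raise ValueError("means must be sorted ascending")
        if self.shared_sd <= 0:
            raise ValueError("shared_sd must be positive")
        if np.any(self.weights < 0) or abs(self.weights.sum() - 1.0) > 1e-9:
            raise ValueError("weights must be a probability vector")
        if self.beta < 0:
            raise ValueError("beta must be >= 0")
        if self.neighborhood not in (6, 18, 26):
            raise ValueError("neighborhood must be 6, 18 or 26")


@dataclass
class ClassMap:
    """Per-voxel class labels: 0 outside the mask, 1..K inside."""

    labels: np.ndarray
    params: MixtureParams
    source_channel: str = ""
    nucleus_id: int = 0

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        inside = self.labels[self.labels > 0]
        if inside.size == 0:
            raise ValueError("class map has no labeled voxels")
        if inside.max() > self.params.K:
            raise ValueError("label exceeds K")

    @property
    def K(self) -> int:
        return self.params.K

    @property
    def n_voxels(self) -> int:
        return int((self.labels > 0).sum())

    def class_counts(self) -> np.ndarray:
        """Voxel count per class, length K (index 0 = class 1)."""
        return np.bincount(self.labels.ravel(), minlength=self.K + 1)[1:].astype(np.int64)


@dataclass
class ClassDistribution:
    """Relative per-class voxel fractions (sum to 1)."""

    fractions: np.ndarray
    n_voxels: int
    per_nucleus: bool = True

    def __post_init__(self) -> None:
        self.fractions = np.asarray(self.fractions, dtype=np.float64)
        if np.any(self.fractions < 0) or abs(self.fractions.sum() - 1.0) > 1e-12:
            raise ValueError("fractions must be non-negative and sum to 1")

    def weighted_mean_class(self) -> float:
        """Intensity-class-weighted mean class, sum_c c * fraction_c."""
        c = np.arange(1, len(self.fractions) + 1)
        return float(np.dot(c, self.fractions))


def _log_component_densities(x: np.ndarray, means: np.ndarray, sd: float) -> np.ndarray:
    # (n, K) log N(x | mu_c, sd); shared sd so the -log sd term is common
    z = (x[:, None] - means[None, :]) / sd
    return -0.5 * z * z - np.log(sd) - 0.5 * _LOG_2PI


def fit_mixture(
    intensities: np.ndarray,
    K: int = 7,
    tol: float = 1e-6,
    max_iter: int = 500,
    seed: int = 0,
) -> MixtureParams:
    """EM fit of the equal-variance K-component Gaussian mixture.

    Initialization is deterministic: means at the K quantile midpoints of the
    intensity distribution, uniform weights, shared sd = sample sd. The
    log-likelihood is non-decreasing across iterations; convergence is a
    relative log-likelihood change below ``tol``. ``seed`` is accepted for
    interface stability (no randomness is used by default).
    """
    x = np.asarray(intensities, dtype=np.float64).ravel()
    if x.size < 10 * K:
        raise ValueError(f"need at least {10 * K} voxels to fit K={K} components")
    if np.ptp(x) == 0:
        raise ValueError("degenerate histogram: all intensities equal")
    if K == 1:
        mu = float(x.mean())
        sd = float(x.std())
        return MixtureParams(1, [mu], sd, [1.0], log_likelihood=float(
            np.sum(_log_component_densities(x, np.array([mu]), sd))
        ))

    q = (2.0 * np.arange(K) + 1.0) / (2.0 * K)
    means = np.quantile(x, q)
    # collapse-proof: spread exactly coincident initial means
    for c in range(1, K):
        if means[c] <= means[c - 1]:
            means[c] = means[c - 1] + 1e-9 * max(np.ptp(x), 1.0)
    # initial shared sd from the within-quantile-block spread: a full-sample
    # sd makes the first responsibilities near-uniform and merges components
    edges = np.quantile(x, np.arange(1, K) / K)
    blocks = np.searchsorted(edges, x)
    within_var = 0.0
    for c in range(K):
        xb = x[blocks == c]
        if xb.size:
            within_var += xb.size * xb.var()
    sd = float(np.sqrt(within_var / x.size))
    if sd <= 0:
        sd = float(max(x.std(), 1e-6))
    weights = np.full(K, 1.0 / K)

    ll_traces: list[list[float]] = []

    def _em_phase(means, sd, weights, budget):
        ll = -np.inf
        ll_prev = -np.inf
        used = 0
        converged = False
        trace: list[float] = []
        ll_traces.append(trace)
        for used in range(1, budget + 1):
            logp = _log_component_densities(x, means, sd) + np.log(weights)[None, :]
            norm = logsumexp(logp, axis=1)
            ll = float(norm.sum())
            trace.append(ll)
            resp = np.exp(logp - norm[:, None])  # (n, K)
            nk = resp.sum(axis=0)
            nk = np.maximum(nk, 1e-300)
            weights = nk / x.size
            means = resp.T @ x / nk
            var = float(np.sum(resp * (x[:, None] - means[None, :]) ** 2) / x.size)
            sd = float(np.sqrt(max(var, 1e-300)))
            if np.isfinite(ll_prev) and (ll - ll_prev) <= tol * abs(ll_prev):
                converged = True
                break
            ll_prev = ll
        return means, sd, weights, ll, used, converged

    # quantile-midpoint init can drop two components onto one heavy intensity
    # mode; after convergence, re-seed any collapsed duplicate into the widest
    # gap between adjacent fitted means and continue (deterministic).
    it = 0
    ll = -np.inf
    converged = False
    budget = max_iter
    for _phase in range(2 * K):
        means, sd, weights, ll, used, converged = _em_phase(means, sd, weights, budget)
        it += used
        budget -= used
        srt = np.sort(means)
        gaps = np.diff(srt)
        dup = np.flatnonzero(gaps < 0.1 * sd)
        if dup.size == 0 or budget <= 0:
            break
        order = np.argsort(means, kind="stable")
        widest = int(np.argmax(gaps))
        means[order[dup[0] + 1]] = 0.5 * (srt[widest] + srt[widest + 1])
        converged = False
    order = np.argsort(means, kind="stable")
    params = MixtureParams(
        K,
        means[order],
        sd,
        weights[order],
        converged=converged,
        log_likelihood=ll,
        n_iter=it,
        ll_traces=ll_traces,
    )
    if not converged:
        import warnings

        warnings.warn(f"EM did not converge in {max_iter} iterations", stacklevel=2)
    return params


def log_likelihood(intensities: np.ndarray, params: MixtureParams) -> float:
    """Mixture log-likelihood of a sample under given parameters."""
    x = np.asarray(intensities, dtype=np.float64).ravel()
    logp = _log_component_densities(x, params.means, params.shared_sd)
    return float(logsumexp(logp + np.log(params.weights)[None, :], axis=1).sum())


def _neighbor_offsets(neighborhood: int) -> np.ndarray:
    offs = []
    for dz in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dx in (-1, 0, 1):
                if dz == dy == dx == 0:
                    continue
                order = abs(dz) + abs(dy) + abs(dx)
                if neighborhood == 6 and order > 1:
                    continue
                if neighborhood == 18 and order > 2:
                    continue
                offs.append((dz, dy, dx))
    return np.array(offs)


def _shift(a: np.ndarray, off) -> np.ndarray:
    """Shift with zero fill (labels outside count as background/absent)."""
    out = np.zeros_like(a)
    src = [slice(None)] * 3
    dst = [slice(None)] * 3
    for ax, d in enumerate(off):
        if d > 0:
            src[ax], dst[ax] = slice(0, a.shape[ax] - d), slice(d, None)
        elif d < 0:
            src[ax], dst[ax] = slice(-d, None), slice(0, a.shape[ax] + d)
    out[tuple(dst)] = a[tuple(src)]
    return out


def classify_voxels(dapi: VoxelGrid, mask: NuclearMask, params: MixtureParams) -> ClassMap:
    """Assign every masked voxel a class 1..K.

    With ``beta = 0`` the label is the per-voxel posterior argmax
    ``argmax_c pi_c N(x | mu_c, sd)``. With ``beta > 0``, iterated
    conditional modes minimize ``-log posterior + beta * (# differently
    labeled masked neighbors)``, initialized from the beta = 0 map and
    iterated to label stability (at most 50 sweeps). Ties break toward the
    lower class index.
    """
    if dapi.shape != mask.data.shape:
        raise ValueError("mask/grid shape mismatch")
    m = mask.data
    x = dapi.data[m].astype(np.float64)
    logpost = _log_component_densities(x, params.means, params.shared_sd)
    with np.errstate(divide="ignore"):
        logpost = logpost + np.log(params.weights)[None, :]
    # argmax with ties toward the lower index: reversed argmax of flipped
    # array would pick the last; plain argmax picks the first (lowest class)
    flat_labels = np.argmax(logpost, axis=1).astype(np.int32) + 1
    labels = np.zeros(m.shape, dtype=np.int32)
    labels[m] = flat_labels

    if params.beta > 0:
        offsets = _neighbor_offsets(params.neighborhood)
        mask_f = m.astype(np.int32)
        n_neighbors = np.zeros(m.shape, dtype=np.int32)
        for off in offsets:
            n_neighbors += _shift(mask_f, off)
        full_logpost = np.full(m.shape + (params.K,), -np.inf)
        full_logpost[m] = logpost
        for _ in range(50):
            same = np.zeros(m.shape + (params.K,), dtype=np.int32)
            for off in offsets:
                shifted = _shift(labels, off)
                for c in range(1, params.K + 1):
                    same[..., c - 1] += shifted == c
            energy = -full_logpost + params.beta * (n_neighbors[..., None] - same)
            new_flat = np.argmin(energy[m], axis=1).astype(np.int32) + 1
            if np.array_equal(new_flat, labels[m]):
                break
            labels[m] = new_flat
    return ClassMap(labels, params, source_channel=dapi.channel_name, nucleus_id=mask.nucleus_id)


def class_distribution(classmap: ClassMap) -> ClassDistribution:
    """Relative per-class voxel fractions D_c of the masked volume."""
    counts = classmap.class_counts()
    total = counts.sum()
    if total == 0:
        raise ValueError("empty class map")
    frac = counts / total
    frac = frac / frac.sum()  # exact renormalization to kill rounding
    return ClassDistribution(frac, int(total))
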