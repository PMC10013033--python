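"""Per-subject criticality measures on corrected epochs.

All measures are read-outs of critical slowing down:

* **DNM index** — geometric mean of the subnetwork node SDs times the
  geometric mean of the absolute edge correlations; both factors rise as
  the dynamics approaches the bifurcation.
* **Lagged Gaussian mutual information** ``I(x_t; y_{t+dt}) =
  -1/2 ln(1 - rho^2)`` with ``rho`` the Pearson correlation of the lagged
  pair, pooled over epochs (pairs never cross epoch boundaries).
* **Distribution entropy (DE)** — Shannon entropy of the MI mass over all
  ``n(n-1)`` directed node pairs, normalised to [0, 1]; near 1 when
  information flow is isotropic.
* **Network entropy (NE)** — mean per-node entropy of the normalised
  outgoing MI, in nats (at most ``ln(n-1)``).
* **Conditional transfer entropy (CTE)** ``-1/2 ln(1 - rho^2)`` with
  ``rho`` the *partial* correlation of ``(x_t, y_{t+dt})`` given all other
  channels at time t (including ``y_t``); conditioning removes indirect
  routes, so CTE maps direct causality.

Natural logarithms throughout (nats); DE is base-independent by its
normalisation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from dnmcrit.dnmnet import DNMnet, correlation_matrix, node_fluctuation
from dnmcrit.epochs_io import CorrectedEpochs
from dnmcrit.stats import TestResult, rank_sum_test

__all__ = [
    "CriticalityMetrics",
    "dnm_index",
    "gaussian_mi",
    "mi_matrix",
    "distribution_entropy",
    "network_entropy",
    "distribution_entropy_from_mi",
    "network_entropy_from_mi",
    "conditional_transfer_entropy",
    "group_compare",
    "group_mean_cte",
    "compute_metrics",
]

#: cap on |rho| so that -1/2 ln(1 - rho^2) stays finite
RHO_CLIP = 1.0 - 1e-12

#: default lag, ms
DEFAULT_DELTA_T = 20.0


@dataclass(frozen=True)
class CriticalityMetrics:
    subject_id: str
    group: str
    dnm_index: float
    distribution_entropy: float
    network_entropy: float
    cte_matrix: np.ndarray
    mi_matrix: np.ndarray
    delta_t: float


def _geometric_mean(values: np.ndarray) -> float:
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        return 1.0
    if np.any(v < 0):
        raise ValueError("geometric mean requires nonnegative values")
    if np.any(v == 0):
        return 0.0
    return float(np.exp(np.mean(np.log(v))))


def dnm_index(corrected: CorrectedEpochs, net: DNMnet) -> float:
    """Geometric mean of subnetwork node SDs times geometric mean of
    absolute edge correlations.  An empty edge set contributes a factor 1;
    a zero SD or correlation gives index 0 (valid)."""
    if len(net.nodes) < 1:
        raise ValueError("dnm_index: the network needs at least one node")
    sds = node_fluctuation(corrected)[list(net.nodes)]
    sd_factor = _geometric_mean(sds)
    if net.edges:
        r = correlation_matrix(corrected)
        rho = np.array([r[i, j] for i, j in net.edges])
        rho_factor = _geometric_mean(rho)
    else:
        rho_factor = 1.0
    return sd_factor * rho_factor


# ---------------------------------------------------------------------------
# lagged pooling


def _as_epochs(series) -> np.ndarray:
    a = np.asarray(series, dtype=float)
    if a.ndim == 1:
        a = a[np.newaxis, :]
    if a.ndim != 2:
        raise ValueError("series must be 1-D or epoch x time")
    return a


def _lag_samples(delta_t: float, sampling_rate: float) -> int:
    lag = int(round(delta_t * sampling_rate / 1000.0))
    if lag < 1:
        raise ValueError(
            f"delta_t {delta_t} ms is below one sample at {sampling_rate} Hz"
        )
    return lag


def gaussian_mi(
    x_series,
    y_series,
    delta_t: float = DEFAULT_DELTA_T,
    sampling_rate: float = 500.0,
    demean_epochs: bool = True,
) -> float:
    """Lagged Gaussian mutual information ``-1/2 ln(1 - rho^2)`` in nats.

    ``rho`` is the Pearson correlation of ``(x_t, y_{t+dt})`` with lagged
    pairs formed within epochs only and pooled across epochs.  Inputs are
    1-D series or epoch x time arrays.  Degenerate (zero-variance) inputs
    yield 0 with a warning; |rho| is clipped just below 1 to keep the value
    finite.
    """
    x = _as_epochs(x_series)
    y = _as_epochs(y_series)
    if x.shape != y.shape:
        raise ValueError("x and y must have identical epoch x time shapes")
    lag = _lag_samples(delta_t, sampling_rate)
    if lag >= x.shape[1]:
        raise ValueError(
            f"lag of {lag} samples is not below the epoch length {x.shape[1]}"
        )
    if demean_epochs:
        x = x - x.mean(axis=1, keepdims=True)
        y = y - y.mean(axis=1, keepdims=True)
    xt = x[:, :-lag].ravel()
    yt = y[:, lag:].ravel()
    if xt.std() == 0.0 or yt.std() == 0.0:
        warnings.warn("gaussian_mi: zero-variance input, returning 0")
        return 0.0
    rho = float(np.corrcoef(xt, yt)[0, 1])
    rho = float(np.clip(rho, -RHO_CLIP, RHO_CLIP))
    return float(-0.5 * np.log1p(-rho * rho))


def _lagged_blocks(
    corrected: CorrectedEpochs,
    delta_t: float,
    channels: list[int] | None = None,
    demean_epochs: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Pooled (sample x channel) matrices at time t and t + lag."""
    lag = _lag_samples(delta_t, corrected.sampling_rate)
    d = corrected.data
    if channels is not None:
        d = d[:, channels, :]
    if lag >= d.shape[2]:
        raise ValueError(
            f"lag of {lag} samples is not below the epoch length {d.shape[2]}"
        )
    if demean_epochs:
        d = d - d.mean(axis=2, keepdims=True)
    xa = d[:, :, :-lag]  # epoch x channel x (T - lag)
    xb = d[:, :, lag:]
    n_ch = d.shape[1]
    xa = xa.transpose(0, 2, 1).reshape(-1, n_ch)
    xb = xb.transpose(0, 2, 1).reshape(-1, n_ch)
    return xa, xb


def _lagged_correlation_matrix(xa: np.ndarray, xb: np.ndarray) -> np.ndarray:
    """corr(xa[:, i], xb[:, j]) for all i, j; zero-variance columns give 0."""
    a = xa - xa.mean(axis=0)
    b = xb - xb.mean(axis=0)
    sa = a.std(axis=0)
    sb = b.std(axis=0)
    bad_a, bad_b = sa == 0.0, sb == 0.0
    sa[bad_a] = 1.0
    sb[bad_b] = 1.0
    c = (a / sa).T @ (b / sb) / a.shape[0]
    c[bad_a, :] = 0.0
    c[:, bad_b] = 0.0
    return c


def mi_matrix(
    corrected: CorrectedEpochs,
    nodes,
    delta_t: float = DEFAULT_DELTA_T,
    demean_epochs: bool = True,
) -> np.ndarray:
    """Directed Gaussian MI between every ordered node pair (zero diagonal)."""
    nodes = list(nodes)
    if len(nodes) < 2:
        raise ValueError("mi_matrix: need at least two nodes")
    xa, xb = _lagged_blocks(corrected, delta_t, nodes, demean_epochs)
    rho = np.clip(_lagged_correlation_matrix(xa, xb), -RHO_CLIP, RHO_CLIP)
    mi = -0.5 * np.log1p(-rho * rho)
    np.fill_diagonal(mi, 0.0)
    return mi


def distribution_entropy_from_mi(mi: np.ndarray) -> float:
    """Normalised entropy of the directed-pair MI mass, in [0, 1].

    Accepts the square directed-MI matrix (the off-diagonal entries are the
    ``n(n-1)`` directed pairs) or a flat array of directed-edge MI values.
    """
    mi = np.asarray(mi, dtype=float)
    if mi.ndim == 1:
        if mi.size < 2:
            raise ValueError("distribution entropy needs at least two directed pairs")
        vals = mi
    else:
        n = mi.shape[0]
        if n < 2:
            raise ValueError("distribution entropy needs at least two nodes")
        mask = ~np.eye(n, dtype=bool)
        vals = mi[mask]
    total = vals.sum()
    if total <= 0.0:
        warnings.warn("all mutual information zero; distribution entropy set to 1")
        return 1.0
    p = vals / total
    nz = p > 0
    h = float(-(p[nz] * np.log(p[nz])).sum())
    return h / np.log(vals.size)


def network_entropy_from_mi(mi: np.ndarray) -> float:
    """Mean per-node entropy of normalised outgoing MI, in nats."""
    n = mi.shape[0]
    if n < 2:
        raise ValueError("network entropy needs at least two nodes")
    total = 0.0
    for i in range(n):
        out = np.delete(mi[i], i)
        s = out.sum()
        if s <= 0.0:
            warnings.warn(f"node {i}: zero outgoing mutual information, contributes 0")
            continue
        q = out / s
        nz = q > 0
        total += float(-(q[nz] * np.log(q[nz])).sum())
    return total / n


def distribution_entropy(
    corrected: CorrectedEpochs, nodes, delta_t: float = DEFAULT_DELTA_T
) -> float:
    return distribution_entropy_from_mi(mi_matrix(corrected, nodes, delta_t))


def network_entropy(
    corrected: CorrectedEpochs, nodes, delta_t: float = DEFAULT_DELTA_T
) -> float:
    return network_entropy_from_mi(mi_matrix(corrected, nodes, delta_t))


# ---------------------------------------------------------------------------
# conditional transfer entropy


def conditional_transfer_entropy(
    corrected: CorrectedEpochs,
    delta_t: float = DEFAULT_DELTA_T,
    demean_epochs: bool = True,
    min_sample_factor: float = 5.0,
    ridge_scale: float = 1e-6,
    cond_threshold: float = 1e10,
) -> np.ndarray:
    """Conditional-transfer-entropy matrix over all channels (nats).

    ``CTE[x, y] = -1/2 ln(1 - rho^2)`` with ``rho`` the partial correlation
    of ``(x_t, y_{t+dt})`` given every channel at time t except ``x``
    (including ``y_t``), so indirect one-step routes are excluded.  The
    conditioning solve works on the pooled covariance; a ridge
    ``ridge_scale * mean(diag)`` is added when the t-block covariance is
    ill-conditioned.  The diagonal is 0 by definition.
    """
    n_ch = corrected.n_channels
    xa, xb = _lagged_blocks(corrected, delta_t, None, demean_epochs)
    n_samples = xa.shape[0]
    required = int(np.ceil(min_sample_factor * (n_ch + 1)))
    if n_samples < required:
        raise ValueError(
            f"conditional_transfer_entropy: {n_samples} pooled samples, "
            f"need at least {required} ({min_sample_factor} x (n_channels + 1))"
        )
    a = xa - xa.mean(axis=0)
    b = xb - xb.mean(axis=0)
    ctt = a.T @ a / n_samples
    cll = b.T @ b / n_samples
    ctl = a.T @ b / n_samples

    if np.linalg.cond(ctt) > cond_threshold:
        ctt = ctt + ridge_scale * float(np.mean(np.diag(ctt))) * np.eye(n_ch)
    t_inv = np.linalg.inv(ctt)

    cte = np.zeros((n_ch, n_ch))
    idx = np.arange(n_ch)
    for u in range(n_ch):
        z = idx[idx != u]
        # inverse of the conditioning block via one-row downdate of t_inv
        w = t_inv[np.ix_(z, z)] - np.outer(t_inv[z, u], t_inv[u, z]) / t_inv[u, u]
        cuz = ctt[u, z]
        cross = ctl[z, :]
        wc = w @ cross
        px = ctt[u, u] - cuz @ w @ ctt[z, u]
        pxy = ctl[u, :] - cuz @ wc
        pyy = np.diag(cll) - np.einsum("ij,ij->j", cross, wc)
        px = max(px, 1e-300)
        pyy = np.clip(pyy, 1e-300, None)
        rho = np.clip(pxy / np.sqrt(px * pyy), -RHO_CLIP, RHO_CLIP)
        cte[u, :] = -0.5 * np.log1p(-rho * rho)
    np.fill_diagonal(cte, 0.0)
    return cte


# ---------------------------------------------------------------------------
# cohort-level summaries


#: the standard trio of contrasts: criticality is hypothesised higher in HC
GROUP_CONTRASTS = (
    ("HC_gt_UHR", "HC", "UHR", "greater"),
    ("HC_gt_PD", "HC", "PD", "greater"),
    ("UHR_vs_PD", "UHR", "PD", "two-sided"),
)


def group_compare(values, groups) -> dict[str, TestResult]:
    """Wilcoxon rank-sum contrasts of a per-subject metric: one-sided for
    HC > UHR and HC > PD, two-sided for UHR vs PD."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    out = {}
    for name, ga, gb, alternative in GROUP_CONTRASTS:
        a = values[groups == ga]
        b = values[groups == gb]
        if a.size == 0 or b.size == 0:
            raise ValueError(f"group_compare: missing group in contrast {name}")
        out[name] = rank_sum_test(a, b, alternative=alternative)
    return out


def group_mean_cte(cte_matrices, groups, group: str):
    """Entrywise mean CTE matrix over the subjects of one group, plus the
    pooled off-diagonal value histogram (density summary)."""
    groups = np.asarray(groups)
    mats = [m for m, g in zip(cte_matrices, groups) if g == group]
    if not mats:
        raise ValueError(f"group_mean_cte: no subjects in group {group!r}")
    mean = np.mean(mats, axis=0)
    n = mean.shape[0]
    off = ~np.eye(n, dtype=bool)
    pooled = np.concatenate([m[off] for m in mats])
    hist, edges = np.histogram(pooled, bins=50)
    return mean, {"hist": hist, "bin_edges": edges, "mean_offdiag": float(mean[off].mean())}


def compute_metrics(
    corrected: CorrectedEpochs,
    net: DNMnet,
    delta_t: float = DEFAULT_DELTA_T,
    with_cte: bool = True,
) -> CriticalityMetrics:
    """All per-subject criticality measures in one pass."""
    nodes = list(net.nodes)
    if len(nodes) >= 2:
        mi = mi_matrix(corrected, nodes, delta_t)
        de = distribution_entropy_from_mi(mi)
        ne = network_entropy_from_mi(mi)
    else:
        mi = np.zeros((len(nodes), len(nodes)))
        de, ne = 1.0, 0.0
    cte = (
        conditional_transfer_entropy(corrected, delta_t)
        if with_cte
        else np.zeros((corrected.n_channels, corrected.n_channels))
    )
    return CriticalityMetrics(
        subject_id=corrected.subject_id,
        group=corrected.group,
        dnm_index=dnm_index(corrected, net) if nodes else 0.0,
        distribution_entropy=de,
        network_entropy=ne,
        cte_matrix=cte,
        mi_matrix=mi,
        delta_t=delta_t,
    )
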