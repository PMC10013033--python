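"""Selection of the dynamical-network-marker subnetwork (DNMnet).

Approaching a codimension-one bifurcation, a leading group of channels
shows (1) sharply increased fluctuation and (2) sharply increased mutual
correlation.  The DNMnet is therefore selected by per-channel and per-pair
group contrasts between the near-critical (HC) and stable (PD) cohorts:
nodes with significantly elevated corrected-epoch SD (adjusted p below the
node threshold, default 1e-3) and edges with significantly strengthened
absolute Pearson correlation (adjusted p below the edge threshold, default
0.005), both Benjamini–Hochberg corrected.  A reverse screen reports any
pair whose correlation is significantly *weaker* in HC (default alpha
0.05).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from dnmcrit.epochs_io import CorrectedEpochs, EpochSet
from dnmcrit.stats import fdr_adjust, rank_sum_test

__all__ = [
    "DNMnet",
    "node_fluctuation",
    "edge_correlation",
    "correlation_matrix",
    "select_nodes",
    "select_edges",
    "build_dnmnet",
]


@dataclass(frozen=True)
class DNMnet:
    """Selected subnetwork: node set, undirected edge set and the selection
    statistics behind them.  Node and edge selections use separate criteria,
    so edge endpoints need not be selected nodes."""

    nodes: tuple[int, ...]
    edges: tuple[tuple[int, int], ...]
    node_stats: pd.DataFrame
    edge_stats: pd.DataFrame
    decreasing_edges: tuple[tuple[int, int], ...] = ()
    direction_checked: bool = False
    node_alpha: float = 1e-3
    edge_alpha: float = 0.005

    def to_json(self, path=None) -> str:
        payload = {
            "nodes": [int(n) for n in self.nodes],
            "edges": [[int(a), int(b)] for a, b in self.edges],
            "decreasing_edges": [[int(a), int(b)] for a, b in self.decreasing_edges],
            "direction_checked": self.direction_checked,
            "node_alpha": self.node_alpha,
            "edge_alpha": self.edge_alpha,
            "node_stats": self.node_stats.to_dict(orient="list"),
            "edge_stats": self.edge_stats.to_dict(orient="list"),
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            with open(path, "w") as f:
                f.write(text)
        return text

    @classmethod
    def from_json(cls, path) -> "DNMnet":
        with open(path) as f:
            payload = json.load(f)
        return cls(
            nodes=tuple(payload["nodes"]),
            edges=tuple((a, b) for a, b in payload["edges"]),
            node_stats=pd.DataFrame(payload["node_stats"]),
            edge_stats=pd.DataFrame(payload["edge_stats"]),
            decreasing_edges=tuple((a, b) for a, b in payload["decreasing_edges"]),
            direction_checked=payload["direction_checked"],
            node_alpha=payload["node_alpha"],
            edge_alpha=payload["edge_alpha"],
        )


def node_fluctuation(corrected: CorrectedEpochs, ddof: int = 1) -> np.ndarray:
    """Per-channel SD (µV) over all epochs and time samples pooled.

    Sample SD (ddof=1) by default.
    """
    d = corrected.data
    if d.shape[0] * d.shape[2] < 2:
        raise ValueError("node_fluctuation: need at least two samples per channel")
    flat = d.transpose(1, 0, 2).reshape(d.shape[1], -1)
    return flat.std(axis=1, ddof=ddof)


def _pooled_matrix(corrected: CorrectedEpochs, demean_epochs: bool) -> np.ndarray:
    """Channel x pooled-sample matrix; optionally demeaned per epoch (per
    channel) before concatenation so that event-locked waveforms do not
    masquerade as cross-channel correlation."""
    d = corrected.data
    if demean_epochs:
        d = d - d.mean(axis=2, keepdims=True)
    return d.transpose(1, 0, 2).reshape(d.shape[1], -1)


def correlation_matrix(
    corrected: CorrectedEpochs, demean_epochs: bool = True
) -> np.ndarray:
    """Absolute Pearson correlation between all channel pairs over pooled
    within-epoch samples.  Channels with zero variance yield 0 (warned)."""
    x = _pooled_matrix(corrected, demean_epochs)
    sd = x.std(axis=1)
    bad = sd == 0.0
    if bad.any():
        warnings.warn(
            f"correlation undefined for zero-variance channel(s) "
            f"{np.flatnonzero(bad).tolist()}; recorded as 0"
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.abs(np.corrcoef(x))
    r[bad, :] = 0.0
    r[:, bad] = 0.0
    np.fill_diagonal(r, 1.0)
    return r


def edge_correlation(
    corrected: CorrectedEpochs, pairs, demean_epochs: bool = True
) -> np.ndarray:
    """|Pearson rho| for the requested channel pairs (pooled within-epoch
    samples, epochs concatenated after per-epoch demeaning)."""
    if corrected.n_epochs * corrected.data.shape[2] < 3:
        raise ValueError("edge_correlation: need at least three paired samples")
    r = correlation_matrix(corrected, demean_epochs)
    return np.array([r[i, j] for i, j in pairs])


def _split_groups(study: list[CorrectedEpochs], group_a: str, group_b: str):
    a = [s for s in study if s.group == group_a]
    b = [s for s in study if s.group == group_b]
    if len(a) < 2 or len(b) < 2:
        raise ValueError(
            f"need at least two subjects in each of {group_a!r} and {group_b!r}"
        )
    return a, b


def select_nodes(
    study: list[CorrectedEpochs],
    test: str = "rank_sum",
    alpha: float = 1e-3,
    group_a: str = "HC",
    group_b: str = "PD",
    epoch_sets: list[EpochSet] | None = None,
    standard_sd: dict[str, np.ndarray] | None = None,
) -> tuple[tuple[int, ...], pd.DataFrame]:
    """Channels whose fluctuation is significantly higher in ``group_a``
    (near-critical) than in ``group_b`` (stable).

    ``test='rank_sum'`` (default): one-sided Wilcoxon rank-sum on the
    per-subject corrected-epoch SDs.  ``test='paired_t'``: each subject's SD
    is first paired against the same subject's standard-epoch SD (supplied
    as ``epoch_sets`` or a precomputed per-subject ``standard_sd`` mapping);
    the per-subject paired differences are then contrasted
    between groups with a one-sided Welch t-test.  Both are adjusted across
    channels by Benjamini–Hochberg; selected nodes satisfy
    ``p_adjusted < alpha``.
    """
    if test not in ("rank_sum", "paired_t"):
        raise ValueError("test must be 'rank_sum' or 'paired_t'")
    a, b = _split_groups(study, group_a, group_b)
    sd = {s.subject_id: node_fluctuation(s) for s in study}

    if test == "paired_t":
        if standard_sd is not None:
            std_sd = dict(standard_sd)
        elif epoch_sets is not None:
            std_sd = {}
            for es in epoch_sets:
                arr = es.standard_epochs
                flat = arr.transpose(1, 0, 2).reshape(arr.shape[1], -1)
                std_sd[es.subject_id] = flat.std(axis=1, ddof=1)
        else:
            raise ValueError(
                "paired_t node test requires epoch_sets or standard_sd"
            )
        feat = {
            sid: sd[sid] - std_sd[sid] for sid in sd if sid in std_sd
        }
    else:
        feat = sd

    fa = np.stack([feat[s.subject_id] for s in a])
    fb = np.stack([feat[s.subject_id] for s in b])
    n_ch = fa.shape[1]

    if test == "rank_sum":
        pvals = np.array([
            rank_sum_test(fa[:, c], fb[:, c], alternative="greater").p_value
            for c in range(n_ch)
        ])
    else:
        from scipy.stats import ttest_ind

        pvals = np.array([
            float(ttest_ind(
                fa[:, c], fb[:, c], equal_var=False, alternative="greater"
            ).pvalue)
            for c in range(n_ch)
        ])
        pvals = np.clip(pvals, np.finfo(float).tiny, 1.0)

    padj = fdr_adjust(pvals)
    stats = pd.DataFrame({
        "channel": np.arange(n_ch),
        "p_value": pvals,
        "p_adjusted": padj,
        "selected": padj < alpha,
    })
    nodes = tuple(int(c) for c in np.flatnonzero(padj < alpha))
    return nodes, stats


def select_edges(
    study: list[CorrectedEpochs],
    alpha: float = 0.005,
    screen_alpha: float = 0.05,
    candidate_nodes: tuple[int, ...] | None = None,
    group_a: str = "HC",
    group_b: str = "PD",
    demean_epochs: bool = True,
) -> tuple[tuple[tuple[int, int], ...], pd.DataFrame, tuple[tuple[int, int], ...]]:
    """Channel pairs whose |correlation| is significantly stronger in
    ``group_a`` than ``group_b`` (one-sided rank-sum, BH-adjusted across
    pairs, ``p_adjusted < alpha``), plus the reverse-direction screen at
    ``screen_alpha``.

    By default all channel pairs are candidates; pass ``candidate_nodes`` to
    restrict the universe to pairs among those channels.
    """
    a, b = _split_groups(study, group_a, group_b)
    mats = {s.subject_id: correlation_matrix(s, demean_epochs) for s in study}
    n_ch = next(iter(mats.values())).shape[0]
    chans = list(candidate_nodes) if candidate_nodes is not None else list(range(n_ch))
    pairs = list(combinations(sorted(chans), 2))
    if not pairs:
        raise ValueError("select_edges: empty candidate pair set")

    ra = np.stack([[mats[s.subject_id][i, j] for i, j in pairs] for s in a])
    rb = np.stack([[mats[s.subject_id][i, j] for i, j in pairs] for s in b])

    p_inc = np.array([
        rank_sum_test(ra[:, k], rb[:, k], alternative="greater").p_value
        for k in range(len(pairs))
    ])
    p_dec = np.array([
        rank_sum_test(ra[:, k], rb[:, k], alternative="less").p_value
        for k in range(len(pairs))
    ])
    padj_inc = fdr_adjust(p_inc)
    padj_dec = fdr_adjust(p_dec)

    stats = pd.DataFrame({
        "channel_i": [i for i, _ in pairs],
        "channel_j": [j for _, j in pairs],
        "p_value": p_inc,
        "p_adjusted": padj_inc,
        "p_value_decreasing": p_dec,
        "p_adjusted_decreasing": padj_dec,
        "selected": padj_inc < alpha,
    })
    edges = tuple(p for p, sel in zip(pairs, padj_inc < alpha) if sel)
    decreasing = tuple(p for p, sig in zip(pairs, padj_dec < screen_alpha) if sig)
    return edges, stats, decreasing


def build_dnmnet(
    study: list[CorrectedEpochs],
    node_alpha: float = 1e-3,
    edge_alpha: float = 0.005,
    screen_alpha: float = 0.05,
    node_test: str = "rank_sum",
    edges_among_nodes: bool = False,
    epoch_sets: list[EpochSet] | None = None,
    standard_sd: dict[str, np.ndarray] | None = None,
) -> DNMnet:
    """Compose node and edge selection into the DNMnet."""
    nodes, node_stats = select_nodes(
        study, test=node_test, alpha=node_alpha, epoch_sets=epoch_sets,
        standard_sd=standard_sd,
    )
    candidates = nodes if edges_among_nodes else None
    if edges_among_nodes and len(nodes) < 2:
        edges, decreasing = (), ()
        edge_stats = pd.DataFrame(columns=[
            "channel_i", "channel_j", "p_value", "p_adjusted",
            "p_value_decreasing", "p_adjusted_decreasing", "selected",
        ])
    else:
        edges, edge_stats, decreasing = select_edges(
            study, alpha=edge_alpha, screen_alpha=screen_alpha,
            candidate_nodes=candidates,
        )
    return DNMnet(
        nodes=nodes,
        edges=edges,
        node_stats=node_stats,
        edge_stats=edge_stats,
        decreasing_edges=decreasing,
        direction_checked=True,
        node_alpha=node_alpha,
        edge_alpha=edge_alpha,
    )
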