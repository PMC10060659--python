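"""Co-occurrence networks with random-matrix-theory threshold selection.

The threshold for calling an edge between two genes is not arbitrary: scanning
the correlation cutoff from 1.0 downward, the nearest-neighbour spacing
distribution (NNSD) of the thresholded matrix's eigenvalues follows Poisson
statistics while the matrix decomposes into independent modules, and crosses
to Wigner (GOE) statistics once noise correlations glue the system together.
The selected threshold is the last cutoff before that transition ("decrease
the cutoff from top", "regress Poisson distribution only").

On the thresholded graph we compute the standard index panel — average
connectivity avgK, average clustering coefficient avgCC, average path distance
GD, geodesic efficiency E and its reciprocal the harmonic geodesic distance HD
— plus Newman's modularity Q from greedy agglomerative (CNM) optimization.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Literal

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from scipy.interpolate import LSQUnivariateSpline

from .abundance import AbundanceTable

logger = logging.getLogger(__name__)

__all__ = [
    "GeneNetwork",
    "IndexPanel",
    "prevalence_filter",
    "correlation_matrix",
    "nnsd",
    "spacing_gof",
    "rmt_threshold",
    "build_network",
    "index_panel",
    "greedy_modularity",
    "write_edge_list_tsv",
    "write_node_attributes_tsv",
]


# ---------------------------------------------------------------------------
# correlations
# ---------------------------------------------------------------------------

def prevalence_filter(table: AbundanceTable, min_prevalence: float = 0.5) -> AbundanceTable:
    """Keep genes present (>0) in at least ``min_prevalence`` of samples."""
    prev = (table.data > 0).mean(axis=0)
    keep = prev.index[prev >= min_prevalence]
    dropped = table.data.shape[1] - len(keep)
    if dropped:
        logger.info("prevalence_filter: dropped %d/%d features below prevalence %.2f",
                    dropped, table.data.shape[1], min_prevalence)
    if len(keep) == 0:
        raise ValueError("prevalence filter removed every feature")
    return AbundanceTable(table.data[list(keep)].copy(), table.feature_kind, table.unit)


def correlation_matrix(
    table: AbundanceTable,
    samples: list[str] | None = None,
    method: Literal["pearson", "spearman"] = "pearson",
    log_transform: bool = True,
) -> pd.DataFrame:
    """Feature x feature correlation over the given samples.

    Default is Pearson on log10(x + 1).  Zero-variance features get masked
    (NaN) off-diagonal correlations; the diagonal is exactly 1.
    """
    data = table.data if samples is None else table.data.loc[samples]
    if data.shape[0] < 3:
        raise ValueError(f"need >= 3 samples for correlations, got {data.shape[0]}")
    X = np.log10(data.values + 1.0) if log_transform else data.values.astype(float)
    if method == "spearman":
        X = np.apply_along_axis(stats.rankdata, 0, X)
    elif method != "pearson":
        raise ValueError(f"unknown correlation method: {method!r}")
    sd = X.std(axis=0)
    flat = sd == 0
    if flat.any():
        logger.info("correlation_matrix: %d zero-variance feature(s) masked", int(flat.sum()))
    with np.errstate(invalid="ignore", divide="ignore"):
        C = np.corrcoef(X, rowvar=False)
    C[flat, :] = np.nan
    C[:, flat] = np.nan
    np.fill_diagonal(C, 1.0)
    C = np.clip(C, -1.0, 1.0)
    return pd.DataFrame(C, index=data.columns, columns=data.columns)


# ---------------------------------------------------------------------------
# random matrix theory: NNSD and threshold scan
# ---------------------------------------------------------------------------

def nnsd(
    eigenvalues: np.ndarray,
    knots: int = 15,
    dedupe_tol: float = 1e-8,
) -> np.ndarray:
    """Nearest-neighbour spacings of an unfolded spectrum, normalized to mean 1.

    Unfolding fits a cubic least-squares spline (``knots`` interior knots) to
    the empirical cumulative spectral density and evaluates it at each
    eigenvalue; spacings are consecutive differences of the unfolded levels.
    Degenerate eigenvalues (within ``dedupe_tol``) are collapsed first —
    thresholded sparse matrices otherwise flood the NNSD with exact-zero
    spacings that reflect degeneracy, not level statistics.
    """
    lam = np.sort(np.asarray(eigenvalues, dtype=float))
    if lam.ndim != 1:
        raise ValueError("eigenvalues must be a 1-D array")
    # collapse numerically degenerate levels
    keep = np.concatenate([[True], np.diff(lam) > dedupe_tol])
    lam = lam[keep]
    n = lam.size
    if n < 30:
        raise ValueError(f"need >= 30 distinct eigenvalues for a spacing sample, got {n}")
    cdf = np.arange(1, n + 1, dtype=float)
    k = min(knots, max(1, n // 4))
    # interior knots at interior quantiles of the spectrum
    qs = np.linspace(0, 1, k + 2)[1:-1]
    t = np.quantile(lam, qs)
    t = np.unique(t[(t > lam[0]) & (t < lam[-1])])
    try:
        spline = LSQUnivariateSpline(lam, cdf, t, k=3)
        unfolded = spline(lam)
    except Exception:  # pathological knot placement: fall back to raw CDF
        unfolded = cdf
    s = np.diff(unfolded)
    s = np.clip(s, 0.0, None)  # spline may be locally non-monotone
    m = s.mean()
    if m <= 0:
        raise ValueError("degenerate spectrum: all unfolded spacings are zero")
    return s / m


def _poisson_cdf(s: np.ndarray) -> np.ndarray:
    return 1.0 - np.exp(-s)


def _wigner_cdf(s: np.ndarray) -> np.ndarray:
    return 1.0 - np.exp(-np.pi * s ** 2 / 4.0)


def spacing_gof(
    spacings: np.ndarray,
    dist: Literal["poisson", "wigner"] = "poisson",
    bins: int = 30,
    upper: float = 3.0,
) -> tuple[float, float]:
    """Chi-square goodness of fit of spacings to Poisson exp(-s) or the Wigner
    surmise (pi s/2) exp(-pi s^2/4).

    Histogram uses ``bins`` equal-width bins on [0, upper] plus an overflow
    bin; adjacent bins are pooled until every expected count is >= 5.  Returns
    (statistic, p-value); degrees of freedom = pooled bins - 2 (one constraint
    from the mean-1 normalization).
    """
    s = np.asarray(spacings, dtype=float)
    edges = np.concatenate([np.linspace(0.0, upper, bins + 1), [np.inf]])
    obs, _ = np.histogram(s, bins=edges)
    cdf = _poisson_cdf if dist == "poisson" else _wigner_cdf
    cdf_vals = np.concatenate([cdf(edges[:-1][edges[:-1] < np.inf]), [1.0]])
    probs = np.diff(np.concatenate([cdf_vals, [1.0]]))[: len(obs)]
    exp = probs * s.size

    # pool adjacent bins so expected counts stay >= 5
    pooled_obs, pooled_exp = [], []
    o_acc = e_acc = 0.0
    for o, e in zip(obs, exp):
        o_acc += o
        e_acc += e
        if e_acc >= 5:
            pooled_obs.append(o_acc)
            pooled_exp.append(e_acc)
            o_acc = e_acc = 0.0
    if pooled_obs:
        pooled_obs[-1] += o_acc
        pooled_exp[-1] += e_acc
    else:
        raise ValueError("too few spacings for a chi-square fit")
    o = np.asarray(pooled_obs)
    e = np.asarray(pooled_exp) * (o.sum() / sum(pooled_exp))
    stat = float(((o - e) ** 2 / e).sum())
    dof = max(len(o) - 2, 1)
    p = float(stats.chi2.sf(stat, dof))
    return stat, p


def rmt_threshold(
    corr: pd.DataFrame | np.ndarray,
    step: float = 0.01,
    start: float = 1.0,
    alpha: float = 0.05,
    min_nodes: int = 30,
    knots: int = 15,
    bins: int = 30,
) -> float:
    """Scan the cutoff from ``start`` downward; return the last cutoff at which
    the NNSD of the thresholded matrix still follows Poisson statistics.

    At each cutoff, entries with |r| below it are zeroed, rows with no
    surviving off-diagonal entry are removed, and the NNSD of the remaining
    matrix is chi-square-tested against exp(-s).  The scan stops at the first
    cutoff whose NNSD both rejects Poisson and fits Wigner better than
    Poisson (chi-square distance) — the Poisson-to-Wigner transition — and
    the previous cutoff is returned.  The directional check matters: at high
    cutoffs, half-assembled correlation blocks produce *clustered* spectra
    (an excess of small spacings, the opposite of GOE repulsion) that also
    reject Poisson but sit on the fragmented side of the transition.  If the
    transition never arrives the lowest scanned cutoff is returned with a
    warning (featureless input).
    """
    C = corr.values if isinstance(corr, pd.DataFrame) else np.asarray(corr, dtype=float)
    if C.shape[0] != C.shape[1]:
        raise ValueError("correlation matrix must be square")
    A = np.abs(np.nan_to_num(C, nan=0.0))
    np.fill_diagonal(A, 0.0)

    cutoffs = np.round(np.arange(start, 0.0, -step), 10)
    last_ok: float | None = None  # last scanned cutoff not rejecting Poisson
    assessed_any = False
    for s in cutoffs:
        mask = A >= s
        deg = mask.sum(axis=1)
        alive = deg > 0
        if int(alive.sum()) < min_nodes:
            if int(alive.sum()) >= 2:
                last_ok = float(s)  # too sparse to assess: vacuously non-rejecting
            continue
        M = np.where(mask, np.nan_to_num(C, nan=0.0), 0.0)[np.ix_(alive, alive)]
        np.fill_diagonal(M, 1.0)
        lam = np.linalg.eigvalsh(M)
        try:
            sp = nnsd(lam, knots=knots)
        except ValueError:
            last_ok = float(s)  # too few distinct levels: vacuously non-rejecting
            continue
        assessed_any = True
        stat_p, p = spacing_gof(sp, "poisson", bins=bins)
        stat_w, _ = spacing_gof(sp, "wigner", bins=bins)
        if p > alpha or stat_w >= stat_p:
            last_ok = float(s)
        else:
            if last_ok is None:
                raise ValueError(
                    f"Poisson rejected already at the highest scanned cutoff {s:.3f}; "
                    "try a smaller scan step"
                )
            return last_ok
    if not assessed_any:
        raise ValueError(f"no cutoff admits >= {min_nodes} non-isolated nodes")
    logger.warning("rmt_threshold: NNSD Poisson at every scanned cutoff "
                   "(noise-like input); returning the lowest cutoff %.3f", last_ok)
    return float(last_ok)


# ---------------------------------------------------------------------------
# networks
# ---------------------------------------------------------------------------

@dataclass
class GeneNetwork:
    """Simple undirected co-occurrence graph at a correlation threshold."""

    graph: nx.Graph
    threshold: float
    corr_method: str = "pearson"
    treatment: str | None = None

    @property
    def nodes(self) -> list:
        return list(self.graph.nodes)

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_links(self) -> int:
        return self.graph.number_of_edges()


def build_network(
    corr: pd.DataFrame,
    threshold: float,
    treatment: str | None = None,
    corr_method: str = "pearson",
) -> GeneNetwork:
    """Edge iff |r| >= threshold (i != j); isolated nodes are dropped.

    The correlation sign is kept as an edge attribute; topology uses |r|.
    """
    if not (0 < threshold <= 1):
        raise ValueError("threshold must lie in (0, 1]")
    C = corr.values
    A = np.abs(np.nan_to_num(C, nan=0.0))
    np.fill_diagonal(A, 0.0)
    ii, jj = np.where(np.triu(A >= threshold, k=1))
    if len(ii) == 0:
        raise ValueError(f"no edge survives threshold {threshold}: "
                         f"max off-diagonal |r| = {A.max():.4f}")
    g = nx.Graph()
    names = corr.index
    for i, j in zip(ii, jj):
        r = float(C[i, j])
        g.add_edge(names[i], names[j], r=r, weight=abs(r), sign=1 if r >= 0 else -1)
    n_iso = len(names) - g.number_of_nodes()
    if n_iso:
        logger.info("build_network: dropped %d isolated node(s)", n_iso)
    return GeneNetwork(g, float(threshold), corr_method, treatment)


@dataclass
class IndexPanel:
    """The topology index panel reported per network."""

    n_nodes: int
    n_links: int
    avgK: float
    avgCC: float
    GD: float | None      # None when no connected pair exists
    E: float
    HD: float             # inf when E == 0
    modularity: float

    def as_dict(self) -> dict:
        return {"n_nodes": self.n_nodes, "n_links": self.n_links, "avgK": self.avgK,
                "avgCC": self.avgCC, "GD": self.GD, "E": self.E, "HD": self.HD,
                "modularity": self.modularity}


def index_panel(net: GeneNetwork) -> IndexPanel:
    """avgK = 2L/N; avgCC = mean node clustering (0 for degree < 2);
    GD = mean geodesic over connected ordered pairs; E = mean of 1/d over all
    ordered pairs (1/inf = 0); HD = 1/E."""
    g = net.graph
    n = g.number_of_nodes()
    if n < 2:
        raise ValueError("index panel needs >= 2 nodes")
    m = g.number_of_edges()
    avg_k = 2.0 * m / n
    avg_cc = float(np.mean(list(nx.clustering(g).values())))
    inv_sum = 0.0
    d_sum = 0.0
    n_connected_pairs = 0
    for src, dmap in nx.all_pairs_shortest_path_length(g):
        for dst, d in dmap.items():
            if dst == src:
                continue
            d_sum += d
            inv_sum += 1.0 / d
            n_connected_pairs += 1
    total_pairs = n * (n - 1)
    gd = d_sum / n_connected_pairs if n_connected_pairs else None
    e = inv_sum / total_pairs
    hd = 1.0 / e if e > 0 else float("inf")
    _, q = greedy_modularity(net)
    panel = IndexPanel(n, m, avg_k, avg_cc, gd, e, hd, q)
    # structural identities asserted on every constructed panel
    assert abs(panel.avgK - 2 * m / n) < 1e-12
    if panel.E > 0:
        assert abs(panel.HD * panel.E - 1.0) < 1e-9
    return panel


# ---------------------------------------------------------------------------
# greedy (CNM) modularity
# ---------------------------------------------------------------------------

def modularity_q(graph: nx.Graph, partition: list[set]) -> float:
    """Newman-Girvan Q = sum_c (e_cc - a_c^2) over communities."""
    m = graph.number_of_edges()
    if m == 0:
        raise ValueError("modularity undefined for an empty edge set")
    q = 0.0
    for comm in partition:
        within = sum(1 for u, v in graph.edges(comm) if u in comm and v in comm)
        degsum = sum(d for _, d in graph.degree(comm))
        q += within / m - (degsum / (2.0 * m)) ** 2
    return q


def greedy_modularity(net: GeneNetwork | nx.Graph) -> tuple[list[set], float]:
    """Agglomerative CNM greedy modularity optimization.

    Starts from singleton communities and repeatedly merges the connected
    pair with the largest modularity gain — even a negative one once no
    positive gain remains — and returns the highest-Q partition seen along
    the merge sequence.  Among equal gains the lexicographically smallest
    community-label pair is merged, making the partition deterministic.
    """
    g = net.graph if isinstance(net, GeneNetwork) else net
    m = g.number_of_edges()
    if m == 0:
        raise ValueError("greedy modularity needs >= 1 edge")

    comm_nodes: dict = {node: {node} for node in g.nodes}
    a = {node: g.degree(node) / (2.0 * m) for node in g.nodes}
    e = {node: {} for node in g.nodes}  # e[i][j]: fraction of edges between i and j
    for u, v in g.edges:
        if u == v:
            continue
        e[u][v] = e[u].get(v, 0.0) + 1.0 / m
        e[v][u] = e[v].get(u, 0.0) + 1.0 / m

    def label_key(c):
        return str(c)

    q = -sum(ai * ai for ai in a.values())  # singleton partition
    best_q = q
    best_partition = [set(s) for s in comm_nodes.values()]
    while True:
        best = None
        for i in comm_nodes:
            for j, eij in e[i].items():
                if label_key(j) <= label_key(i):
                    continue
                # e[i][j] holds E_ij / m, hence dQ = E_ij/m - 2 a_i a_j
                gain = eij - 2.0 * a[i] * a[j]
                key = (-gain, label_key(i), label_key(j))
                if best is None or key < best[0]:
                    best = (key, i, j)
        if best is None:  # no connected community pair remains
            break
        key, i, j = best
        q += -key[0]
        # merge j into i
        comm_nodes[i] |= comm_nodes.pop(j)
        a[i] += a.pop(j)
        for k, ejk in e.pop(j).items():
            if k == i:
                continue
            e[k].pop(j, None)
            e[i][k] = e[i].get(k, 0.0) + ejk
            e[k][i] = e[i][k]
        e[i].pop(j, None)
        if q > best_q + 1e-15:
            best_q = q
            best_partition = [set(s) for s in comm_nodes.values()]

    partition = sorted(best_partition, key=lambda s: str(min(s, key=str)))
    return partition, modularity_q(g, partition)


# ---------------------------------------------------------------------------
# exports (Cytoscape-loadable)
# ---------------------------------------------------------------------------

def write_edge_list_tsv(net: GeneNetwork, path) -> None:
    rows = [{"node1": u, "node2": v, "r": d["r"], "sign": d["sign"]}
            for u, v, d in net.graph.edges(data=True)]
    pd.DataFrame(rows, columns=["node1", "node2", "r", "sign"]).to_csv(path, sep="\t", index=False)


def write_node_attributes_tsv(net: GeneNetwork, catalog, path) -> None:
    partition, _ = greedy_modularity(net)
    module_of = {}
    for k, comm in enumerate(partition):
        for node in comm:
            module_of[node] = k
    ann = catalog.frame
    rows = []
    for node in net.nodes:
        rec = {"gene": node, "module": module_of[node]}
        if node in ann.index:
            rec.update({"species": ann.loc[node, "species"],
                        "category": ann.loc[node, "category"],
                        "func_class": ann.loc[node, "func_class"]})
        rows.append(rec)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
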