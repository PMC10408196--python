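"""SparCC co-abundance networks and centrality comparison.

SparCC estimates correlations between the (unobserved) basis abundances
of compositional data from the variances of pairwise log-ratios,

    t_ij = var(log(x_i / x_j)) = w_i + w_j - 2 rho_ij sqrt(w_i w_j),

solving for the basis variances w under the sparsity assumption that most
correlations are near zero, and iteratively excluding the most strongly
correlated pairs from the system.  Pseudo p-values come from null data
sets in which every feature's samples are resampled independently
(breaking all cross-feature association).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .differential import fdr_adjust
from .profiles import AbundanceTable

DEFAULT_PSEUDO_COUNT = 0.5


def _log_fractions(counts: np.ndarray, pseudo_count: float) -> np.ndarray:
    """Log relative abundances after zero replacement (features x samples)."""
    x = counts + pseudo_count
    return np.log(x / x.sum(axis=0, keepdims=True))


def _basis_correlations(logf: np.ndarray, n_iter: int,
                        exclusion_threshold: float) -> np.ndarray:
    """SparCC basis correlation matrix from log fractions."""
    d = logf.shape[0]
    t = np.var(logf[:, None, :] - logf[None, :, :], axis=2, ddof=1)
    included = ~np.eye(d, dtype=bool)
    rho = np.eye(d)
    for _ in range(max(n_iter, 1)):
        deg = included.sum(axis=1)
        if (deg < 2).any():
            break  # remaining pairs unestimable for starved features
        a = np.diag(deg.astype(float)) + included.astype(float)
        tsum = (t * included).sum(axis=1)
        try:
            w = np.linalg.solve(a, tsum)
        except np.linalg.LinAlgError:
            break
        w = np.clip(w, 1e-12, None)
        denom = 2.0 * np.sqrt(np.outer(w, w))
        rho = (w[:, None] + w[None, :] - t) / denom
        np.fill_diagonal(rho, 1.0)
        rho = np.clip(rho, -1.0, 1.0)
        # exclude the single most correlated still-included off-diagonal pair
        masked = np.where(included, np.abs(rho), 0.0)
        np.fill_diagonal(masked, 0.0)
        i, j = np.unravel_index(np.argmax(masked), masked.shape)
        if masked[i, j] <= exclusion_threshold:
            break
        included[i, j] = included[j, i] = False
    return rho


def sparcc_correlations(counts: AbundanceTable, n_iter: int = 20,
                        exclusion_threshold: float = 0.1, n_boot: int = 100,
                        seed: int | None = None,
                        pseudo_count: float = DEFAULT_PSEUDO_COUNT,
                        ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Basis correlations and pseudo p-values for a counts table.

    Requires >= 4 features and >= 10 samples.  p_ij is the fraction of
    null data sets (independent per-feature resampling with replacement)
    whose |rho| meets or exceeds the observed |rho_ij|, with the +1
    correction so p >= 1/(1+n_boot).
    """
    data = counts.unstratified()
    x = data.to_numpy(dtype=float)
    d, n = x.shape
    if d < 4:
        raise ValueError("need at least 4 features")
    if n < 10:
        raise ValueError("need at least 10 samples")
    logf = _log_fractions(x, pseudo_count)
    rho = _basis_correlations(logf, n_iter, exclusion_threshold)
    rng = np.random.default_rng(seed)
    exceed = np.zeros((d, d))
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=(d, n))
        null = x[np.arange(d)[:, None], idx]
        rho_null = _basis_correlations(_log_fractions(null, pseudo_count),
                                       n_iter, exclusion_threshold)
        exceed += np.abs(rho_null) >= np.abs(rho)
    p = (1.0 + exceed) / (1.0 + n_boot)
    np.fill_diagonal(p, 0.0)
    ids = list(data.index)
    return (pd.DataFrame(rho, index=ids, columns=ids),
            pd.DataFrame(p, index=ids, columns=ids))


# ---------------------------------------------------------------------------
# network construction and centrality
# ---------------------------------------------------------------------------

@dataclass
class CorrelationNetwork:
    graph: nx.Graph
    group: str = ""
    edges: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)


def build_network(rho: pd.DataFrame, p: pd.DataFrame, edge_threshold: float = 0.1,
                  group: str = "") -> CorrelationNetwork:
    """Significance-filtered undirected network (BH q < edge_threshold).

    BH adjustment runs over the off-diagonal upper triangle; nodes with no
    surviving edge are kept as isolates.
    """
    if list(rho.index) != list(p.index) or list(rho.columns) != list(p.columns):
        raise ValueError("rho and p matrices are not aligned")
    r = rho.to_numpy(dtype=float)
    if np.abs(r - r.T).max(initial=0.0) > 1e-8:
        raise ValueError("rho matrix is not symmetric")
    ids = list(rho.index)
    d = len(ids)
    iu = np.triu_indices(d, 1)
    q = fdr_adjust(p.to_numpy()[iu])
    g = nx.Graph()
    g.add_nodes_from(ids)
    rows = []
    for (i, j), qv in zip(zip(*iu), q):
        if qv < edge_threshold:
            g.add_edge(ids[i], ids[j], rho=float(r[i, j]),
                       p=float(p.iat[i, j]), q=float(qv))
            rows.append({"source": ids[i], "target": ids[j],
                         "rho": float(r[i, j]), "p": float(p.iat[i, j]),
                         "q": float(qv)})
    return CorrelationNetwork(g, group, pd.DataFrame(
        rows, columns=["source", "target", "rho", "p", "q"]))


def network_centrality(net: CorrelationNetwork) -> pd.DataFrame:
    """Degree and component-normalised closeness per node.

    Closeness of v = (reachable nodes) / (sum of unweighted shortest-path
    lengths within v's component); isolates get 0.
    """
    g = net.graph
    if g.number_of_nodes() == 0:
        return pd.DataFrame(columns=["node", "degree", "closeness"])
    closeness = nx.closeness_centrality(g, wf_improved=False)
    return pd.DataFrame({
        "node": list(g.nodes),
        "degree": [g.degree(v) for v in g.nodes],
        "closeness": [closeness[v] for v in g.nodes],
    })


def compare_centrality(net_a: CorrelationNetwork, net_b: CorrelationNetwork) -> pd.DataFrame:
    """Welch t-tests on per-node degree and closeness between two networks."""
    ca, cb = network_centrality(net_a), network_centrality(net_b)
    rows = []
    for measure in ("degree", "closeness"):
        xa, xb = ca[measure].to_numpy(float), cb[measure].to_numpy(float)
        if len(xa) < 2 or len(xb) < 2 or (np.ptp(xa) == 0 and np.ptp(xb) == 0):
            t, p = np.nan, np.nan
            warnings.warn(f"cannot compare {measure}: degenerate samples")
        else:
            t, p = stats.ttest_ind(xa, xb, equal_var=False)
        rows.append({"measure": measure, "group_a": net_a.group, "group_b": net_b.group,
                     "mean_a": float(xa.mean()) if len(xa) else np.nan,
                     "mean_b": float(xb.mean()) if len(xb) else np.nan,
                     "t": float(t), "p": float(p)})
    return pd.DataFrame(rows)


def annotate_nodes(net: CorrelationNetwork, annotation) -> pd.Series:
    """Flag network nodes present in an annotation list.

    ``annotation`` is an iterable of species names (or a path to a
    one-column text file of them, e.g. amino-acid auxotrophs); matching is
    on the terminal clade name.  Returns a boolean Series over nodes.
    """
    if isinstance(annotation, (str, bytes)) or hasattr(annotation, "read"):
        with open(annotation) as fh:
            names = {line.strip() for line in fh if line.strip()}
    else:
        names = set(annotation)
    terminals = {n.rsplit("|", 1)[-1] for n in names} | names
    return pd.Series({node: node.rsplit("|", 1)[-1] in terminals or node in terminals
                      for node in net.nodes}, name="annotated")


def write_edge_list(net: CorrelationNetwork, path) -> None:
    net.edges.to_csv(path, sep="\t", index=False)


def write_graphml(net: CorrelationNetwork, path) -> None:
    nx.write_graphml(net.graph, path)
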