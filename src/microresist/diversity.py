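"""Alpha diversity, beta dissimilarity and principal coordinates.

Shannon uses the natural log; Chao1 is the bias-corrected estimator
(defined even when no doubletons are present).  Principal-coordinate
analysis is classical scaling of the double-centred squared-distance
matrix; negative eigenvalues are dropped from the coordinates and reported
separately, and proportion explained is taken over the positive
eigenvalues only.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .profiles import AbundanceTable

ALPHA_INDICES = ("shannon", "simpson", "chao1")


@dataclass
class DistanceMatrix:
    """Symmetric sample-by-sample dissimilarity with zero diagonal."""

    sample_ids: list[str]
    values: np.ndarray
    metric: str

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1] or v.shape[0] != len(self.sample_ids):
            raise ValueError("distance matrix shape does not match sample ids")
        if np.abs(v - v.T).max(initial=0.0) > 1e-12:
            raise ValueError("distance matrix is not symmetric")
        if (v < 0).any():
            raise ValueError("negative distances")
        np.fill_diagonal(v, 0.0)
        self.values = v

    @property
    def n(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.sample_ids)

    def subset(self, sample_ids) -> "DistanceMatrix":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return DistanceMatrix(list(sample_ids), self.values[np.ix_(idx, idx)], self.metric)


@dataclass
class PcoaResult:
    coordinates: pd.DataFrame          # samples x retained axes
    eigenvalues: np.ndarray            # retained (positive) eigenvalues
    proportion_explained: np.ndarray   # relative to the positive-eigenvalue sum
    negative_eigenvalues: np.ndarray   # dropped spectrum, for diagnostics


# ---------------------------------------------------------------------------
# alpha diversity
# ---------------------------------------------------------------------------

def alpha_diversity(table: AbundanceTable, index: str) -> pd.Series:
    """Per-sample alpha diversity (``shannon``, ``simpson`` or ``chao1``).

    Shannon and Simpson accept relative abundances or counts (counts are
    closed to proportions first); Chao1 requires integer counts because it
    is built on singleton/doubleton frequencies.
    """
    if index not in ALPHA_INDICES:
        raise ValueError(f"index must be one of {ALPHA_INDICES}")
    data = table.unstratified()
    x = data.to_numpy(dtype=float)
    if index == "chao1":
        if table.unit != "counts":
            raise ValueError("chao1 requires counts (singletons/doubletons are undefined "
                             "on relative abundances)")
        s_obs = (x > 0).sum(axis=0)
        f1 = (x == 1).sum(axis=0)
        f2 = (x == 2).sum(axis=0)
        vals = s_obs + f1 * (f1 - 1) / (2.0 * (f2 + 1))
        return pd.Series(vals, index=data.columns, name="chao1")
    colsum = x.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(colsum > 0, x / np.where(colsum > 0, colsum, 1.0), 0.0)
    if index == "shannon":
        with np.errstate(divide="ignore", invalid="ignore"):
            terms = np.where(p > 0, -p * np.log(p), 0.0)
        vals = terms.sum(axis=0)
    else:  # simpson, as 1 - dominance
        vals = 1.0 - (p ** 2).sum(axis=0)
    return pd.Series(vals, index=data.columns, name=index)


# ---------------------------------------------------------------------------
# beta diversity
# ---------------------------------------------------------------------------

def bray_curtis(table: AbundanceTable) -> DistanceMatrix:
    """Bray–Curtis dissimilarity between samples of a relative table."""
    if table.unit != "relative":
        raise ValueError("bray_curtis requires unit='relative' (apply normalize(..., 'tss'))")
    x = table.unstratified().to_numpy(dtype=float).T
    d = squareform(pdist(x, metric="braycurtis"))
    d = np.nan_to_num(d, nan=0.0)  # two all-zero samples are identical
    return DistanceMatrix(table.sample_ids, d, "braycurtis")


def unifrac(table: AbundanceTable, tree, weighted: bool = False) -> DistanceMatrix:
    """UniFrac distances on a Newick phylogeny.

    ``tree`` may be a newick string, a path, or an skbio TreeNode.  Every
    feature's terminal clade must map to a tree leaf; an unrooted (basal
    multifurcation) tree is midpoint-rooted with a warning.  The weighted
    form is the normalised weighted UniFrac.
    """
    import skbio
    from skbio.diversity import beta_diversity

    if isinstance(tree, skbio.TreeNode):
        t = tree
    else:
        text = str(tree)
        if "(" not in text:  # a path, not newick text
            with open(text) as fh:
                text = fh.read()
        t = skbio.TreeNode.read(io.StringIO(text), convert_underscores=False)
    if len(t.children) > 2:
        warnings.warn("unrooted tree: rooting at midpoint")
        t = t.root_at_midpoint()
    names = table.terminal_names()
    leaves = {leaf.name for leaf in t.tips()}
    missing = sorted(set(names) - leaves)
    if missing:
        raise ValueError(f"features without a tree leaf: {missing[:5]}")
    counts = table.unstratified().to_numpy(dtype=float).T
    if table.unit == "relative":
        # skbio truncates counts to integers; both UniFrac forms are
        # invariant to per-sample scale, so blow proportions up first
        counts = np.round(counts * 1e9)
    kwargs = {"normalized": True} if weighted else {}
    metric = "weighted_unifrac" if weighted else "unweighted_unifrac"
    dm = beta_diversity(metric, counts, ids=table.sample_ids, taxa=names, tree=t,
                        validate=True, **kwargs)
    return DistanceMatrix(list(dm.ids), np.asarray(dm.data, dtype=float),
                          "weighted_unifrac" if weighted else "unweighted_unifrac")


# ---------------------------------------------------------------------------
# principal coordinates
# ---------------------------------------------------------------------------

def pcoa(dist: DistanceMatrix, n_axes: int = 5) -> PcoaResult:
    """Classical scaling of a dissimilarity matrix (top ``n_axes`` axes)."""
    d2 = dist.values ** 2
    n = d2.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    evals, evecs = np.linalg.eigh((b + b.T) / 2.0)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    tol = max(1e-12, 1e-10 * max(abs(evals[0]), 1.0))
    pos = evals > tol
    negative = evals[evals < -tol]
    pos_vals = evals[pos]
    k = min(n_axes, pos_vals.size)
    if k < n_axes:
        warnings.warn(f"only {k} positive axes available (requested {n_axes})")
    coords = evecs[:, pos][:, :k] * np.sqrt(pos_vals[:k])
    frame = pd.DataFrame(coords, index=dist.sample_ids,
                         columns=[f"PCo{i + 1}" for i in range(k)])
    prop = pos_vals[:k] / pos_vals.sum() if pos_vals.size else np.zeros(0)
    return PcoaResult(frame, pos_vals[:k], prop, negative)
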