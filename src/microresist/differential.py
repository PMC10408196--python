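"""Group-level statistics across response groups.

Covers the distance-based test (PERMANOVA), ordinal (proportional-odds)
differential abundance across the three ordered response groups, Wilcoxon
rank-sum tests on gene families, 2x2 chi-square enrichment, Spearman
species-pathway association, stratified contribution linking, and BH-FDR
adjustment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .diversity import DistanceMatrix
from .profiles import AbundanceTable, contribution_ratios, parent_feature

GROUP_ORDER = ("non_responder", "partial_responder", "responder")

# BH thresholds used per analysis (configuration, not constants of the method)
DEFAULT_Q_SPECIES = 0.2
DEFAULT_Q_PATHWAYS = 0.1
DEFAULT_Q_KOS = 0.1
DEFAULT_Q_CORRELATIONS = 0.1


def fdr_adjust(pvals) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values (monotone in p-rank)."""
    p = np.asarray(pvals, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values outside [0, 1]")
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------

def _pseudo_f(d2: np.ndarray, groups: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """Anderson pseudo-F and R^2 from squared distances and integer labels."""
    n = d2.shape[0]
    ss_total = d2[np.triu_indices(n, 1)].sum() / n
    ss_within = 0.0
    for g in labels:
        idx = np.flatnonzero(groups == g)
        sub = d2[np.ix_(idx, idx)]
        ss_within += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
    ss_among = ss_total - ss_within
    a = len(labels)
    f = (ss_among / (a - 1)) / (ss_within / (n - a)) if ss_within > 0 else np.inf
    r2 = ss_among / ss_total if ss_total > 0 else 0.0
    return f, r2


def permanova(dist: DistanceMatrix, groups, n_perm: int = 999,
              seed: int | None = None) -> dict:
    """Permutational multivariate ANOVA on a distance matrix.

    Returns pseudo-F, R^2 = SS_among/SS_total and the permutation p-value
    (1 + #{F_perm >= F_obs}) / (1 + n_perm) under free label permutation.
    """
    g = np.asarray(pd.Series(list(groups)).astype("category").cat.codes)
    labels, counts = np.unique(g, return_counts=True)
    if len(labels) < 2:
        raise ValueError("need at least 2 groups")
    if counts.min() < 2:
        raise ValueError("every group needs at least 2 samples")
    if len(g) != dist.n:
        raise ValueError("group labels do not match the distance matrix")
    d2 = dist.values ** 2
    f_obs, r2 = _pseudo_f(d2, g, labels)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        f_perm, _ = _pseudo_f(d2, rng.permutation(g), labels)
        if f_perm >= f_obs:
            hits += 1
    p = (1 + hits) / (1 + n_perm)
    return {"pseudo_F": float(f_obs), "R2": float(r2), "p": float(p), "n_perm": n_perm}


# ---------------------------------------------------------------------------
# ordinal (proportional-odds) regression
# ---------------------------------------------------------------------------

@dataclass
class OrdinalFit:
    feature: str
    beta: float
    thresholds: tuple[float, float]
    p: float
    q: float = np.nan
    direction: str = ""
    separation: bool = False
    valid: bool = True
    max_grad: float = np.nan


def _null_loglik(y: np.ndarray) -> float:
    _, counts = np.unique(y, return_counts=True)
    props = counts / counts.sum()
    return float((counts * np.log(props)).sum())


def _sigmoid(u: np.ndarray) -> np.ndarray:
    out = np.empty_like(u)
    pos = u >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-u[pos]))
    e = np.exp(u[~pos])
    out[~pos] = e / (1.0 + e)
    return out


def _po_loglik(x: np.ndarray, masks, a0, a1, beta) -> np.ndarray:
    """Log-likelihood of the 3-category proportional-odds model, batched.

    x: (F, n); a0/a1/beta: (F,); masks: boolean (n,) per category.
    """
    u0 = a0[:, None] - beta[:, None] * x
    u1 = a1[:, None] - beta[:, None] * x
    f0, f1 = _sigmoid(u0), _sigmoid(u1)
    eps = 1e-300
    ll = np.zeros_like(x)
    ll[:, masks[0]] = np.log(f0[:, masks[0]] + eps)
    ll[:, masks[1]] = np.log(np.clip(f1[:, masks[1]] - f0[:, masks[1]], eps, None))
    ll[:, masks[2]] = np.log(1.0 - f1[:, masks[2]] + eps)
    return ll.sum(axis=1)


def _po_grad_hess(x, masks, a0, a1, beta):
    """Analytic gradient and observed Hessian, batched over features."""
    u0 = a0[:, None] - beta[:, None] * x
    u1 = a1[:, None] - beta[:, None] * x
    f0, f1 = _sigmoid(u0), _sigmoid(u1)
    d0f = f0 * (1 - f0)
    d1f = f1 * (1 - f1)
    m0, m1, m2 = masks
    d_a0 = np.zeros_like(x)
    d_a1 = np.zeros_like(x)
    h00 = np.zeros_like(x)
    h11 = np.zeros_like(x)
    h01 = np.zeros_like(x)
    # y = 0: log sigma(u0)
    d_a0[:, m0] = 1.0 - f0[:, m0]
    h00[:, m0] = -d0f[:, m0]
    # y = 2: log(1 - sigma(u1))
    d_a1[:, m2] = -f1[:, m2]
    h11[:, m2] = -d1f[:, m2]
    # y = 1: log(sigma(u1) - sigma(u0))
    p = np.clip(f1[:, m1] - f0[:, m1], 1e-12, None)
    g0 = -d0f[:, m1] / p
    g1 = d1f[:, m1] / p
    d_a0[:, m1] = g0
    d_a1[:, m1] = g1
    fp0 = d0f[:, m1] * (1 - 2 * f0[:, m1])
    fp1 = d1f[:, m1] * (1 - 2 * f1[:, m1])
    h00[:, m1] = -fp0 / p - (d0f[:, m1] / p) ** 2
    h11[:, m1] = fp1 / p - (d1f[:, m1] / p) ** 2
    h01[:, m1] = d0f[:, m1] * d1f[:, m1] / p ** 2
    grad = np.stack([d_a0.sum(1), d_a1.sum(1), (-x * (d_a0 + d_a1)).sum(1)], axis=1)
    hess = np.empty((x.shape[0], 3, 3))
    hess[:, 0, 0] = h00.sum(1)
    hess[:, 1, 1] = h11.sum(1)
    hess[:, 0, 1] = hess[:, 1, 0] = h01.sum(1)
    hess[:, 0, 2] = hess[:, 2, 0] = (-x * (h00 + h01)).sum(1)
    hess[:, 1, 2] = hess[:, 2, 1] = (-x * (h01 + h11)).sum(1)
    hess[:, 2, 2] = (x ** 2 * (h00 + 2 * h01 + h11)).sum(1)
    return grad, hess


def fit_ordinal_batch(x: np.ndarray, labels, max_iter: int = 100,
                      tol: float = 1e-8) -> pd.DataFrame:
    """Damped-Newton proportional-odds fit for many features at once.

    ``x`` is features x samples; ``labels`` the shared ordered outcome.
    Cumulative logits P(Y <= j) = logistic(theta_j - beta * x); beta > 0
    means enrichment toward responders.  Wald p from the observed
    information; monotone separation (exploding |beta| or standard error)
    switches the feature to a likelihood-ratio p-value and sets a flag.
    """
    lab = list(labels)
    present = [g for g in GROUP_ORDER if g in lab]
    if len(present) < 2:
        raise ValueError("need at least 2 distinct ordered labels")
    y = np.asarray([present.index(g) for g in lab])
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        x = x[None, :]
    n_feat, n = x.shape
    masks = [y == j for j in range(3)]
    valid = np.ptp(x, axis=1) > 0
    # scale covariates to unit SD for conditioning; beta rescaled afterwards
    sd = np.where(valid, x.std(axis=1, ddof=1), 1.0)
    xs = (x - x.mean(axis=1, keepdims=True)) / sd[:, None]
    # starting thresholds from the empirical cumulative logits
    c0 = max(masks[0].mean(), 1e-3)
    c1 = max((masks[0] | masks[1]).mean(), c0 + 1e-3)
    a0 = np.full(n_feat, np.log(c0 / (1 - c0 + 1e-12)))
    a1 = np.full(n_feat, np.log(min(c1, 1 - 1e-3) / max(1 - c1, 1e-3)))
    beta = np.zeros(n_feat)
    ll = _po_loglik(xs, masks, a0, a1, beta)
    active = valid.copy()
    for _ in range(max_iter):
        if not active.any():
            break
        grad, hess = _po_grad_hess(xs[active], masks, a0[active], a1[active],
                                   beta[active])
        step = np.zeros_like(grad)
        for i, idx in enumerate(np.flatnonzero(active)):
            h = hess[i] - 1e-10 * np.eye(3)
            try:
                step[i] = np.linalg.solve(h, grad[i])
            except np.linalg.LinAlgError:
                step[i] = grad[i] * 1e-3
        # damped update with per-feature step halving
        idxs = np.flatnonzero(active)
        scale = np.ones(len(idxs))
        for _half in range(30):
            na0 = a0[idxs] - scale * step[:, 0]
            na1 = a1[idxs] - scale * step[:, 1]
            nb = beta[idxs] - scale * step[:, 2]
            bad = na1 <= na0
            nll = _po_loglik(xs[idxs], masks, na0, na1, nb)
            worse = bad | (nll < ll[idxs] - 1e-12)
            if not worse.any():
                break
            scale[worse] *= 0.5
        a0[idxs], a1[idxs], beta[idxs] = na0, na1, nb
        improved = np.abs(nll - ll[idxs]) > tol * (np.abs(ll[idxs]) + 1.0)
        gmax = np.abs(grad).max(axis=1)
        ll[idxs] = nll
        still = improved | (gmax > 1e-6)
        active[idxs] = still
    grad_all, hess_all = _po_grad_hess(xs, masks, a0, a1, beta)
    max_grad = np.abs(grad_all).max(axis=1)
    se = np.full(n_feat, np.inf)
    for f in range(n_feat):
        if not valid[f]:
            continue
        try:
            cov = np.linalg.inv(-hess_all[f])
            if cov[2, 2] > 0:
                se[f] = np.sqrt(cov[2, 2])
        except np.linalg.LinAlgError:
            pass
    beta_raw = beta / sd
    se_raw = se / sd
    separation = valid & ((np.abs(beta) > 30) | (se > 1e3))
    with np.errstate(divide="ignore", invalid="ignore"):
        p_wald = 2.0 * stats.norm.sf(np.abs(beta) / se)
    ll_null = _null_loglik(y)
    lr = np.clip(2.0 * (ll - ll_null), 0.0, None)
    p_lr = stats.chi2.sf(lr, df=1)
    p = np.where(separation, p_lr, p_wald)
    out = pd.DataFrame({
        "beta": np.where(valid, beta_raw, np.nan),
        "theta0": a0 + beta * x.mean(axis=1) / sd,
        "theta1": a1 + beta * x.mean(axis=1) / sd,
        "p": np.where(valid, p, np.nan),
        "separation": separation,
        "valid": valid,
        "max_grad": max_grad,
    })
    return out


def fit_ordinal_regression(values, labels, feature: str = "") -> OrdinalFit:
    """Proportional-odds fit of one feature against the ordered groups."""
    x = np.asarray(values, dtype=float)
    res = fit_ordinal_batch(x[None, :], labels)
    row = res.iloc[0]
    if not row.valid:
        return OrdinalFit(feature, np.nan, (np.nan, np.nan), np.nan, valid=False)
    direction = "responder" if row.beta > 0 else "non_responder"
    return OrdinalFit(feature, float(row.beta), (float(row.theta0), float(row.theta1)),
                      float(row.p), direction=direction,
                      separation=bool(row.separation), max_grad=float(row.max_grad))


def ordinal_da(table: AbundanceTable, labels: pd.Series,
               transform: bool = True) -> pd.DataFrame:
    """Per-feature ordinal regression across the three response groups.

    ``labels`` maps sample id -> ordered label; relative abundances are
    arcsine-root transformed before fitting (per-feature covariate only).
    """
    from .stability import transform_measurements

    data = table.relative().unstratified() if transform else table.unstratified()
    samples = [s for s in data.columns if s in labels.index]
    lab = labels.loc[samples]
    x = data[samples].to_numpy(dtype=float)
    if transform:
        x = transform_measurements(np.clip(x, 0, 1), "arcsine_sqrt")
    fits = fit_ordinal_batch(x, lab)
    out = pd.DataFrame({
        "feature": list(data.index), "beta": fits["beta"], "p": fits["p"],
        "direction": np.where(fits["beta"] > 0, "responder", "non_responder"),
        "separation": fits["separation"], "valid": fits["valid"],
    })
    ok = out["valid"] & out["p"].notna()
    out["q"] = np.nan
    if ok.any():
        out.loc[ok, "q"] = fdr_adjust(out.loc[ok, "p"])
    return out


# ---------------------------------------------------------------------------
# Wilcoxon differential abundance (responders vs non-responders)
# ---------------------------------------------------------------------------

def wilcoxon_da(table: AbundanceTable, labels: pd.Series) -> pd.DataFrame:
    """Rank-sum test per feature between responders and non-responders.

    log2FC = log2((mean_R + eps) / (mean_NR + eps)) with eps half the
    smallest nonzero value in the table, so the pseudo-count follows the
    data scale (CPM vs relative).
    """
    data = table.unstratified()
    samples = [s for s in data.columns if s in labels.index]
    lab = labels.loc[samples]
    r_ids = [s for s in samples if lab[s] == "responder"]
    n_ids = [s for s in samples if lab[s] == "non_responder"]
    if not r_ids or not n_ids:
        raise ValueError("both groups must be non-empty")
    xr = data[r_ids].to_numpy(dtype=float)
    xn = data[n_ids].to_numpy(dtype=float)
    nonzero = data.to_numpy()[data.to_numpy() > 0]
    eps = 0.5 * nonzero.min() if nonzero.size else 1e-12
    rows = []
    for i, f in enumerate(data.index):
        if np.ptp(np.concatenate([xr[i], xn[i]])) == 0:
            p = 1.0
        else:
            _, p = stats.mannwhitneyu(xr[i], xn[i], alternative="two-sided",
                                      method="asymptotic")
        lfc = np.log2((xr[i].mean() + eps) / (xn[i].mean() + eps))
        rows.append({"feature": f, "log2FC": float(lfc), "p": float(p)})
    out = pd.DataFrame(rows)
    out["q"] = fdr_adjust(out["p"])
    return out


# ---------------------------------------------------------------------------
# chi-square enrichment
# ---------------------------------------------------------------------------

def chi_square_enrichment(k_hit_a: int, k_tot_a: int, k_hit_b: int,
                          k_tot_b: int) -> tuple[float, float]:
    """Pearson chi-square (no continuity correction) on a 2x2 hit table."""
    if k_tot_a <= 0 or k_tot_b <= 0:
        raise ValueError("totals must be positive")
    if k_hit_a > k_tot_a or k_hit_b > k_tot_b:
        raise ValueError("hit counts exceed totals")
    obs = np.array([[k_hit_a, k_tot_a - k_hit_a],
                    [k_hit_b, k_tot_b - k_hit_b]], dtype=float)
    if obs.sum(axis=0).min() == 0 or obs.sum(axis=1).min() == 0:
        return 0.0, 1.0
    chi2, p, _, expected = stats.chi2_contingency(obs, correction=False)
    if expected.min() < 5:
        warnings.warn("chi-square approximation doubtful: expected count < 5")
    return float(chi2), float(p)


# ---------------------------------------------------------------------------
# Spearman association between two feature sets
# ---------------------------------------------------------------------------

def spearman_assoc(table_a: AbundanceTable, table_b: AbundanceTable) -> pd.DataFrame:
    """All-pairs Spearman correlation between two tables' features.

    Shares samples by id (>= 4 required); ties get mean ranks, p-values
    use the t approximation, and BH adjustment runs across the full
    matrix.  Constant features yield NaN rho, flagged rather than tested.
    """
    shared = [s for s in table_a.sample_ids if s in set(table_b.sample_ids)]
    if len(shared) < 4:
        raise ValueError("need at least 4 shared samples")
    a = table_a.unstratified()[shared].to_numpy(dtype=float)
    b = table_b.unstratified()[shared].to_numpy(dtype=float)
    n = len(shared)
    ra = np.apply_along_axis(stats.rankdata, 1, a)
    rb = np.apply_along_axis(stats.rankdata, 1, b)
    const_a = np.ptp(a, axis=1) == 0
    const_b = np.ptp(b, axis=1) == 0
    za = (ra - ra.mean(axis=1, keepdims=True))
    zb = (rb - rb.mean(axis=1, keepdims=True))
    sa = np.sqrt((za ** 2).sum(axis=1))
    sb = np.sqrt((zb ** 2).sum(axis=1))
    with np.errstate(divide="ignore", invalid="ignore"):
        rho = (za @ zb.T) / np.outer(sa, sb)
    rho[const_a, :] = np.nan
    rho[:, const_b] = np.nan
    rho = np.clip(rho, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho * np.sqrt((n - 2) / (1.0 - rho ** 2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p[np.isclose(np.abs(rho), 1.0)] = 0.0
    rows = []
    fa, fb = list(table_a.unstratified().index), list(table_b.unstratified().index)
    for i, f1 in enumerate(fa):
        for j, f2 in enumerate(fb):
            rows.append({"feature_a": f1, "feature_b": f2,
                         "rho": float(rho[i, j]), "p": float(p[i, j])})
    out = pd.DataFrame(rows)
    ok = out["rho"].notna()
    out["q"] = np.nan
    if ok.any():
        out.loc[ok, "q"] = fdr_adjust(out.loc[ok, "p"])
    return out


# ---------------------------------------------------------------------------
# stratified contribution linking
# ---------------------------------------------------------------------------

@dataclass
class ContributionLink:
    species: str
    function: str
    contributes: bool
    fraction: float


def link_contributions(stratified: AbundanceTable, species_list, function_list,
                       min_prevalence: float = 0.1) -> list[ContributionLink]:
    """Which species contribute to which functions, and how much.

    A species contributes to a function when its stratified row is nonzero
    in at least ``min_prevalence`` of samples; the contribution fraction
    is the mean stratified/unstratified ratio over samples with a nonzero
    community total.  Species absent from the stratification simply do
    not contribute (no error).
    """
    ratios = contribution_ratios(stratified)
    strat = stratified.stratified()
    # map (function, species terminal name) -> stratified row id
    index: dict[tuple[str, str], str] = {}
    for fid in strat.index:
        func = parent_feature(fid)
        tax = fid.split("|", 1)[1]
        sp = tax.split(".")[-1] if "." in tax else tax
        index[(func, sp)] = fid
    links = []
    n_samples = stratified.n_samples
    for sp in species_list:
        terminal = sp.rsplit("|", 1)[-1]
        for func in function_list:
            fid = index.get((func, terminal))
            if fid is None:
                links.append(ContributionLink(sp, func, False, 0.0))
                continue
            prev = float((strat.loc[fid] > 0).sum()) / n_samples
            frac = float(np.nanmean(ratios.loc[fid])) if ratios.loc[fid].notna().any() else 0.0
            links.append(ContributionLink(sp, func, prev >= min_prevalence,
                                          float(np.clip(frac, 0.0, 1.0))))
    return links


def links_table(links: list[ContributionLink]) -> pd.DataFrame:
    return pd.DataFrame([{
        "species": l.species, "function": l.function,
        "contributes": l.contributes, "fraction": l.fraction,
    } for l in links])
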