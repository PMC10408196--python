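"""Intraclass-correlation estimation of microbiome stability.

The stability of a measurement (a diversity index, a PCoA axis, or a
single feature's abundance) across repeated visits of the same subject is
summarised by the two-way random-effects, absolute-agreement, mean-rating
intraclass correlation ICC(A,k):

    ICC(A,k) = (MS_R - MS_E) / (MS_R + (MS_C - MS_E) / n)

with MS_R, MS_C, MS_E the subject, occasion and residual mean squares of
the subjects x occasions ANOVA.  Values run from 0 (no stability) to 1
(perfect stability); negative estimates are truncated to 0 and estimates
with fewer than 3 subjects or no total variance are flagged invalid.
Confidence intervals are percentile bootstrap over subjects.

Measurements are transformed before estimation: diversity indexes with a
rank-based inverse-normal (Blom) transform, relative abundances with
arcsine square-root.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .profiles import AbundanceTable, SampleMetadata

DEFAULT_STABILITY_THRESHOLD = 0.5


@dataclass
class ICCResult:
    target: str
    icc: float              # in [0, 1]; NaN when invalid
    ci_low: float
    ci_high: float
    n_subjects: int
    k: int
    valid: bool
    transformation: str = "none"
    ms_r: float = np.nan
    ms_c: float = np.nan
    ms_e: float = np.nan

    def stable(self, threshold: float = DEFAULT_STABILITY_THRESHOLD) -> bool:
        """Strict stability call: ICC strictly above the threshold."""
        return bool(self.valid and self.icc > threshold)


# ---------------------------------------------------------------------------
# transforms
# ---------------------------------------------------------------------------

def transform_measurements(values, kind: str) -> np.ndarray:
    """``arcsine_sqrt`` for proportions, ``gaussianize`` for anything else.

    The Gaussianizing transform is the rank-based inverse-normal transform
    with Blom offsets, z = Phi^-1((r - 3/8) / (n + 1/4)); ties share their
    mean rank, so any monotone re-expression of the input produces the
    same output.
    """
    x = np.asarray(values, dtype=float)
    if kind == "arcsine_sqrt":
        if np.any((x < 0) | (x > 1)):
            raise ValueError("arcsine_sqrt requires values in [0, 1]")
        return np.arcsin(np.sqrt(x))
    if kind == "gaussianize":
        flat = x.ravel()
        ok = np.isfinite(flat)
        ranks = stats.rankdata(flat[ok], method="average")
        n = ok.sum()
        z = stats.norm.ppf((ranks - 0.375) / (n + 0.25))
        out = np.full(flat.shape, np.nan)
        out[ok] = z
        return out.reshape(x.shape)
    raise ValueError("kind must be 'gaussianize' or 'arcsine_sqrt'")


# ---------------------------------------------------------------------------
# ICC estimation
# ---------------------------------------------------------------------------

def _anova_ms(m: np.ndarray) -> tuple[float, float, float]:
    """Two-way crossed ANOVA mean squares (subjects x occasions)."""
    n, k = m.shape
    grand = m.mean()
    rows = m.mean(axis=1)
    cols = m.mean(axis=0)
    ms_r = k * np.sum((rows - grand) ** 2) / (n - 1)
    ms_c = n * np.sum((cols - grand) ** 2) / (k - 1)
    resid = m - rows[:, None] - cols[None, :] + grand
    ms_e = np.sum(resid ** 2) / ((n - 1) * (k - 1))
    return ms_r, ms_c, ms_e


def _icc_ak(m: np.ndarray) -> float:
    n, _ = m.shape
    ms_r, ms_c, ms_e = _anova_ms(m)
    denom = ms_r + (ms_c - ms_e) / n
    if denom <= 0:
        return 0.0
    return float(np.clip((ms_r - ms_e) / denom, 0.0, 1.0))


def _invalid(target: str, n: int, k: int, transformation: str) -> ICCResult:
    return ICCResult(target, np.nan, np.nan, np.nan, n, k, False, transformation)


def estimate_icc(measurements, n_boot: int = 1000, seed: int | None = None,
                 target: str = "", transformation: str = "none") -> ICCResult:
    """ICC(A,k) of a subjects x k measurement matrix with bootstrap CI.

    Subjects containing missing cells are dropped (reported via warning).
    Fewer than 3 complete subjects, or an all-constant matrix, yields an
    invalid result rather than an exception.
    """
    m = np.asarray(measurements, dtype=float)
    if m.ndim != 2 or m.shape[1] < 2:
        raise ValueError("measurements must be a subjects x k matrix with k >= 2")
    complete = np.all(np.isfinite(m), axis=1)
    if not complete.all():
        warnings.warn(f"dropping {int((~complete).sum())} subject(s) with missing cells")
    m = m[complete]
    n, k = m.shape
    if n < 3 or np.ptp(m) == 0:
        return _invalid(target, n, k, transformation)
    icc = _icc_ak(m)
    ms_r, ms_c, ms_e = _anova_ms(m)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_boot, n))
    boots = _icc_ak_batch(m[idx])
    lo, hi = np.nanpercentile(boots, [2.5, 97.5])
    lo, hi = min(lo, icc), max(hi, icc)
    return ICCResult(target, icc, float(lo), float(hi), n, k, True, transformation,
                     ms_r, ms_c, ms_e)


def _icc_ak_batch(b: np.ndarray) -> np.ndarray:
    """Vectorised ICC(A,k) over a batch of resampled matrices (B, n, k)."""
    _, n, k = b.shape
    grand = b.mean(axis=(1, 2), keepdims=True)
    rows = b.mean(axis=2, keepdims=True)
    cols = b.mean(axis=1, keepdims=True)
    ms_r = k * ((rows - grand) ** 2).sum(axis=(1, 2)) / (n - 1)
    ms_c = n * ((cols - grand) ** 2).sum(axis=(1, 2)) / (k - 1)
    resid = b - rows - cols + grand
    ms_e = (resid ** 2).sum(axis=(1, 2)) / ((n - 1) * (k - 1))
    denom = ms_r + (ms_c - ms_e) / n
    with np.errstate(divide="ignore", invalid="ignore"):
        icc = np.where(denom > 0, (ms_r - ms_e) / denom, 0.0)
    return np.clip(icc, 0.0, 1.0)


# ---------------------------------------------------------------------------
# profile-level ICC
# ---------------------------------------------------------------------------

def feature_icc_profile(table: AbundanceTable, metadata: SampleMetadata,
                        k: int = 2, n_boot: int = 1000,
                        seed: int | None = None) -> list[ICCResult]:
    """Per-feature ICC of arcsine-root relative abundances.

    Subjects contribute their first ``k`` samples by collection day;
    subjects with fewer samples are excluded (warning).  Features absent
    from every sample are returned as non-valid ICC.
    """
    rel = table.relative()
    pairs, excluded = metadata.for_samples(rel.sample_ids).paired_samples(k)
    if excluded:
        warnings.warn(f"excluding {len(excluded)} subject(s) with fewer than {k} samples")
    if not pairs:
        raise ValueError("no subject contributes k samples")
    sample_sets = list(pairs.values())
    data = rel.unstratified()
    cube = np.stack([data[cols].to_numpy(dtype=float) for cols in sample_sets], axis=1)
    # cube: features x subjects x k
    cube = transform_measurements(np.clip(cube, 0.0, 1.0), "arcsine_sqrt")
    rng = np.random.default_rng(seed)
    results = []
    for f, fid in enumerate(data.index):
        m = cube[f]
        if np.ptp(m) == 0:
            results.append(_invalid(fid, m.shape[0], k, "arcsine_sqrt"))
            continue
        results.append(estimate_icc(m, n_boot=n_boot,
                                    seed=int(rng.integers(2 ** 31)),
                                    target=fid, transformation="arcsine_sqrt"))
    return results


def diversity_icc(values: pd.Series, metadata: SampleMetadata, k: int = 2,
                  n_boot: int = 1000, seed: int | None = None,
                  target: str = "") -> ICCResult:
    """ICC of a per-sample measurement series, Gaussianised first."""
    pairs, _ = metadata.for_samples(values.index).paired_samples(k)
    if not pairs:
        raise ValueError("no subject contributes k samples")
    m = np.array([[values[s] for s in cols] for cols in pairs.values()], dtype=float)
    m = transform_measurements(m, "gaussianize")
    return estimate_icc(m, n_boot=n_boot, seed=seed, target=target,
                        transformation="gaussianize")


def icc_table(results: list[ICCResult],
              threshold: float = DEFAULT_STABILITY_THRESHOLD) -> pd.DataFrame:
    rows = [{
        "target": r.target, "icc": r.icc, "ci_low": r.ci_low, "ci_high": r.ci_high,
        "n_subjects": r.n_subjects, "k": r.k, "valid": r.valid,
        "transformation": r.transformation, "ms_r": r.ms_r, "ms_c": r.ms_c,
        "ms_e": r.ms_e, "stable": r.stable(threshold),
    } for r in results]
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# cross-cohort comparison
# ---------------------------------------------------------------------------

def compare_icc_groups(icc_sets: dict[str, pd.Series], paired: bool = False) -> pd.DataFrame:
    """Pairwise t-tests between named sets of ICC values, BH-adjusted.

    ``paired=True`` requires identical target ids across each compared
    pair (per-target differences); otherwise a Welch two-sample t-test on
    the pooled values is used.
    """
    names = list(icc_sets)
    rows = []
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            xa, xb = icc_sets[a].dropna(), icc_sets[b].dropna()
            if paired:
                if set(xa.index) != set(xb.index):
                    diff = set(xa.index) ^ set(xb.index)
                    raise ValueError(f"paired comparison with mismatched targets: "
                                     f"{sorted(diff)[:5]}")
                xb = xb.reindex(xa.index)
                if np.allclose(xa.to_numpy(), xb.to_numpy()):
                    t, p = 0.0, 1.0
                else:
                    t, p = stats.ttest_rel(xa, xb)
            else:
                t, p = stats.ttest_ind(xa, xb, equal_var=False)
            rows.append({"group_a": a, "group_b": b, "t": float(t), "p": float(p)})
    out = pd.DataFrame(rows)
    if len(out):
        from statsmodels.stats.multitest import multipletests
        out["q"] = multipletests(out["p"], method="fdr_bh")[1]
    return out
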