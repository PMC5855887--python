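"""Community-composition analysis: standardization, Bray-Curtis distances,
nonmetric multidimensional scaling, PERMANOVA and PERMDISP.

The abundance matrix mixes measurement metrics (density, basal cover, canopy
cover), so each species column is z-scored before analysis, which weights
common and rare species equally; a constant +2 shift then makes values
positive for Bray-Curtis (z-scores below -2 are floored at 0.01 with a
warning).  The permutation tests are implemented from first principles:
PERMANOVA partitions squared inter-point distances into among- and
within-group sums of squares and permutes group labels; PERMDISP embeds the
distance matrix by principal coordinates (with the standard correction for
negative eigenvalues), measures each sample's distance to its group
centroid, and permutes those distances under a one-way ANOVA F statistic.
NMDS minimizes Kruskal stress-1 by alternating isotonic regression of
configuration distances on dissimilarities with Guttman-transform updates,
over several random restarts plus a metric (PCoA) start.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
from sklearn.isotonic import IsotonicRegression


# ---------------------------------------------------------------------------
# matrix preparation
# ---------------------------------------------------------------------------

def community_pivot(long_table: pd.DataFrame) -> pd.DataFrame:
    """Pivot a long (plot, year, treatment, species, value) table to wide.

    The result has a (plot_id, year, treatment) MultiIndex and one column
    per species.
    """
    wide = long_table.pivot_table(index=["plot_id", "year", "treatment"],
                                  columns="species", values="value", aggfunc="sum")
    return wide.fillna(0.0)


def standardize_abundance(raw_matrix: pd.DataFrame, offset: float = 2.0,
                          floor: float = 0.01) -> pd.DataFrame:
    """Per-column z-score (population s.d.) plus a positivity offset.

    Zero-variance columns are dropped with a warning.  Values still <= 0
    after the offset (z-scores < -2) are floored at ``floor`` with a
    warning, since Bray-Curtis requires positive abundances.
    """
    if len(raw_matrix) < 2:
        raise ValueError("need >= 2 samples to standardize")
    mat = raw_matrix.astype(float)
    sds = mat.std(axis=0, ddof=0)
    dead = sds[sds == 0].index.tolist()
    if dead:
        warnings.warn(f"dropping {len(dead)} zero-variance species column(s): {dead[:5]}")
        mat = mat.drop(columns=dead)
        sds = sds.drop(dead)
    z = (mat - mat.mean(axis=0)) / sds
    shifted = z + offset
    n_low = int((shifted <= 0).to_numpy().sum())
    if n_low:
        warnings.warn(f"{n_low} standardized value(s) <= 0 after +{offset} shift; floored at {floor}")
        shifted = shifted.clip(lower=floor)
    return shifted


def bray_curtis(matrix) -> np.ndarray:
    """Pairwise Bray-Curtis distances: sum|x-y| / sum(x+y), zero diagonal."""
    X = np.asarray(matrix, dtype=float)
    if (X < 0).any():
        raise ValueError("Bray-Curtis requires non-negative values")
    n = X.shape[0]
    totals = X.sum(axis=1)
    denom = totals[:, None] + totals[None, :]
    if np.any((denom == 0) & ~np.eye(n, dtype=bool)):
        raise ValueError("a pair of samples has all-zero abundances")
    num = np.abs(X[:, None, :] - X[None, :, :]).sum(axis=2)
    with np.errstate(invalid="ignore"):
        D = np.where(denom > 0, num / np.where(denom > 0, denom, 1.0), 0.0)
    np.fill_diagonal(D, 0.0)
    return D


# ---------------------------------------------------------------------------
# NMDS
# ---------------------------------------------------------------------------

@dataclass
class OrdinationResult:
    """NMDS scores with final Kruskal stress-1."""

    scores: np.ndarray
    stress: float
    n_restarts: int
    converged: bool
    stress_history: list


def _pcoa_coords(D: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Principal-coordinate embedding: returns (real axes, neg axes, eigvals)."""
    n = len(D)
    J = np.eye(n) - np.ones((n, n)) / n
    G = -0.5 * J @ (D ** 2) @ J
    vals, vecs = np.linalg.eigh((G + G.T) / 2)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    pos = vals > 1e-10
    neg = vals < -1e-10
    real = vecs[:, pos] * np.sqrt(vals[pos])
    imag = vecs[:, neg] * np.sqrt(-vals[neg])
    return real, imag, vals


def _kruskal_stress(d: np.ndarray, dhat: np.ndarray) -> float:
    return float(np.sqrt(np.sum((d - dhat) ** 2) / np.sum(d ** 2)))


def nmds(distances: np.ndarray, k: int = 2, n_restarts: int = 8, seed: int = 0,
         max_iter: int = 300, tol: float = 1e-7) -> OrdinationResult:
    """Nonmetric MDS minimizing Kruskal stress-1.

    Alternates isotonic regression of configuration distances on the rank
    order of the input dissimilarities (disparities) with Guttman-transform
    configuration updates.  The best of ``n_restarts`` random starts plus a
    metric PCoA start is returned; scores are centered at the origin.
    """
    D = np.asarray(distances, dtype=float)
    n = len(D)
    if n < 4:
        raise ValueError("need >= 4 samples for a 2-D ordination")
    iu = np.triu_indices(n, 1)
    delta = D[iu]
    order = np.argsort(delta, kind="stable")
    iso = IsotonicRegression()
    rng = np.random.default_rng(seed)

    starts = []
    real, _, _ = _pcoa_coords(D, k)
    if real.shape[1] >= k:
        starts.append(real[:, :k].copy())
    else:
        pad = np.zeros((n, k))
        pad[:, :real.shape[1]] = real
        starts.append(pad)
    for _ in range(n_restarts):
        starts.append(rng.normal(size=(n, k)))

    best = None
    for X in starts:
        X = X - X.mean(axis=0)
        scale = np.sqrt((X ** 2).sum())
        if scale > 0:
            X = X / scale * np.sqrt(n)
        history = []
        converged = False
        prev = np.inf
        for _ in range(max_iter):
            d = np.sqrt(((X[:, None, :] - X[None, :, :]) ** 2).sum(-1))[iu]
            dhat = iso.fit_transform(np.arange(len(order)), d[order])
            inv = np.empty_like(dhat)
            inv[order] = dhat
            stress = _kruskal_stress(d, inv)
            history.append(stress)
            if prev - stress < tol:
                converged = True
                break
            prev = stress
            # Guttman transform toward the disparities
            W = np.zeros((n, n))
            ratio = np.where(d > 1e-12, inv / np.where(d > 1e-12, d, 1.0), 1.0)
            W[iu] = ratio
            W = W + W.T
            B = -W
            np.fill_diagonal(B, W.sum(axis=1))
            X = B @ X / n
            X = X - X.mean(axis=0)
        final = history[-1] if history else np.inf
        if best is None or final < best.stress:
            best = OrdinationResult(scores=X - X.mean(axis=0), stress=final,
                                    n_restarts=n_restarts, converged=converged,
                                    stress_history=history)
    return best


# ---------------------------------------------------------------------------
# permutation tests
# ---------------------------------------------------------------------------

@dataclass
class PermTestResult:
    """Permutation-test outcome for PERMANOVA ('adonis') or PERMDISP ('betadisper')."""

    test: str
    F: float
    p_value: float
    n: int
    df: tuple
    n_permutations: int
    p_parametric: float | None = None


def _check_groups(groups: np.ndarray):
    labels, counts = np.unique(groups, return_counts=True)
    if len(labels) < 2:
        raise ValueError("need >= 2 groups")
    if (counts < 2).any():
        small = labels[counts < 2]
        raise ValueError(f"group(s) of size 1 not allowed: {list(small)}")
    return labels


def _permanova_F(D2: np.ndarray, groups: np.ndarray, labels) -> float:
    n = len(groups)
    a = len(labels)
    ss_total = D2[np.triu_indices(n, 1)].sum() / n
    ss_within = 0.0
    for g in labels:
        idx = np.flatnonzero(groups == g)
        sub = D2[np.ix_(idx, idx)]
        ss_within += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
    ss_among = ss_total - ss_within
    return (ss_among / (a - 1)) / (ss_within / (n - a))


def permanova(distances: np.ndarray, groups, n_permutations: int = 999,
              seed: int = 0) -> PermTestResult:
    """Permutational multivariate ANOVA (pseudo-F) on a distance matrix.

    p = (1 + #{F_perm >= F_obs}) / (1 + n_permutations) under free
    permutation of group labels.
    """
    D = np.asarray(distances, dtype=float)
    groups = np.asarray(groups)
    labels = _check_groups(groups)
    D2 = D ** 2
    n, a = len(groups), len(labels)
    F_obs = _permanova_F(D2, groups, labels)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_permutations):
        perm = rng.permutation(groups)
        if _permanova_F(D2, perm, labels) >= F_obs:
            hits += 1
    p = (1 + hits) / (1 + n_permutations)
    return PermTestResult("adonis", float(F_obs), float(p), n, (a - 1, n - a), n_permutations)


def centroid_distances(distances: np.ndarray, groups) -> np.ndarray:
    """Distance of each sample to its group centroid in PCoA space.

    Negative eigenvalues are handled with the imaginary-axis correction:
    squared centroid distance = (real-part distance)^2 - (imaginary-part
    distance)^2, floored at zero.
    """
    D = np.asarray(distances, dtype=float)
    groups = np.asarray(groups)
    real, imag, _ = _pcoa_coords(D, k=len(D))
    out = np.empty(len(groups))
    for g in np.unique(groups):
        idx = np.flatnonzero(groups == g)
        c_real = real[idx].mean(axis=0)
        d2 = ((real[idx] - c_real) ** 2).sum(axis=1)
        if imag.shape[1]:
            c_imag = imag[idx].mean(axis=0)
            d2 = d2 - ((imag[idx] - c_imag) ** 2).sum(axis=1)
        out[idx] = np.sqrt(np.maximum(d2, 0.0))
    return out


def _anova_F(values: np.ndarray, groups: np.ndarray, labels) -> float:
    grand = values.mean()
    ss_among = sum(len(values[groups == g]) * (values[groups == g].mean() - grand) ** 2
                   for g in labels)
    ss_within = sum(((values[groups == g] - values[groups == g].mean()) ** 2).sum()
                    for g in labels)
    a, n = len(labels), len(values)
    if ss_within == 0:
        return np.inf if ss_among > 0 else 0.0
    return (ss_among / (a - 1)) / (ss_within / (n - a))


def permdisp(distances: np.ndarray, groups, n_permutations: int = 999,
             seed: int = 0) -> PermTestResult:
    """Homogeneity-of-dispersion test on distances to group centroids.

    One-way ANOVA F on sample-to-centroid distances; the permutation p-value
    shuffles those distances among samples, and the parametric F-test p is
    also reported.
    """
    D = np.asarray(distances, dtype=float)
    groups = np.asarray(groups)
    labels = _check_groups(groups)
    z = centroid_distances(D, groups)
    n, a = len(groups), len(labels)
    F_obs = _anova_F(z, groups, labels)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_permutations):
        if _anova_F(rng.permutation(z), groups, labels) >= F_obs:
            hits += 1
    p = (1 + hits) / (1 + n_permutations)
    p_param = float(scipy.stats.f.sf(F_obs, a - 1, n - a)) if np.isfinite(F_obs) else 0.0
    return PermTestResult("betadisper", float(F_obs), float(p), n, (a - 1, n - a),
                          n_permutations, p_parametric=p_param)


def yearly_tests(long_table: pd.DataFrame, n_permutations: int = 999,
                 seed: int = 0) -> pd.DataFrame:
    """Per-year PERMANOVA and PERMDISP on the standardized community matrix.

    Returns a table shaped like the study's clustering/dispersion summary:
    year, test, n, d.f., F, P.
    """
    rows = []
    for i, (year, sub) in enumerate(sorted(long_table.groupby("year"))):
        wide = community_pivot(sub)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            mat = standardize_abundance(wide)
        D = bray_curtis(mat.to_numpy())
        groups = mat.index.get_level_values("treatment").to_numpy()
        for test_fn in (permanova, permdisp):
            res = test_fn(D, groups, n_permutations=n_permutations, seed=seed + i)
            rows.append({"year": year, "test": res.test, "n": res.n,
                         "df": res.df[0], "F": res.F, "P": res.p_value})
    return pd.DataFrame(rows)
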