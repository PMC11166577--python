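"""Graph-spatial statistics on projected cell graphs.

Polarity: Moran's I spatial autocorrelation of each marker's
CLR-transformed node counts, with spatial weights given by the
row-normalised adjacency matrix of the one-mode UPI-A projection.
The analytic randomisation null (E[I] = -1/(N-1) and the standard
randomisation variance) yields a z-score and two-sided P value.

Colocalization: per unordered marker pair, Pearson's r between the
markers' neighbourhood-aggregated log1p counts, compared against a
Gaussian fit to the same statistic on components whose marker counts
were independently shuffled across nodes (equal abundance, random
localisation). The reported colocalization score is the z-score.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats

from .graph import CountMatrix, ProjectedGraph


def clr_transform(counts) -> np.ndarray:
    """Centered log ratio with a unit pseudocount.

    clr_i = ln(1 + x_i) - mean_j ln(1 + x_j); the output sums to zero.
    The ln(1+x) form keeps zero counts finite, which dominate sparse
    antibody panels.
    """
    x = np.asarray(counts, dtype=float)
    if x.size == 0:
        raise ValueError("clr_transform requires a non-empty vector")
    if (x < 0).any():
        raise ValueError("counts must be >= 0")
    logs = np.log1p(x)
    return logs - logs.mean()


# ---------------------------------------------------------------------------
# Moran's I


@dataclass(frozen=True)
class MoranResult:
    I: float
    z: float
    p: float
    expected: float
    n_nodes: int


def _row_normalize(adj: sp.spmatrix) -> sp.csr_matrix:
    adj = sp.csr_matrix(adj, dtype=float)
    deg = np.asarray(adj.sum(axis=1)).ravel()
    if (deg == 0).any():
        raise ValueError("graph has isolated nodes; supply one component")
    inv = sp.diags(1.0 / deg)
    return (inv @ adj).tocsr()


def _moran_columns(W: sp.csr_matrix, X: np.ndarray):
    """Moran's I + randomisation moments for every column of X.

    Row-normalised W has S0 = N, so I reduces to the normalised
    cross-product quadratic form. Returns (I, z, p) arrays with NaN
    where the variance is undefined (N < 4 or zero attribute variance).
    """
    N = W.shape[0]
    Z = X - X.mean(axis=0, keepdims=True)
    denom = (Z ** 2).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        I = (Z * (W @ Z)).sum(axis=0) / denom
    E = -1.0 / (N - 1)
    if N < 4:
        nan = np.full(X.shape[1], np.nan)
        return I, nan, nan, E
    S0 = float(N)
    A = (W + W.T).tocsr()
    S1 = 0.5 * float((A.multiply(A)).sum())
    col = np.asarray(W.sum(axis=0)).ravel()
    S2 = float(((1.0 + col) ** 2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        b2 = N * (Z ** 4).sum(axis=0) / denom ** 2
    n2 = N * N
    EI2 = (
        N * ((n2 - 3 * N + 3) * S1 - N * S2 + 3 * S0 ** 2)
        - b2 * ((n2 - N) * S1 - 2 * N * S2 + 6 * S0 ** 2)
    ) / ((N - 1) * (N - 2) * (N - 3) * S0 ** 2)
    var = EI2 - E ** 2
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (I - E) / np.sqrt(var)
    p = 2.0 * stats.norm.sf(np.abs(z))
    return I, z, p, E


def morans_i(g: ProjectedGraph, values) -> MoranResult:
    """Moran's I of one node attribute vector under randomisation.

    Requires a connected projection with >= 2 nodes and a non-constant
    attribute; z and p are NaN when N < 4 (the randomisation variance
    is undefined there).
    """
    x = np.asarray(values, dtype=float)
    if g.n_nodes != len(x):
        raise ValueError("attribute length does not match node count")
    if g.n_nodes < 2:
        raise ValueError("Moran's I needs >= 2 nodes")
    if not g.is_connected():
        raise ValueError("projection is disconnected; supply one component")
    if np.ptp(x) == 0:
        raise ValueError("attribute has zero variance; Moran's I undefined")
    W = _row_normalize(g.adjacency)
    I, z, p, E = _moran_columns(W, x[:, None])
    return MoranResult(I=float(I[0]), z=float(z[0]), p=float(p[0]),
                       expected=E, n_nodes=g.n_nodes)


def polarity_scores(g: ProjectedGraph) -> pd.DataFrame:
    """MPX polarity score (Moran's I of per-node CLR counts) per marker.

    CLR is applied per node across markers; markers absent from the
    component or with constant CLR values are flagged and carry NaN
    scores.
    """
    logs = np.log1p(g.counts.astype(float))
    clr = logs - logs.mean(axis=1, keepdims=True)
    totals = g.counts.sum(axis=0)
    W = _row_normalize(g.adjacency)
    I, z, p, _ = _moran_columns(W, clr)
    rows = []
    for j, marker in enumerate(g.markers):
        if totals[j] == 0:
            flag = "Absent"
        elif np.ptp(clr[:, j]) == 0:
            flag = "NoVariance"
        else:
            flag = "OK"
        ok = flag == "OK"
        rows.append({
            "component": g.component,
            "marker": marker,
            "morans_i": I[j] if ok else np.nan,
            "z": z[j] if ok else np.nan,
            "p": p[j] if ok else np.nan,
            "n_nodes": g.n_nodes,
            "flag": flag,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# colocalization


def _aggregate(S: sp.csr_matrix, X: np.ndarray, min_neighborhood: int):
    """Neighbourhood-sum counts; drop nodes aggregating < threshold."""
    Y = S @ X
    mask = Y.sum(axis=1) >= min_neighborhood
    return np.log1p(Y[mask]), int(mask.sum())


def _pair_corr(Y: np.ndarray) -> np.ndarray:
    """Pairwise Pearson matrix with NaN for constant columns."""
    if Y.shape[0] < 2:
        return np.full((Y.shape[1], Y.shape[1]), np.nan)
    with np.errstate(invalid="ignore", divide="ignore"):
        sd = Y.std(axis=0)
        Z = (Y - Y.mean(axis=0)) / sd
    Z[:, sd == 0] = np.nan
    return (Z.T @ Z) / Y.shape[0]


def colocalization_scores(
    g: ProjectedGraph,
    min_marker: int = 10,
    min_neighborhood: int = 5,
    n_perm: int = 50,
    seed: int = 0,
) -> pd.DataFrame:
    """Six-step MPX colocalization score per unordered marker pair.

    1. drop markers with < ``min_marker`` counts in the component;
    2. aggregate each marker over every node and its immediate
       neighbours, dropping neighbourhoods totalling < ``min_neighborhood``;
    3. build ``n_perm`` permuted components by shuffling each marker's
       node counts independently;
    4. log1p the aggregated counts (observed and permuted);
    5. Pearson's r per marker pair;
    6. Gaussian fit of the permuted r null -> z-score and two-sided P.
    """
    if n_perm < 10:
        raise ValueError("n_perm must be >= 10")
    rng = np.random.default_rng(seed)
    totals = g.counts.sum(axis=0)
    keep = totals >= min_marker
    markers = [m for m, k in zip(g.markers, keep) if k]
    if len(markers) < 2:
        return pd.DataFrame(columns=[
            "component", "marker_a", "marker_b", "pearson_r", "perm_mean",
            "perm_sd", "z", "p", "n_permutations", "n_nodes_used"])
    X = g.counts[:, keep].astype(float)
    S = (g.adjacency + sp.eye(g.n_nodes, format="csr")).tocsr()

    Y_obs, n_used = _aggregate(S, X, min_neighborhood)
    r_obs = _pair_corr(Y_obs)

    K = X.shape[1]
    perm_r = np.empty((n_perm, K, K))
    for t in range(n_perm):
        Xp = rng.permuted(X, axis=0)
        Yp, _ = _aggregate(S, Xp, min_neighborhood)
        perm_r[t] = _pair_corr(Yp)
    perm_mean = perm_r.mean(axis=0)
    perm_sd = perm_r.std(axis=0, ddof=1)

    rows = []
    for i, j in combinations(range(K), 2):
        r = r_obs[i, j]
        mu, sd = perm_mean[i, j], perm_sd[i, j]
        with np.errstate(invalid="ignore", divide="ignore"):
            z = (r - mu) / sd if sd > 0 else np.nan
        p = 2.0 * stats.norm.sf(abs(z)) if np.isfinite(z) else np.nan
        rows.append({
            "component": g.component,
            "marker_a": markers[i],
            "marker_b": markers[j],
            "pearson_r": r,
            "perm_mean": mu,
            "perm_sd": sd,
            "z": z,
            "p": p,
            "n_permutations": n_perm,
            "n_nodes_used": n_used,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# differential comparisons


def differential_analysis(
    data: pd.DataFrame,
    reference: str,
    mode: str = "polarity",
    downsample_n: int | None = None,
    adjust: str = "BH",
    seed: int = 0,
) -> pd.DataFrame:
    """Two-sided Wilcoxon rank-sum comparisons against a reference.

    ``data`` is long-format with columns ``condition``, ``component``,
    ``feature`` (marker or marker pair) and ``value`` (CLR count for
    abundance mode, score otherwise). Components are downsampled
    without replacement per condition; P values are adjusted across
    features within each condition (Benjamini-Hochberg or Bonferroni).
    Effect: mean difference for scores; for abundance, the mean CLR
    difference divided by ln 2, i.e. a log2 fold change.
    """
    from statsmodels.stats.multitest import multipletests

    if mode not in ("abundance", "polarity", "colocalization"):
        raise ValueError(f"unknown mode {mode!r}")
    if adjust not in ("BH", "Bonferroni"):
        raise ValueError(f"unknown adjustment {adjust!r}")
    need = {"condition", "component", "feature", "value"}
    if not need <= set(data.columns):
        raise ValueError(f"data must have columns {sorted(need)}")
    conditions = [c for c in data.condition.unique() if c != reference]
    if reference not in set(data.condition):
        raise ValueError(f"reference condition {reference!r} not in data")
    rng = np.random.default_rng(seed)

    sampled = {}
    for cond in data.condition.unique():
        ids = np.sort(data.loc[data.condition == cond, "component"].unique())
        if downsample_n is not None and len(ids) > downsample_n:
            ids = rng.choice(ids, size=downsample_n, replace=False)
        sampled[cond] = set(ids)

    rows = []
    for cond in conditions:
        feats = sorted(set(data.loc[data.condition == cond, "feature"])
                       & set(data.loc[data.condition == reference, "feature"]))
        pvals, effects = [], []
        for feat in feats:
            a = data.loc[(data.condition == cond) & (data.feature == feat)
                         & data.component.isin(sampled[cond]), "value"].dropna()
            b = data.loc[(data.condition == reference) & (data.feature == feat)
                         & data.component.isin(sampled[reference]),
                         "value"].dropna()
            if len(a) < 2 or len(b) < 2:
                pvals.append(np.nan)
                effects.append(np.nan)
                continue
            p = stats.ranksums(a, b).pvalue
            eff = float(a.mean() - b.mean())
            if mode == "abundance":
                eff /= np.log(2.0)
            pvals.append(p)
            effects.append(eff)
        pvals = np.asarray(pvals)
        adj = np.full_like(pvals, np.nan)
        ok = np.isfinite(pvals)
        if ok.any():
            method = "fdr_bh" if adjust == "BH" else "bonferroni"
            adj[ok] = multipletests(pvals[ok], method=method)[1]
        for feat, p, q, eff in zip(feats, pvals, adj, effects):
            rows.append({
                "condition": cond, "reference": reference, "feature": feat,
                "mode": mode, "effect": eff, "p": p, "p_adjusted": q,
                "adjustment": adjust,
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# gating


def gate_components(clr: pd.DataFrame, rules) -> list:
    """Select components by CLR cutoff rules.

    ``rules`` is a list whose items are either a single
    ``(marker, op, cutoff)`` tuple (op in {'>', '<'}) or a list of such
    tuples forming a disjunction (e.g. CD4-or-CD8); items combine
    conjunctively. An empty rule list retains every component.
    """
    mask = pd.Series(True, index=clr.index)
    for item in rules:
        group = item if isinstance(item, list) else [item]
        sub = pd.Series(False, index=clr.index)
        for marker, op, cutoff in group:
            if marker not in clr.columns:
                raise KeyError(f"unknown marker {marker!r}")
            if op == ">":
                sub |= clr[marker] > cutoff
            elif op == "<":
                sub |= clr[marker] < cutoff
            else:
                raise ValueError(f"unknown operator {op!r}")
        mask &= sub
    return clr.index[mask].tolist()
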