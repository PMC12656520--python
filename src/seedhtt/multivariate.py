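"""Cultivar-level multivariate stage: PCA and hierarchical clustering.

Relates seed trait profiles (e.g. fatty-acid percentages) to fitted
germination-model parameters. The PCA is an eigendecomposition of the
correlation matrix of the active (trait) columns; model parameters such as
Tb, Ψb50 and θHT enter as supplementary variables — projected as correlations
with the component scores without influencing the decomposition. Per-variable
contributions (% of each component) and cos² (quality of representation) are
reported, and cultivars are grouped by Ward hierarchical clustering on the
retained component scores (the HCPC workflow).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.stats import pearsonr

from .errors import DataError, SchemaError


@dataclass
class TraitMatrix:
    """Cultivar × trait table with active and supplementary columns."""

    data: pd.DataFrame
    active_columns: list[str]
    supplementary_columns: list[str] | None = None

    def __post_init__(self) -> None:
        self.supplementary_columns = list(self.supplementary_columns or [])
        missing = [
            c
            for c in self.active_columns + self.supplementary_columns
            if c not in self.data.columns
        ]
        if missing:
            raise SchemaError(f"trait table missing column(s) {missing}")
        if len(self.data) < 3:
            raise DataError("trait matrix needs >= 3 rows")
        if self.data[self.active_columns].isna().any().any():
            raise DataError("active columns must have no missing values")

    @property
    def active(self) -> pd.DataFrame:
        return self.data[self.active_columns]


@dataclass
class PcaResult:
    """Eigenstructure plus the derived interpretation tables.

    ``loadings`` are variable coordinates (correlation of each variable with
    each component), ``contributions`` the percentage each variable brings to
    a component (columns sum to 100), ``cos2`` the squared coordinates
    (quality of representation, in [0, 1]).
    """

    eigenvalues: np.ndarray
    percent_variance: np.ndarray
    scores: pd.DataFrame  # rows = observations, cols = PC1..PCm
    loadings: pd.DataFrame  # rows = active variables
    contributions: pd.DataFrame
    cos2: pd.DataFrame
    supplementary: pd.DataFrame | None  # correlations of supp vars with scores
    standardized: bool


def pca(matrix: TraitMatrix, standardize: bool = True) -> PcaResult:
    """PCA of the active columns; supplementary columns projected afterwards.

    Standardized (correlation-matrix) PCA by default, since trait percentages
    and model parameters live on different scales. Components are ordered by
    decreasing eigenvalue; the sign of each component is fixed so that its
    largest-magnitude loading is positive.
    """
    X = matrix.active.to_numpy(dtype=float)
    n, p = X.shape
    variances = X.var(axis=0, ddof=1)
    if standardize:
        dead = [c for c, v in zip(matrix.active_columns, variances) if v == 0]
        if dead:
            raise DataError(f"zero-variance active column(s): {dead}")
        Z = (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)
    else:
        Z = X - X.mean(axis=0)
    C = (Z.T @ Z) / (n - 1)  # correlation (or covariance) matrix
    eigval, eigvec = np.linalg.eigh(C)
    order = np.argsort(eigval)[::-1]
    eigval = np.clip(eigval[order], 0.0, None)
    eigvec = eigvec[:, order]
    # sign convention: largest-|loading| entry of each component positive
    for k in range(p):
        j = int(np.argmax(np.abs(eigvec[:, k])))
        if eigvec[j, k] < 0:
            eigvec[:, k] = -eigvec[:, k]

    total = eigval.sum()
    pct = 100.0 * eigval / total if total > 0 else np.zeros_like(eigval)
    comp_names = [f"PC{k + 1}" for k in range(p)]
    scores = pd.DataFrame(Z @ eigvec, index=matrix.data.index, columns=comp_names)
    # variable coordinate = corr(variable, score) = sqrt(λ)·eigvec entry
    coords = eigvec * np.sqrt(eigval)
    loadings = pd.DataFrame(coords, index=matrix.active_columns, columns=comp_names)
    contributions = pd.DataFrame(
        100.0 * eigvec**2, index=matrix.active_columns, columns=comp_names
    )
    cos2 = pd.DataFrame(
        np.clip(coords**2, 0.0, 1.0) if standardize else coords**2,
        index=matrix.active_columns,
        columns=comp_names,
    )

    supp = None
    if matrix.supplementary_columns:
        rows = {}
        for c in matrix.supplementary_columns:
            v = matrix.data[c].to_numpy(dtype=float)
            rows[c] = [
                _safe_corr(v, scores[pc].to_numpy()) for pc in comp_names
            ]
        supp = pd.DataFrame.from_dict(rows, orient="index", columns=comp_names)

    return PcaResult(
        eigenvalues=eigval,
        percent_variance=pct,
        scores=scores,
        loadings=loadings,
        contributions=contributions,
        cos2=cos2,
        supplementary=supp,
        standardized=standardize,
    )


def _safe_corr(a: np.ndarray, b: np.ndarray) -> float:
    if a.std() == 0 or b.std() == 0:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


def retained_components(result: PcaResult, n_components) -> int:
    """Resolve an int count or a fractional cumulative-variance threshold."""
    m = len(result.eigenvalues)
    if n_components is None:
        return m
    if isinstance(n_components, float) and 0 < n_components < 1:
        cum = np.cumsum(result.percent_variance) / 100.0
        return int(np.searchsorted(cum, n_components - 1e-12) + 1)
    k = int(n_components)
    if not 1 <= k <= m:
        raise DataError(f"n_components must be in [1, {m}], got {n_components}")
    return k


def hcpc(result: PcaResult, k: int, n_components=None) -> np.ndarray:
    """Ward hierarchical clustering on retained PC scores.

    Deterministic given its inputs. Cluster labels are 1..k, ordered by
    decreasing cluster size with ties broken by first-member order.
    """
    n = len(result.scores)
    if k > n:
        raise DataError(f"k={k} exceeds the {n} observations")
    m = retained_components(result, n_components)
    S = result.scores.to_numpy()[:, :m]
    if k == n:
        raw = np.arange(n)
    else:
        Z = linkage(S, method="ward", metric="euclidean")
        raw = fcluster(Z, t=k, criterion="maxclust") - 1
    # canonical label order: size desc, then first appearance
    stats = []
    for lab in np.unique(raw):
        members = np.flatnonzero(raw == lab)
        stats.append((-(members.size), members[0], lab))
    stats.sort()
    remap = {lab: i + 1 for i, (_, _, lab) in enumerate(stats)}
    return np.array([remap[lab] for lab in raw])


def trait_correlations(matrix: TraitMatrix, target: str) -> pd.DataFrame:
    """Pearson correlation of each active trait with a target column.

    Returns r, the two-sided p-value, and flags: ``low_power`` when fewer
    than 10 rows support the estimate, ``undefined`` for constant columns.
    """
    if target not in matrix.data.columns:
        raise SchemaError(f"unknown target column {target!r}")
    y = matrix.data[target].to_numpy(dtype=float)
    n = len(y)
    rows = []
    for c in matrix.active_columns:
        x = matrix.data[c].to_numpy(dtype=float)
        if x.std() == 0 or y.std() == 0:
            rows.append({"trait": c, "r": np.nan, "p_value": np.nan, "undefined": True})
            continue
        r, p = pearsonr(x, y)
        rows.append({"trait": c, "r": float(r), "p_value": float(p), "undefined": False})
    out = pd.DataFrame(rows)
    out["low_power"] = n < 10
    return out
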