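"""Descriptor-space ordination and permutation group tests.

Taxa are ordinated by PCA of the correlation matrix of their network
descriptors (each variable z-scored before eigendecomposition, so the
analysis is scale-free), and group separation in that space is tested with
one-way PERMANOVA: a pseudo-F computed from the matrix of Euclidean
distances between z-scored descriptor vectors, with a permutation null for
the p-value.

Two descriptor presets mirror the two ordinations typically run: the
tetrapod-scale set (D, L, C, H) and the cetacean set which adds
parcellation (D, L, C, H, P).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

VARIABLE_PRESETS = {
    "tetrapod": ["D", "L", "C", "H"],
    "cetacean": ["D", "L", "C", "H", "P"],
}


@dataclass
class MorphospaceResult:
    variables: list[str]
    scores: pd.DataFrame        # taxa x components
    loadings: pd.DataFrame      # variables x components
    variance_pct: np.ndarray    # per-component %, sums to 100
    group_labels: dict[str, str] | None = None


@dataclass
class PermanovaResult:
    F: float
    p: float
    n_perm: int
    seed: int
    distance: str = "euclidean (z-scored variables)"
    pairwise: pd.DataFrame | None = None


def _as_matrix(table: pd.DataFrame, variables: list[str]) -> tuple[np.ndarray, list[str]]:
    missing = [v for v in variables if v not in table.columns]
    if missing:
        raise ValueError(f"variables absent from table: {missing}")
    X = table[variables].to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("descriptor table contains missing values")
    taxa = (table["taxon"].astype(str).tolist() if "taxon" in table.columns
            else [str(i) for i in table.index])
    return X, taxa


def _zscore(X: np.ndarray, variables: list[str]) -> np.ndarray:
    sd = X.std(axis=0, ddof=1)
    zero = np.where(sd == 0)[0]
    if zero.size:
        names = [variables[i] for i in zero]
        raise ValueError(f"zero-variance variable(s): {names}")
    return (X - X.mean(axis=0)) / sd


def pca_correlation(table: pd.DataFrame, variables: list[str] | str = "cetacean",
                    group_labels: dict[str, str] | None = None) -> MorphospaceResult:
    """PCA of the correlation matrix of the chosen descriptors.

    Columns are standardized to mean 0 / sample sd 1; the correlation matrix
    is eigendecomposed; components are ordered by decreasing eigenvalue and
    the sign of each is fixed so its largest-magnitude loading is positive.
    Variance percentages are 100 * eigenvalue / number of variables.
    """
    if isinstance(variables, str):
        variables = VARIABLE_PRESETS[variables]
    X, taxa = _as_matrix(table, variables)
    if X.shape[0] < 3 or X.shape[1] < 2:
        raise ValueError("PCA needs at least 3 taxa and 2 variables")
    Z = _zscore(X, variables)
    R = (Z.T @ Z) / (Z.shape[0] - 1)
    eigvals, eigvecs = np.linalg.eigh(R)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    eigvals = np.clip(eigvals, 0.0, None)
    for j in range(eigvecs.shape[1]):
        k = np.argmax(np.abs(eigvecs[:, j]))
        if eigvecs[k, j] < 0:
            eigvecs[:, j] = -eigvecs[:, j]
    comp_names = [f"PC{i + 1}" for i in range(len(variables))]
    scores = pd.DataFrame(Z @ eigvecs, index=taxa, columns=comp_names)
    loadings = pd.DataFrame(eigvecs, index=variables, columns=comp_names)
    variance_pct = 100.0 * eigvals / eigvals.sum()
    return MorphospaceResult(
        variables=list(variables), scores=scores, loadings=loadings,
        variance_pct=variance_pct, group_labels=group_labels,
    )


# ---------------------------------------------------------------------------
# PERMANOVA


def _pseudo_f(d2: np.ndarray, labels: np.ndarray) -> float:
    """One-way pseudo-F from a squared-distance matrix (Anderson's partition).

    SS_total = sum of squared distances over all pairs / n;
    SS_within = sum over groups of within-group squared distances / group size.
    """
    n = d2.shape[0]
    groups, counts = np.unique(labels, return_counts=True)
    a = len(groups)
    ss_total = d2[np.triu_indices(n, k=1)].sum() / n
    ss_within = 0.0
    for g, n_g in zip(groups, counts):
        idx = np.where(labels == g)[0]
        sub = d2[np.ix_(idx, idx)]
        ss_within += sub[np.triu_indices(n_g, k=1)].sum() / n_g
    ss_among = ss_total - ss_within
    return (ss_among / (a - 1)) / (ss_within / (n - a))


def _permuted_f(d2: np.ndarray, labels: np.ndarray, n_perm: int,
                rng: np.random.Generator) -> np.ndarray:
    """Vectorized pseudo-F over ``n_perm`` label permutations."""
    n = d2.shape[0]
    groups, counts = np.unique(labels, return_counts=True)
    a = len(groups)
    ss_total = d2[np.triu_indices(n, k=1)].sum() / n
    perms = np.array([rng.permutation(labels) for _ in range(n_perm)])
    ss_within = np.zeros(n_perm)
    for g, n_g in zip(groups, counts):
        Z = (perms == g).astype(float)                      # n_perm x n
        ss_within += (np.einsum("pi,ij,pj->p", Z, d2, Z) / 2.0) / n_g
    ss_among = ss_total - ss_within
    return (ss_among / (a - 1)) / (ss_within / (n - a))


def permanova(table: pd.DataFrame, variables: list[str] | str, groups: dict[str, str],
              n_perm: int = 9999, seed: int = 0, pairwise: bool = False,
              ) -> PermanovaResult:
    """One-way PERMANOVA on Euclidean distances between z-scored descriptors.

    ``groups`` maps taxon -> group label; every group needs >= 2 members.
    The p-value is the (b + 1)/(n_perm + 1) estimator, b the number of
    permuted pseudo-F values >= the observed one, so p is never 0.  With
    ``pairwise`` each group pair is tested too, and Bonferroni-adjusted
    p-values are reported next to the raw ones.
    """
    if isinstance(variables, str):
        variables = VARIABLE_PRESETS[variables]
    X, taxa = _as_matrix(table, variables)
    missing = [t for t in taxa if t not in groups]
    if missing:
        raise ValueError(f"taxa missing from groups: {missing}")
    labels = np.array([groups[t] for t in taxa])
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("PERMANOVA needs at least 2 groups")
    small = [str(g) for g, c in zip(uniq, counts) if c < 2]
    if small:
        raise ValueError(f"groups with fewer than 2 members: {small}")
    Z = _zscore(X, list(variables))
    diff = Z[:, None, :] - Z[None, :, :]
    d2 = np.einsum("ijk,ijk->ij", diff, diff)
    f_obs = _pseudo_f(d2, labels)
    rng = np.random.default_rng(seed)
    f_perm = _permuted_f(d2, labels, n_perm, rng)
    b = int(np.sum(f_perm >= f_obs - 1e-12))
    p = (b + 1) / (n_perm + 1)
    pw = None
    if pairwise:
        records = []
        pairs = list(combinations(sorted(map(str, uniq)), 2))
        for g1, g2 in pairs:
            mask = np.isin(labels, [g1, g2])
            sub_table = table.loc[mask].reset_index(drop=True) if "taxon" in table.columns \
                else table.loc[mask]
            sub = permanova(sub_table, variables,
                            {t: groups[t] for t, m in zip(taxa, mask) if m},
                            n_perm=n_perm, seed=seed, pairwise=False)
            records.append({"group_1": g1, "group_2": g2, "F": sub.F,
                            "p_raw": sub.p,
                            "p_bonferroni": min(1.0, sub.p * len(pairs))})
        pw = pd.DataFrame(records)
    return PermanovaResult(F=float(f_obs), p=float(p), n_perm=n_perm, seed=seed,
                           pairwise=pw)
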