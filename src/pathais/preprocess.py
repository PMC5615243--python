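"""Data preparation: missing-value imputation and coherent-subset selection.

Genetic-interaction screens leave many double-mutant fitnesses unmeasured.
Missing entries are predicted by least-squares regression of a gene's
observed interaction profile on the profiles of its most similar genes
(profile similarity = Pearson correlation over pairwise-complete entries).
Independently, genes whose profiles are mutually highly correlated form
"coherent subsets" — the tractable units the sampler is run on.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .errors import ImputationError, InvalidInputError
from .model import FitnessData, GeneSet

__all__ = ["profile_correlations", "impute_missing", "coherent_subsets"]

#: Pearson correlation needs enough shared observations to mean anything;
#: below this overlap the correlation is treated as 0.
MIN_PROFILE_OVERLAP = 10


def profile_correlations(
    fd: FitnessData, min_overlap: int = MIN_PROFILE_OVERLAP
) -> pd.DataFrame:
    """Pairwise-complete Pearson correlation between interaction profiles.

    Profiles are the rows of D (diagonal treated as missing).  Pairs with
    fewer than ``min_overlap`` shared observed entries, or with a constant
    profile on the shared entries, get ``nan``.
    """
    genes = list(fd.genes)
    D = fd.D.copy()
    np.fill_diagonal(D, np.nan)
    df = pd.DataFrame(D, index=genes, columns=genes)
    # columns of df are the per-gene profiles (D is symmetric)
    return df.corr(min_periods=min_overlap)


def impute_missing(
    fd: FitnessData, q: int = 5, min_overlap: int = MIN_PROFILE_OVERLAP
) -> FitnessData:
    """Fill missing double-mutant fitnesses by profile regression.

    Each missing D(x, y) is predicted twice — from x's side and from y's
    side — and the two predictions averaged, which keeps the matrix
    symmetric.  The x-side prediction regresses x's observed profile on
    the profiles of the ``q`` genes most correlated with x that have an
    observed value in column y; y's column is excluded from the fit.
    Predictions use only originally observed entries, so the operation is
    idempotent and independent of imputation order.
    """
    if q < 1:
        raise InvalidInputError(f"q must be >= 1, got {q}")
    n = len(fd.genes)
    obs = np.isfinite(fd.D)
    np.fill_diagonal(obs, False)
    missing = [
        (i, j) for i in range(n) for j in range(i + 1, n) if not obs[i, j]
    ]
    if not missing:
        return fd

    corr = profile_correlations(fd, min_overlap).to_numpy()
    corr = np.nan_to_num(corr, nan=0.0)

    D_new = fd.D.copy()
    for i, j in missing:
        pred = 0.5 * (
            _predict_entry(fd, corr, obs, i, j, q)
            + _predict_entry(fd, corr, obs, j, i, q)
        )
        D_new[i, j] = D_new[j, i] = pred
    out = FitnessData(fd.genes, fd.S.copy(), D_new, fd.E.copy(), fd.sigma2)
    return out


def _predict_entry(
    fd: FitnessData, corr: np.ndarray, obs: np.ndarray, i: int, j: int, q: int
) -> float:
    """Regress gene i's profile on its q nearest profiles; predict column j."""
    n = obs.shape[0]
    gene = fd.genes[i]
    if not obs[i].any():
        raise ImputationError(gene, f"gene {gene!r} has a fully missing profile")
    # candidate predictors: observed in column j, with a usable correlation
    cand = [z for z in range(n) if z != i and z != j and obs[z, j]]
    cand.sort(key=lambda z: (-corr[i, z], z))
    predictors: list[int] = []
    cols: np.ndarray | None = None
    for z in cand:
        if len(predictors) == q:
            break
        trial = predictors + [z]
        mask = obs[i].copy()
        mask[j] = False
        for t in trial:
            mask &= obs[t]
        if mask.sum() >= 2:
            predictors = trial
            cols = mask
    if not predictors or cols is None:
        raise ImputationError(
            gene, f"gene {gene!r}: no usable predictor profiles for column "
            f"{fd.genes[j]!r}"
        )
    idx = np.flatnonzero(cols)
    X = np.column_stack([np.ones(len(idx))] + [fd.D[z, idx] for z in predictors])
    y = fd.D[i, idx]
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    x_star = np.concatenate([[1.0], [fd.D[z, j] for z in predictors]])
    return float(x_star @ coef)


def coherent_subsets(
    fd: FitnessData,
    r_min: float = 0.8,
    k_min: int = 2,
    min_overlap: int = MIN_PROFILE_OVERLAP,
) -> list[GeneSet]:
    """Groups of genes with mutually correlated interaction profiles.

    Builds the graph with an edge wherever profile correlation >= r_min
    and returns its connected components of size >= k_min, largest first.
    Genes with a constant (zero-variance) profile are excluded with a
    warning rather than an error.
    """
    if not -1.0 <= r_min <= 1.0:
        raise InvalidInputError(f"r_min must be in [-1, 1], got {r_min}")
    if k_min < 2:
        raise InvalidInputError(f"k_min must be >= 2, got {k_min}")
    n = len(fd.genes)
    D = fd.D.copy()
    np.fill_diagonal(D, np.nan)
    keep = []
    for i in range(n):
        row = D[i][np.isfinite(D[i])]
        if row.size and np.ptp(row) == 0.0:
            warnings.warn(
                f"gene {fd.genes[i]!r} has a constant profile; excluded from "
                "coherent-subset search",
                stacklevel=2,
            )
        else:
            keep.append(i)

    corr = profile_correlations(fd, min_overlap).to_numpy()
    parent = {i: i for i in keep}

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for ai, i in enumerate(keep):
        for j in keep[ai + 1 :]:
            if np.isfinite(corr[i, j]) and corr[i, j] >= r_min:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[ri] = rj
    comps: dict[int, list[int]] = {}
    for i in keep:
        comps.setdefault(find(i), []).append(i)
    subsets = [
        GeneSet(fd.genes[i] for i in sorted(members))
        for members in comps.values()
        if len(members) >= k_min
    ]
    subsets.sort(key=lambda gs: (-len(gs), fd.genes.index(gs[0])))
    return subsets
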