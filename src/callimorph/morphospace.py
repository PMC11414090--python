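"""Principal components analysis of the flat 13-trait matrix."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import DegenerateDataError
from .schema import TRAIT_NAMES

__all__ = ["PCAResult", "run_pca", "pca_report"]


@dataclass
class PCAResult:
    subset: tuple[str, ...]
    n_used: int
    n_dropped: int
    eigenvalues: np.ndarray          # nonincreasing, nonnegative
    pct_variance: np.ndarray         # sums to 100
    loadings: pd.DataFrame           # traits x components
    scores: pd.DataFrame             # individuals x components (+ taxon)
    scaling: str                     # 'correlation' | 'covariance'


def run_pca(
    flat: pd.DataFrame,
    subset: Sequence[str] | None = None,
    scaling: str = "correlation",
) -> PCAResult:
    """PCA of the 13 traits on complete-case rows of the chosen taxa.

    Rows with any missing trait are dropped (listwise deletion, count
    logged in the result). Columns are centered; under ``correlation``
    scaling they are also divided by their sample SD. Components follow a
    deterministic sign convention: the largest-magnitude loading of each
    component is positive.
    """
    if scaling not in ("correlation", "covariance"):
        raise ValueError("scaling must be 'correlation' or 'covariance'")
    traits = [t for t in TRAIT_NAMES if t in flat.columns]
    sub = flat if subset is None else flat[flat["taxon"].isin(list(subset))]
    values = sub[traits].apply(pd.to_numeric, errors="coerce")
    complete = values.dropna()
    n_used, p = complete.shape
    if n_used <= p:
        raise DegenerateDataError(
            f"need more complete rows ({n_used}) than traits ({p})"
        )

    X = complete.to_numpy(dtype=float)
    X = X - X.mean(axis=0)
    if scaling == "correlation":
        sd = X.std(axis=0, ddof=1)
        zero = [traits[i] for i in np.flatnonzero(sd == 0)]
        if zero:
            raise DegenerateDataError(f"constant trait(s) under correlation scaling: {zero}")
        X = X / sd

    cov = (X.T @ X) / (n_used - 1)
    eigvals, eigvecs = np.linalg.eigh(cov)
    order = np.argsort(eigvals)[::-1]
    eigvals = np.clip(eigvals[order], 0.0, None)
    eigvecs = eigvecs[:, order]
    # sign convention: largest-|loading| entry of each component positive
    for j in range(eigvecs.shape[1]):
        i = np.argmax(np.abs(eigvecs[:, j]))
        if eigvecs[i, j] < 0:
            eigvecs[:, j] = -eigvecs[:, j]

    pct = eigvals / eigvals.sum() * 100.0
    comp_names = [f"PC{i + 1}" for i in range(len(eigvals))]
    loadings = pd.DataFrame(eigvecs, index=traits, columns=comp_names)
    score_mat = X @ eigvecs
    scores = pd.DataFrame(score_mat, columns=comp_names, index=complete.index)
    if "taxon" in sub.columns:
        scores.insert(0, "taxon", sub.loc[complete.index, "taxon"])

    return PCAResult(
        subset=tuple(subset) if subset is not None else tuple(sorted(sub["taxon"].unique())) if "taxon" in sub.columns else (),
        n_used=n_used,
        n_dropped=len(values) - n_used,
        eigenvalues=eigvals,
        pct_variance=pct,
        loadings=loadings,
        scores=scores,
        scaling=scaling,
    )


def pca_report(result: PCAResult, outdir: str | Path | None = None, prefix: str = "pca") -> dict[str, pd.DataFrame]:
    """Eigenvalue/percent-variance, loadings, and score tables (CSV if outdir given)."""
    eigen = pd.DataFrame(
        {
            "component": [f"PC{i + 1}" for i in range(len(result.eigenvalues))],
            "eigenvalue": result.eigenvalues,
            "pct_variance": result.pct_variance,
            "cum_pct_variance": np.cumsum(result.pct_variance),
        }
    )
    tables = {"eigen": eigen, "loadings": result.loadings, "scores": result.scores}
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        tag = "_".join(result.subset) if result.subset else "all"
        eigen.to_csv(outdir / f"{prefix}_{tag}_eigen.csv", index=False)
        result.loadings.to_csv(outdir / f"{prefix}_{tag}_loadings.csv")
        result.scores.to_csv(outdir / f"{prefix}_{tag}_scores.csv", index=False)
    return tables
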