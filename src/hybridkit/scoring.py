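"""PCA-based comprehensive scoring for backcross-parent selection.

Traits are standardized, the correlation matrix is eigen-decomposed,
components are retained up to a cumulative-contribution threshold, each
plant gets component scores Y_i, and the synthesis score

    Z = sum_i(contribution_i * Y_i) / cumulative_contribution_k

ranks plants; those with Z above a threshold are flagged as candidates.

Eigenvector signs are oriented so the largest-|loading| entry of each
component is positive.  Z is not invariant to component sign, so scores
are comparable only under a fixed orientation convention.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import AnalysisError, InputError


def standardize(traits: pd.DataFrame) -> pd.DataFrame:
    """Column-wise zero mean, unit sample SD.  Rows with any missing value
    are dropped (they cannot be scored)."""
    complete = traits.dropna()
    if len(complete) < 2:
        raise InputError("need >= 2 complete rows to standardize")
    sd = complete.std(ddof=1)
    constant = list(sd.index[(sd == 0) | sd.isna()])
    if constant:
        raise InputError(f"constant trait(s), cannot standardize: {constant}")
    return (complete - complete.mean()) / sd


@dataclass
class PCAResult:
    eigenvalues: np.ndarray  # descending
    loadings: np.ndarray  # columns are unit-norm eigenvectors, sign-oriented
    trait_names: list[str]
    n_retained: int

    @property
    def contribution_rates(self) -> np.ndarray:
        return self.eigenvalues / self.eigenvalues.sum()

    @property
    def cumulative_rates(self) -> np.ndarray:
        return np.cumsum(self.contribution_rates)

    def summary_frame(self) -> pd.DataFrame:
        comps = [f"Y{i + 1}" for i in range(len(self.eigenvalues))]
        head = pd.DataFrame(
            [self.eigenvalues, 100 * self.contribution_rates, 100 * self.cumulative_rates],
            index=["eigenvalue", "contribution_pct", "cumulative_pct"],
            columns=comps,
        )
        body = pd.DataFrame(self.loadings, index=self.trait_names, columns=comps)
        return pd.concat([head, body])


def _orient_signs(vectors: np.ndarray) -> np.ndarray:
    """Flip each column so its largest-|entry| loading is positive."""
    out = vectors.copy()
    for j in range(out.shape[1]):
        k = np.argmax(np.abs(out[:, j]))
        if out[k, j] < 0:
            out[:, j] = -out[:, j]
    return out


def run_pca(
    standardized: pd.DataFrame,
    cumulative_threshold: float | None = 0.85,
    n_components: int | None = None,
) -> PCAResult:
    """Eigen-decompose the sample correlation matrix of standardized traits.

    Retention: the smallest k whose cumulative contribution reaches
    ``cumulative_threshold``, or exactly ``n_components`` if given.
    """
    if n_components is None:
        if cumulative_threshold is None or not 0.0 < cumulative_threshold <= 1.0:
            raise InputError(
                f"cumulative_threshold must be in (0, 1], got {cumulative_threshold}"
            )
    n, p = standardized.shape
    if n < 2 or p < 2:
        raise InputError("need at least 2 rows and 2 columns for PCA")
    corr = np.corrcoef(standardized.to_numpy(), rowvar=False)
    eigval, eigvec = np.linalg.eigh(corr)
    order = np.argsort(eigval)[::-1]
    eigval = np.clip(eigval[order], 0.0, None)
    eigvec = _orient_signs(eigvec[:, order])
    if n_components is not None:
        if not 1 <= n_components <= p:
            raise InputError(f"n_components must be in [1, {p}], got {n_components}")
        k = n_components
    else:
        cum = np.cumsum(eigval / eigval.sum())
        k = int(np.searchsorted(cum, cumulative_threshold - 1e-12) + 1)
        k = min(k, p)
    return PCAResult(eigval, eigvec, list(standardized.columns), k)


def component_scores(standardized: pd.DataFrame, p: PCAResult) -> pd.DataFrame:
    """Per-plant scores on the retained components: Y = X @ loadings."""
    if list(standardized.columns) != p.trait_names:
        raise InputError("trait columns do not match the fitted PCA loading order")
    y = standardized.to_numpy() @ p.loadings[:, : p.n_retained]
    cols = [f"Y{i + 1}" for i in range(p.n_retained)]
    return pd.DataFrame(y, index=standardized.index, columns=cols)


def synthesis_score(scores: pd.DataFrame, p: PCAResult) -> pd.Series:
    """Contribution-weighted mean of retained component scores."""
    rates = p.contribution_rates[: p.n_retained]
    return synthesis_score_from_weights(scores, rates)


def synthesis_score_from_weights(scores: pd.DataFrame, rates) -> pd.Series:
    """Z from explicit contribution rates (normalized by their sum).

    Accepts rates as proportions; this is the entry point for recomputing
    published scores from printed component values and rates.
    """
    rates = np.asarray(rates, dtype=float)
    if rates.shape != (scores.shape[1],):
        raise InputError(
            f"expected {scores.shape[1]} contribution rates, got {rates.shape}"
        )
    total = rates.sum()
    if total <= 0:
        raise AnalysisError("contribution rates sum to zero")
    z = scores.to_numpy() @ rates / total
    return pd.Series(z, index=scores.index, name="Z")


def rank_and_select(z: pd.Series, z_threshold: float = 0.80) -> pd.DataFrame:
    """Descending rank by Z (stable tie-break by plant id) and a strict
    Z > threshold selection flag."""
    frame = z.rename("Z").to_frame()
    frame["plant_id"] = frame.index.astype(str)
    ordered = frame.sort_values(["Z", "plant_id"], ascending=[False, True], kind="stable")
    ordered["rank"] = np.arange(1, len(ordered) + 1)
    ordered["selected"] = ordered["Z"] > z_threshold
    return ordered.drop(columns="plant_id")


def score_table(
    traits: pd.DataFrame,
    cumulative_threshold: float | None = 0.85,
    n_components: int | None = None,
    z_threshold: float = 0.80,
) -> tuple[PCAResult, pd.DataFrame]:
    """End-to-end: standardize, fit PCA, score, synthesize and rank.

    Plants with missing trait values are excluded from fitting and absent
    from the returned table (consistent with standardize()).
    """
    x = standardize(traits)
    pca = run_pca(x, cumulative_threshold=cumulative_threshold, n_components=n_components)
    y = component_scores(x, pca)
    z = synthesis_score(y, pca)
    ranked = rank_and_select(z, z_threshold=z_threshold)
    table = y.join(ranked, how="inner").loc[ranked.index]
    return pca, table
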