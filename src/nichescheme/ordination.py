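"""Correlation-matrix PCA and the two-stage meta-ordination.

All ordinations are eigenanalyses of the Pearson correlation matrix,
i.e. PCA of column-z-scored data, so every input variable carries unit
variance and the eigenvalues sum to the number of variables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from nichescheme.trait_data import TraitMatrix, standardize


class OrdinationError(ValueError):
    pass


@dataclass(frozen=True)
class PCAResult:
    """Eigen-decomposition of a correlation matrix plus observation scores.

    ``loadings`` columns are unit-norm eigenvectors; ``scores`` are the
    z-scored data projected onto them, so score column ``j`` has sample
    variance ``eigenvalues[j]``.
    """

    eigenvalues: np.ndarray
    loadings: np.ndarray
    scores: np.ndarray
    var_names: tuple

    @property
    def prop_var(self) -> np.ndarray:
        return self.eigenvalues / self.eigenvalues.sum()

    def cumulative_prop_var(self, k: int) -> float:
        return float(self.prop_var[:k].sum())


@dataclass(frozen=True)
class DimensionOrdination:
    dimension: str
    pca: PCAResult
    retained: int
    species_ids: tuple

    @property
    def retained_scores(self) -> np.ndarray:
        return self.pca.scores[:, : self.retained]

    @property
    def retained_prop_var(self) -> float:
        return self.pca.cumulative_prop_var(self.retained)


@dataclass(frozen=True)
class MetaOrdination:
    """Second-stage PCA over the concatenated retained dimension scores."""

    input_block: np.ndarray
    pca: PCAResult
    species_ids: tuple
    dimensions: tuple


def _apply_sign_convention(loadings: np.ndarray) -> np.ndarray:
    # orient each component so its largest-|loading| entry is positive;
    # ties resolved toward the lowest variable index
    out = loadings.copy()
    for j in range(out.shape[1]):
        col = out[:, j]
        i = int(np.argmax(np.abs(np.abs(col) - np.max(np.abs(col))) < 1e-12))
        if col[i] < 0:
            out[:, j] = -col
    return out


def pca_correlation(X: np.ndarray, var_names=None) -> PCAResult:
    """PCA via eigen-decomposition of the Pearson correlation matrix.

    Parameters
    ----------
    X : ndarray of shape (n_obs, n_vars)
        Raw data; each column is z-scored internally.

    Raises
    ------
    OrdinationError
        If fewer than 3 observations, fewer than 2 variables, or any
        constant variable is present (flag/drop it upstream via
        :func:`nichescheme.trait_data.standardize`).
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 3:
        raise OrdinationError("need an (n>=3) x (p>=2) matrix")
    n, p = X.shape
    if p < 2:
        raise OrdinationError("need >= 2 variables")
    sd = X.std(axis=0, ddof=1)
    const = sd <= 1e-12 * np.maximum(np.abs(X).max(axis=0), 1.0)
    if const.any():
        j = int(np.argmax(const))
        raise OrdinationError(
            f"variable {j} is constant; standardize/flag zero-variance "
            "columns before ordination"
        )
    if var_names is None:
        var_names = tuple(f"v{j}" for j in range(p))
    Z = (X - X.mean(axis=0)) / sd
    R = (Z.T @ Z) / (n - 1)
    evals, evecs = np.linalg.eigh(R)
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    evecs = evecs[:, order]
    # degenerate eigenvalue ties: stable ordering by first-loading lexicographic
    i = 0
    while i < len(evals):
        j = i + 1
        while j < len(evals) and abs(evals[j] - evals[i]) < 1e-10:
            j += 1
        if j - i > 1:
            block = evecs[:, i:j]
            keys = [tuple(np.round(block[:, k], 10)) for k in range(j - i)]
            sub = sorted(range(j - i), key=lambda k: keys[k])
            evecs[:, i:j] = block[:, sub]
        i = j
    evals = np.where(np.abs(evals) < 1e-12, 0.0, evals)
    if (evals < -1e-10).any():
        raise OrdinationError("correlation matrix not PSD (numerical failure)")
    evecs = _apply_sign_convention(evecs)
    scores = Z @ evecs
    return PCAResult(evals, evecs, scores, tuple(var_names))


def ordinate_dimension(tm: TraitMatrix, retained: int = 2) -> DimensionOrdination:
    """Per-dimension PCA retaining the leading ``retained`` components."""
    z = tm if tm.standardized else standardize(tm)
    pca = pca_correlation(z.values, z.trait_names)
    rank = int(np.sum(pca.eigenvalues > 1e-10))
    if retained > rank:
        raise OrdinationError(
            f"retained={retained} exceeds rank {rank} of dimension {tm.dimension!r}"
        )
    return DimensionOrdination(tm.dimension, pca, retained, z.species_ids)


def meta_ordinate(ords) -> MetaOrdination:
    """PCA of PCAs: correlation-matrix PCA over stacked retained scores.

    Because the second-stage PCA z-scores its input columns, each
    dimension contributes components of equal variance, giving every
    niche dimension an equal chance to shape the composite gradients.
    """
    ords = list(ords)
    if len(ords) < 2:
        raise OrdinationError("need >= 2 dimension ordinations")
    ref = ords[0].species_ids
    for o in ords[1:]:
        if o.species_ids != ref:
            raise OrdinationError(
                f"species mismatch between {ords[0].dimension!r} and {o.dimension!r}"
            )
    block = np.hstack([o.retained_scores for o in ords])
    names = tuple(
        f"{o.dimension}_PC{k + 1}" for o in ords for k in range(o.retained)
    )
    pca = pca_correlation(block, names)
    return MetaOrdination(block, pca, ref, tuple(o.dimension for o in ords))
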