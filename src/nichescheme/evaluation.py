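"""Correlation of niche-axis scores with ecological response variables.

Signed Pearson r and |r| are both reported; headline comparisons use
|r| because component signs are an arbitrary convention.  Species with
undefined CV (zero mean abundance) are excluded pairwise from CV
correlations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from nichescheme.trait_data import ResponseTable


class EvaluationError(ValueError):
    pass


def pearson(x, y) -> float:
    """Product-moment correlation; NaN if either vector is constant."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise EvaluationError("need two equal-length vectors of length >= 3")
    xd = x - x.mean()
    yd = y - y.mean()
    sx = float(np.sqrt((xd**2).sum()))
    sy = float(np.sqrt((yd**2).sum()))
    if sx == 0 or sy == 0:
        return float("nan")
    return float((xd @ yd) / (sx * sy))


@dataclass(frozen=True)
class CorrelationReport:
    """Pearson r of every niche axis against each response variable."""

    table: pd.DataFrame  # columns: axis, component, response, r, abs_r, n
    n_cv_excluded: int

    def abs_r(self, axis: str, component: int, response: str) -> float:
        t = self.table
        row = t[(t.axis == axis) & (t.component == component) & (t.response == response)]
        if row.empty:
            raise KeyError((axis, component, response))
        return float(row.abs_r.iloc[0])

    def best(self, response: str):
        t = self.table[self.table.response == response]
        row = t.loc[t.abs_r.idxmax()]
        return str(row.axis), int(row.component), float(row.abs_r)

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False, float_format="%.10g")


def correlate_axes(meta, dims, raw, resp: ResponseTable,
                   n_components: int = 2) -> CorrelationReport:
    """Correlate PC scores with mean abundance and CV of abundance.

    Covers the first ``n_components`` scores of every dimension
    ordination, the meta-ordination, and (optionally) the pooled raw
    baseline PCA, against both responses.
    """
    blocks = []
    species = None
    for o in dims:
        blocks.append((o.dimension, o.pca.scores, o.species_ids))
    if meta is not None:
        blocks.append(("meta", meta.pca.scores, meta.species_ids))
    if raw is not None:
        raw_scores, raw_species = raw
        blocks.append(("raw", raw_scores, raw_species))
    if not blocks:
        raise EvaluationError("no ordinations supplied")
    for _, _, sp in blocks:
        if species is None:
            species = sp
        elif tuple(sp) != tuple(species):
            raise EvaluationError("species mismatch across ordinations")
    if tuple(resp.species_ids) != tuple(species):
        raise EvaluationError("species mismatch between ordinations and responses")

    cv_mask = resp.cv_defined
    rows = []
    for axis, scores, _ in blocks:
        for k in range(min(n_components, scores.shape[1])):
            s = scores[:, k]
            r_mean = pearson(s, resp.mean_abundance)
            r_cv = pearson(s[cv_mask], resp.cv_abundance[cv_mask])
            rows.append((axis, k + 1, "mean_abundance", r_mean, abs(r_mean), len(s)))
            rows.append((axis, k + 1, "cv_abundance", r_cv, abs(r_cv), int(cv_mask.sum())))
    table = pd.DataFrame(
        rows, columns=["axis", "component", "response", "r", "abs_r", "n"]
    )
    return CorrelationReport(table, int((~cv_mask).sum()))
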