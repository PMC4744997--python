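"""Ingestion, validation and standardization of trait and response tables.

Trait tables are delimited text with a header row of trait names and a
first column of species identifiers.  Species order is canonicalized
lexicographically on load so that multiple dimension tables align
deterministically.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

DIMENSIONS = ("habitat", "life_history", "trophic", "defence", "metabolic")


class TraitDataError(ValueError):
    """Raised on malformed or inconsistent trait/abundance input."""


@dataclass(frozen=True)
class TraitMatrix:
    """One niche dimension's species x trait table.

    Parameters
    ----------
    dimension : str
        Niche-dimension label (free-form; the canonical five are
        ``habitat``, ``life_history``, ``trophic``, ``defence``,
        ``metabolic``).
    species_ids : tuple of str
        Unique species identifiers, one per row.
    trait_names : tuple of str
        Column names, one per trait.
    values : ndarray of shape (n_species, n_traits)
    standardized : bool
        True once every retained column has been z-scored.
    zero_variance : tuple of str
        Trait names flagged as constant during standardization; these
        columns are excluded from ``values`` of the standardized matrix.
    """

    dimension: str
    species_ids: tuple
    trait_names: tuple
    values: np.ndarray
    standardized: bool = False
    zero_variance: tuple = field(default_factory=tuple)

    def __post_init__(self):
        vals = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", vals)
        object.__setattr__(self, "species_ids", tuple(self.species_ids))
        object.__setattr__(self, "trait_names", tuple(self.trait_names))
        if len(set(self.species_ids)) != len(self.species_ids):
            raise TraitDataError(f"duplicate species ids in {self.dimension!r}")
        if vals.shape != (len(self.species_ids), len(self.trait_names)):
            raise TraitDataError(
                f"shape {vals.shape} inconsistent with "
                f"{len(self.species_ids)} species x {len(self.trait_names)} traits"
            )
        if np.isnan(vals).any():
            raise TraitDataError(f"missing values in dimension {self.dimension!r}")

    @property
    def n_species(self) -> int:
        return len(self.species_ids)

    @property
    def n_traits(self) -> int:
        return len(self.trait_names)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.species_ids), columns=list(self.trait_names)
        )

    def write_csv(self, path) -> None:
        df = self.to_frame()
        df.index.name = "species_id"
        df.to_csv(path, float_format="%.17g")

    def reorder(self, species_ids) -> "TraitMatrix":
        """Return a copy with rows in the given species order."""
        index = {s: i for i, s in enumerate(self.species_ids)}
        try:
            rows = [index[s] for s in species_ids]
        except KeyError as exc:
            raise TraitDataError(
                f"species {exc.args[0]!r} absent from dimension {self.dimension!r}"
            ) from None
        if len(rows) != self.n_species:
            raise TraitDataError("reorder must use the full species set")
        return replace(
            self, species_ids=tuple(species_ids), values=self.values[rows]
        )


@dataclass(frozen=True)
class Assemblage:
    """A set of dimension tables sharing one species list in one order."""

    dimension_tables: tuple

    def __post_init__(self):
        tables = tuple(self.dimension_tables)
        object.__setattr__(self, "dimension_tables", tables)
        if len(tables) < 2:
            raise TraitDataError("an assemblage needs at least 2 dimensions")
        ref = tables[0].species_ids
        for tm in tables[1:]:
            if tm.species_ids != ref:
                raise TraitDataError(
                    f"species mismatch between {tables[0].dimension!r} "
                    f"and {tm.dimension!r}"
                )
        labels = [tm.dimension for tm in tables]
        if len(set(labels)) != len(labels):
            raise TraitDataError(f"duplicate dimension labels: {labels}")

    @property
    def species_ids(self) -> tuple:
        return self.dimension_tables[0].species_ids

    @property
    def dimensions(self) -> tuple:
        return tuple(tm.dimension for tm in self.dimension_tables)

    def __getitem__(self, dimension: str) -> TraitMatrix:
        for tm in self.dimension_tables:
            if tm.dimension == dimension:
                return tm
        raise KeyError(dimension)

    def pooled(self) -> TraitMatrix:
        """Column-concatenation of all dimension tables (the raw baseline)."""
        names = []
        for tm in self.dimension_tables:
            names.extend(f"{tm.dimension}:{t}" for t in tm.trait_names)
        values = np.hstack([tm.values for tm in self.dimension_tables])
        return TraitMatrix("pooled", self.species_ids, tuple(names), values)


@dataclass(frozen=True)
class ResponseTable:
    """Per-species mean abundance and CV over repeated surveys.

    ``cv_abundance`` is NaN for species whose mean abundance is zero
    (CV undefined); ``cv_defined`` flags the rest.
    """

    species_ids: tuple
    monthly_abundance: np.ndarray
    mean_abundance: np.ndarray
    cv_abundance: np.ndarray

    @property
    def cv_defined(self) -> np.ndarray:
        return ~np.isnan(self.cv_abundance)

    @property
    def n_surveys(self) -> int:
        return self.monthly_abundance.shape[1]

    def reorder(self, species_ids) -> "ResponseTable":
        index = {s: i for i, s in enumerate(self.species_ids)}
        try:
            rows = [index[s] for s in species_ids]
        except KeyError as exc:
            raise TraitDataError(
                f"species {exc.args[0]!r} absent from abundance table"
            ) from None
        return ResponseTable(
            tuple(species_ids),
            self.monthly_abundance[rows],
            self.mean_abundance[rows],
            self.cv_abundance[rows],
        )


def _read_delimited(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep=None, engine="python", dtype=str)
    if df.shape[0] == 0 or df.shape[1] < 2:
        raise TraitDataError(f"{path}: empty table or missing trait columns")
    return df


def load_trait_table(path, dimension: str, impute: bool = False) -> TraitMatrix:
    """Read a delimited species x trait table for one niche dimension.

    First column is the species id, remaining columns are numeric traits.
    Rows are canonicalized to lexicographic species order.  Missing cells
    are rejected unless ``impute`` is set, in which case column means are
    substituted (and a warning is emitted).
    """
    df = _read_delimited(path)
    species = df.iloc[:, 0].astype(str).tolist()
    dupes = sorted({s for s in species if species.count(s) > 1})
    if dupes:
        raise TraitDataError(f"{path}: duplicated species id(s): {', '.join(dupes)}")
    trait_names = tuple(df.columns[1:])
    values = np.empty((len(species), len(trait_names)))
    for j, name in enumerate(trait_names):
        raw_missing = df[name].isna().to_numpy()
        col = np.full(len(species), np.nan)
        for i, cell in enumerate(df[name]):
            if raw_missing[i]:
                continue
            try:
                # exact round-trip parsing (pd.to_numeric is last-ulp sloppy)
                col[i] = float(cell)
            except ValueError:
                raise TraitDataError(
                    f"{path}: non-numeric value {cell!r} "
                    f"at species {species[i]!r}, trait {name!r}"
                ) from None
        if raw_missing.any():
            if not impute:
                i = int(np.argmax(raw_missing))
                raise TraitDataError(
                    f"{path}: missing value at species {species[i]!r}, "
                    f"trait {name!r} (pass impute=True for column-mean fill)"
                )
            fill = float(np.nanmean(col))
            warnings.warn(
                f"{path}: imputed {int(raw_missing.sum())} value(s) in trait "
                f"{name!r} with column mean {fill:.6g}",
                stacklevel=2,
            )
            col = np.where(raw_missing, fill, col)
        values[:, j] = col
    order = np.argsort(np.asarray(species, dtype=object))
    species_sorted = tuple(species[i] for i in order)
    return TraitMatrix(dimension, species_sorted, trait_names, values[order])


def standardize(tm: TraitMatrix) -> TraitMatrix:
    """Z-score every trait column (sample SD, n-1 denominator).

    Constant columns are dropped from the result and recorded in
    ``zero_variance`` so downstream ordination never sees them.
    """
    if tm.standardized:
        raise TraitDataError(f"dimension {tm.dimension!r} already standardized")
    if tm.n_species < 3:
        raise TraitDataError("need >= 3 species for stable standardization")
    sd = tm.values.std(axis=0, ddof=1)
    keep = sd > 1e-12 * np.maximum(np.abs(tm.values).max(axis=0), 1.0)
    zv = tuple(t for t, k in zip(tm.trait_names, keep) if not k)
    vals = tm.values[:, keep]
    z = (vals - vals.mean(axis=0)) / sd[keep]
    return TraitMatrix(
        tm.dimension,
        tm.species_ids,
        tuple(t for t, k in zip(tm.trait_names, keep) if k),
        z,
        standardized=True,
        zero_variance=zv,
    )


def compute_response_stats(
    abund: np.ndarray, species_ids=None
) -> ResponseTable:
    """Mean abundance and CV (sample SD / mean) over survey columns.

    Species with zero mean get ``cv = NaN`` rather than a number.
    """
    abund = np.asarray(abund, dtype=float)
    if abund.ndim != 2 or abund.shape[1] < 2:
        raise TraitDataError("need a species x survey matrix with >= 2 surveys")
    if np.isnan(abund).any():
        raise TraitDataError("missing abundance values")
    if (abund < 0).any():
        i, j = np.argwhere(abund < 0)[0]
        raise TraitDataError(f"negative abundance at row {i}, survey {j}")
    if species_ids is None:
        species_ids = tuple(f"sp{i:03d}" for i in range(abund.shape[0]))
    mean = abund.mean(axis=1)
    sd = abund.std(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(mean > 0, sd / np.where(mean > 0, mean, 1.0), np.nan)
    return ResponseTable(tuple(species_ids), abund, mean, cv)


def load_abundance_table(path) -> ResponseTable:
    """Read a species x survey abundance CSV (first column ``species_id``)."""
    df = _read_delimited(path)
    species = [str(s) for s in df.iloc[:, 0]]
    try:
        values = df.iloc[:, 1:].astype(float).to_numpy()
    except ValueError as exc:
        raise TraitDataError(f"{path}: non-numeric abundance cell ({exc})") from None
    order = np.argsort(np.asarray(species, dtype=object))
    return compute_response_stats(
        values[order], tuple(species[i] for i in order)
    )
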