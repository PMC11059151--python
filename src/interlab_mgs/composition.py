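"""Compositional and diversity statistics on abundance tables.

Relative abundances are closed to 1, so single-taxon abundances are not
comparable across samples; within-profile taxa ratios cancel the closure
and are the measurand used throughout.  This module provides closure
(normalization), rank aggregation, taxa ratios with an explicit
pseudocount policy, inverse Simpson diversity, Bray-Curtis dissimilarity,
classical PCoA, and without-replacement rarefaction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .tables_io import AbundanceTable, TaxonLabel, ValidationError

__all__ = [
    "RatioSeries",
    "DissimilarityMatrix",
    "Ordination",
    "normalize",
    "aggregate",
    "taxa_ratio",
    "inverse_simpson",
    "inverse_simpson_series",
    "bray_curtis",
    "pcoa",
    "rarefy",
]


@dataclass
class RatioSeries:
    """Per-(lab, sample) values of one taxa ratio.

    ``values`` is a Series indexed by (lab_id, sample_id); entries where a
    zero abundance forced a pseudocount are listed in ``pseudocounted``.
    """

    numerator: TaxonLabel
    denominator: TaxonLabel
    values: pd.Series
    pseudocount_used: bool = False
    pseudocounted: frozenset = frozenset()

    def __post_init__(self) -> None:
        vals = self.values.to_numpy(dtype=float)
        if not np.isfinite(vals).all() or (vals <= 0).any():
            raise ValidationError("ratio values must be positive and finite")

    def for_sample(self, sample: str) -> pd.Series:
        """Ratios of all labs for one sample, indexed by lab."""
        return self.values.xs(sample, level="sample_id")

    def restrict_labs(self, labs) -> "RatioSeries":
        keep = self.values[
            self.values.index.get_level_values("lab_id").isin(set(labs))
        ]
        return replace(self, values=keep)


@dataclass
class DissimilarityMatrix:
    ids: list[str]
    D: np.ndarray

    def __post_init__(self) -> None:
        D = np.asarray(self.D, dtype=float)
        if D.shape != (len(self.ids), len(self.ids)):
            raise ValidationError("dissimilarity matrix shape mismatch")
        if not np.allclose(D, D.T):
            raise ValidationError("dissimilarity matrix must be symmetric")
        if not np.allclose(np.diag(D), 0.0):
            raise ValidationError("dissimilarity diagonal must be zero")
        if (D < -1e-12).any() or (D > 1 + 1e-12).any():
            raise ValidationError("Bray-Curtis entries must lie in [0, 1]")
        self.D = D

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.D, index=self.ids, columns=self.ids)


@dataclass
class Ordination:
    """Principal coordinates: sample scores plus the full eigenvalue list."""

    coordinates: pd.DataFrame  # ids x retained axes
    eigenvalues: np.ndarray  # all eigenvalues, nonincreasing (may be < 0)
    proportion_explained: np.ndarray  # per retained axis


def normalize(table: AbundanceTable) -> AbundanceTable:
    """Close every (lab, sample) profile to sum 1.

    Idempotent on relative tables; rejects all-zero profiles by name.
    """
    sums = table.data.sum(axis=1)
    zero = sums[sums == 0]
    if len(zero):
        raise ValidationError(f"all-zero profiles cannot be normalized: {list(zero.index)}")
    data = table.data.div(sums, axis=0)
    return AbundanceTable(data=data, taxa=table.taxa, units="relative")


def aggregate(table: AbundanceTable, rank: str) -> AbundanceTable:
    """Sum abundances within groups of the requested rank.

    Taxa lacking the rank are pooled into ``unclassified_<rank>``.  The
    per-profile total is preserved exactly.
    """
    if rank not in ("kingdom", "phylum", "class", "order", "family", "genus", "species"):
        raise ValidationError(f"unknown rank {rank!r}")
    groups: dict[str, list[str]] = {}
    for taxon, column in zip(table.taxa, table.data.columns):
        value = taxon.at_rank(rank)
        key = value if value is not None else f"unclassified_{rank}"
        groups.setdefault(key, []).append(column)
    agg = pd.DataFrame(
        {name: table.data[cols].sum(axis=1) for name, cols in groups.items()},
        index=table.data.index,
    )
    taxa = tuple(
        TaxonLabel(name=name, rank=rank, **{("class_" if rank == "class" else rank): name})
        if not name.startswith("unclassified_")
        else TaxonLabel(name=name)
        for name in agg.columns
    )
    agg.columns = [t.to_string() for t in taxa]
    return AbundanceTable(data=agg, taxa=taxa, units=table.units)


def _default_pseudocount(profile: np.ndarray) -> float:
    """Half the smallest nonzero value in the profile."""
    nonzero = profile[profile > 0]
    if nonzero.size == 0:
        raise ValidationError("profile is all zero; no pseudocount defined")
    return 0.5 * float(nonzero.min())


def taxa_ratio(
    table: AbundanceTable,
    numerator: str,
    denominator: str,
    pseudocount: float | None = None,
) -> RatioSeries:
    """Ratio of two taxa's abundances per (lab, sample) profile.

    The pseudocount is added to both terms only in profiles where either
    abundance is zero; those profiles are flagged.  ``pseudocount=None``
    uses half the smallest nonzero abundance of each affected profile.
    The ratio is invariant to closure and to rescaling of other taxa.
    """
    names = list(table.data.columns)
    num_col = _find_taxon(names, table.taxa, numerator)
    den_col = _find_taxon(names, table.taxa, denominator)
    if num_col is None and den_col is None:
        raise ValidationError(
            f"neither {numerator!r} nor {denominator!r} present in table"
        )
    if num_col is None or den_col is None:
        missing = numerator if num_col is None else denominator
        raise ValidationError(f"taxon {missing!r} not present in table")
    if pseudocount is not None and pseudocount < 0:
        raise ValidationError("pseudocount must be >= 0")

    num = table.data[num_col].to_numpy(dtype=float)
    den = table.data[den_col].to_numpy(dtype=float)
    values = np.empty(len(num))
    flagged = []
    for i, (a, b) in enumerate(zip(num, den)):
        if a == 0 or b == 0:
            pc = (
                pseudocount
                if pseudocount is not None
                else _default_pseudocount(table.data.iloc[i].to_numpy(dtype=float))
            )
            if pc == 0:
                raise ValidationError(
                    f"zero abundance with zero pseudocount at "
                    f"{table.data.index[i]}"
                )
            values[i] = (a + pc) / (b + pc)
            flagged.append(table.data.index[i])
        else:
            values[i] = a / b
    series = pd.Series(values, index=table.data.index)
    num_i = names.index(num_col)
    den_i = names.index(den_col)
    return RatioSeries(
        numerator=table.taxa[num_i],
        denominator=table.taxa[den_i],
        values=series,
        pseudocount_used=bool(flagged),
        pseudocounted=frozenset(flagged),
    )


def _find_taxon(columns, taxa, query: str) -> str | None:
    """Match a taxon by column string or by its short name."""
    if query in columns:
        return query
    matches = [c for c, t in zip(columns, taxa) if t.name == query]
    if len(matches) > 1:
        raise ValidationError(f"taxon name {query!r} is ambiguous: {matches}")
    return matches[0] if matches else None


def inverse_simpson(profile: np.ndarray | pd.Series) -> float:
    """Inverse Simpson diversity 1 / sum(p_i^2) of one relative profile."""
    p = np.asarray(profile, dtype=float)
    total = p.sum()
    if total <= 0:
        raise ValidationError("profile sums to zero")
    p = p / total
    return float(1.0 / np.sum(p**2))


def inverse_simpson_series(table: AbundanceTable) -> pd.Series:
    """Inverse Simpson per (lab, sample) profile."""
    rel = normalize(table) if table.units == "counts" else table
    p = rel.data.to_numpy(dtype=float)
    return pd.Series(1.0 / (p**2).sum(axis=1), index=rel.data.index)


def bray_curtis(table: AbundanceTable) -> DissimilarityMatrix:
    """Bray-Curtis dissimilarity between all (lab, sample) profiles.

    D(x, y) = sum|x_i - y_i| / sum(x_i + y_i); on relative profiles this
    equals half the total variation distance.
    """
    if table.units != "relative":
        raise ValidationError("bray_curtis expects relative units; normalize first")
    values = table.data.to_numpy(dtype=float)
    D = squareform(pdist(values, metric="braycurtis"))
    ids = [f"{lab}:{sample}" for lab, sample in table.data.index]
    return DissimilarityMatrix(ids=ids, D=D)


def pcoa(dm: DissimilarityMatrix, n_axes: int = 2) -> Ordination:
    """Classical (metric) multidimensional scaling of a dissimilarity matrix.

    Gower-centers -D^2/2, takes the symmetric eigendecomposition, and keeps
    the top ``n_axes`` axes with positive eigenvalues.  Negative eigenvalues
    (Bray-Curtis is non-Euclidean) are reported in ``eigenvalues`` but
    excluded from coordinates; proportion_explained divides by the sum of
    positive eigenvalues.
    """
    D = dm.D
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    eigval, eigvec = np.linalg.eigh((B + B.T) / 2)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    positive = eigval > max(1e-12 * max(eigval.max(), 0.0), 0.0)
    n_pos = int(positive.sum())
    if n_axes > n_pos:
        warnings.warn(
            f"requested {n_axes} axes but only {n_pos} positive eigenvalues; truncating",
            stacklevel=2,
        )
        n_axes = n_pos
    coords = eigvec[:, :n_axes] * np.sqrt(eigval[:n_axes])
    pos_sum = eigval[positive].sum()
    proportion = eigval[:n_axes] / pos_sum if pos_sum > 0 else np.zeros(n_axes)
    frame = pd.DataFrame(
        coords, index=dm.ids, columns=[f"PC{i + 1}" for i in range(n_axes)]
    )
    return Ordination(
        coordinates=frame, eigenvalues=eigval, proportion_explained=proportion
    )


def rarefy(table: AbundanceTable, depth: int, seed: int | None = None) -> AbundanceTable:
    """Subsample every profile without replacement to exactly ``depth`` reads.

    Multivariate-hypergeometric draws, deterministic under ``seed``.
    Profiles shallower than ``depth`` are rejected by name.
    """
    if table.units != "counts":
        raise ValidationError("rarefy requires a counts table")
    counts = np.round(table.data.to_numpy(dtype=float)).astype(np.int64)
    totals = counts.sum(axis=1)
    shallow = totals < depth
    if shallow.any():
        bad = table.data.index[shallow].tolist()
        raise ValidationError(f"profiles shallower than depth {depth}: {bad}")
    rng = np.random.default_rng(seed)
    out = np.empty_like(counts)
    for i in range(counts.shape[0]):
        out[i] = rng.multivariate_hypergeometric(counts[i], depth)
    data = pd.DataFrame(
        out.astype(float), index=table.data.index, columns=table.data.columns
    )
    return AbundanceTable(data=data, taxa=table.taxa, units="counts")
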