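"""Reading, validating and writing the tabular objects of an interlab study.

The central object is the :class:`AbundanceTable`: a (lab, sample) x taxon
matrix of counts or relative abundances, with taxonomic lineage attached to
every column.  Protocol questionnaires, reference panels (genome size and
16S rRNA copy number per taxon) and ddPCR replicate measurements each get a
small typed container with the validation rules they need.

All files are plain delimited text: tab-separated by default, with
comma-separated input auto-detected.  Abundance files carry two leading key
columns ``lab_id`` and ``sample_id``; the remaining header cells are taxon
labels, either bare names or greengenes-style lineage strings such as
``k__Bacteria;p__Firmicutes;g__Blautia``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TaxonLabel",
    "AbundanceTable",
    "ProtocolMetadata",
    "ReferencePanel",
    "DdpcrMeasurements",
    "ValidationError",
    "read_abundance_table",
    "write_abundance_table",
    "read_metadata",
    "write_metadata",
    "read_reference_panel",
    "write_reference_panel",
    "read_ddpcr",
    "write_ddpcr",
]

#: Canonical rank order, deepest last.
RANKS = ("kingdom", "phylum", "class", "order", "family", "genus", "species")

_PREFIX_TO_RANK = {
    "k": "kingdom",
    "p": "phylum",
    "c": "class",
    "o": "order",
    "f": "family",
    "g": "genus",
    "s": "species",
}
_RANK_TO_PREFIX = {v: k for k, v in _PREFIX_TO_RANK.items()}

#: Accepted spellings of the two sequencing strategies.
STRATEGY_SYNONYMS = {
    "16s": "amplicon",
    "amplicon": "amplicon",
    "wgs": "shotgun",
    "shotgun": "shotgun",
    "metagenomic": "shotgun",
}


class ValidationError(ValueError):
    """Raised when an input table violates a documented invariant."""


def normalize_strategy(value: str) -> str:
    """Map a strategy spelling (``16S``, ``WGS`` ...) to amplicon/shotgun."""
    key = str(value).strip().lower()
    try:
        return STRATEGY_SYNONYMS[key]
    except KeyError:
        raise ValidationError(
            f"unrecognized sequencing strategy {value!r}; "
            f"accepted: {sorted(set(STRATEGY_SYNONYMS))}"
        ) from None


@dataclass(frozen=True)
class TaxonLabel:
    """A taxon with as much of its lineage as is known.

    ``name`` is the deepest populated rank's value and ``rank`` that rank;
    a bare label with no lineage information has ``rank=None``.
    """

    name: str
    rank: str | None = None
    kingdom: str | None = None
    phylum: str | None = None
    class_: str | None = None
    order: str | None = None
    family: str | None = None
    genus: str | None = None
    species: str | None = None

    def __post_init__(self) -> None:
        if not self.name:
            raise ValidationError("taxon name must be non-empty")
        if self.rank is not None:
            if self.rank not in RANKS:
                raise ValidationError(f"unknown rank {self.rank!r}")
            if self.at_rank(self.rank) != self.name:
                raise ValidationError(
                    f"name {self.name!r} inconsistent with rank "
                    f"{self.rank!r} field {self.at_rank(self.rank)!r}"
                )

    def at_rank(self, rank: str) -> str | None:
        attr = "class_" if rank == "class" else rank
        return getattr(self, attr)

    @classmethod
    def from_string(cls, label: str) -> "TaxonLabel":
        """Parse ``k__Bacteria;p__Firmicutes;g__Blautia`` or a bare name."""
        label = label.strip()
        if "__" not in label:
            return cls(name=label)
        fields: dict[str, str] = {}
        deepest: str | None = None
        for part in label.split(";"):
            part = part.strip()
            if not part:
                continue
            prefix, _, value = part.partition("__")
            rank = _PREFIX_TO_RANK.get(prefix.lower())
            if rank is None:
                raise ValidationError(f"bad lineage field {part!r} in {label!r}")
            if value:
                fields["class_" if rank == "class" else rank] = value
                deepest = rank
        if deepest is None:
            raise ValidationError(f"lineage {label!r} has no populated rank")
        name = fields["class_" if deepest == "class" else deepest]
        return cls(name=name, rank=deepest, **fields)

    def to_string(self) -> str:
        if self.rank is None:
            return self.name
        parts = []
        for rank in RANKS:
            value = self.at_rank(rank)
            if value is not None:
                parts.append(f"{_RANK_TO_PREFIX[rank]}__{value}")
            if rank == self.rank:
                break
        return ";".join(parts)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.to_string()


@dataclass
class AbundanceTable:
    """(lab, sample) x taxon matrix of counts or relative abundances.

    ``data`` is a DataFrame whose row index is a (lab_id, sample_id)
    MultiIndex and whose columns are canonical taxon strings; ``taxa``
    holds the parsed :class:`TaxonLabel` for each column in order.
    """

    data: pd.DataFrame
    taxa: tuple[TaxonLabel, ...]
    units: str  # "counts" | "relative"

    REL_TOL = 1e-9
    RENORM_BAND = (0.99, 1.01)

    def __post_init__(self) -> None:
        self.validate()

    # -- construction ---------------------------------------------------
    @classmethod
    def from_arrays(
        cls,
        labs: Sequence[str],
        samples: Sequence[str],
        taxa: Sequence[TaxonLabel | str],
        values: np.ndarray,
        units: str,
    ) -> "AbundanceTable":
        """Build from a dense (lab, sample, taxon) array."""
        taxa_t = tuple(
            t if isinstance(t, TaxonLabel) else TaxonLabel.from_string(t) for t in taxa
        )
        values = np.asarray(values, dtype=float)
        if values.shape != (len(labs), len(samples), len(taxa_t)):
            raise ValidationError(
                f"values shape {values.shape} != "
                f"({len(labs)}, {len(samples)}, {len(taxa_t)})"
            )
        index = pd.MultiIndex.from_product(
            [list(labs), list(samples)], names=["lab_id", "sample_id"]
        )
        data = pd.DataFrame(
            values.reshape(len(labs) * len(samples), len(taxa_t)),
            index=index,
            columns=[t.to_string() for t in taxa_t],
        )
        return cls(data=data, taxa=taxa_t, units=units)

    # -- validation -----------------------------------------------------
    def validate(self) -> None:
        if self.units not in ("counts", "relative"):
            raise ValidationError(f"units must be counts|relative, got {self.units!r}")
        if self.data.shape[0] == 0 or self.data.shape[1] == 0:
            raise ValidationError("empty abundance table")
        if self.data.index.nlevels != 2:
            raise ValidationError("row index must be (lab_id, sample_id)")
        if self.data.index.duplicated().any():
            dupes = self.data.index[self.data.index.duplicated()].tolist()
            raise ValidationError(f"duplicate (lab, sample) rows: {dupes}")
        if len(self.taxa) != self.data.shape[1]:
            raise ValidationError("taxa list does not match column count")
        values = self.data.to_numpy(dtype=float)
        if not np.isfinite(values).all():
            raise ValidationError("non-finite abundance values")
        if (values < 0).any():
            bad = self.data.index[(values < 0).any(axis=1)].tolist()
            raise ValidationError(f"negative abundances in rows {bad}")
        if self.units == "relative":
            sums = values.sum(axis=1)
            off = np.abs(sums - 1.0) > self.REL_TOL
            if off.any():
                lo, hi = self.RENORM_BAND
                fixable = (sums >= lo) & (sums <= hi)
                if (off & ~fixable).any():
                    bad = self.data.index[off & ~fixable].tolist()
                    raise ValidationError(
                        f"relative profiles do not sum to 1: rows {bad} "
                        f"(sums {sums[off & ~fixable][:5]})"
                    )
                warnings.warn(
                    f"renormalizing {int((off & fixable).sum())} profiles with "
                    f"sums in [{lo}, {hi}]",
                    stacklevel=2,
                )
                self.data = self.data.div(sums, axis=0)

    # -- accessors ------------------------------------------------------
    @property
    def labs(self) -> list[str]:
        return list(self.data.index.get_level_values("lab_id").unique())

    @property
    def samples(self) -> list[str]:
        return list(self.data.index.get_level_values("sample_id").unique())

    @property
    def taxon_names(self) -> list[str]:
        return list(self.data.columns)

    def profile(self, lab: str, sample: str) -> pd.Series:
        return self.data.loc[(lab, sample)]

    def select_labs(self, labs: Iterable[str]) -> "AbundanceTable":
        keep = self.data.loc[self.data.index.get_level_values("lab_id").isin(set(labs))]
        return replace(self, data=keep.copy())

    def copy(self) -> "AbundanceTable":
        return replace(self, data=self.data.copy())


@dataclass
class ProtocolMetadata:
    """One lab's questionnaire: strategy plus parameter -> level answers."""

    lab: str
    strategy: str  # "amplicon" | "shotgun"
    answers: dict[str, str] = field(default_factory=dict)
    complete: bool = True

    def __post_init__(self) -> None:
        self.strategy = normalize_strategy(self.strategy)

    def level_of(self, parameter: str) -> str | None:
        """The lab's level for a parameter; ``strategy`` is always answered."""
        if parameter == "strategy":
            return self.strategy
        return self.answers.get(parameter)


@dataclass
class ReferencePanel:
    """Per-taxon genome size (bp) and 16S rRNA gene copy number."""

    genome_size: dict[str, float]
    ssu_copy_number: dict[str, int]

    def __post_init__(self) -> None:
        if set(self.genome_size) != set(self.ssu_copy_number):
            raise ValidationError("genome_size and ssu_copy_number taxa differ")
        for taxon, size in self.genome_size.items():
            if not size > 0:
                raise ValidationError(f"genome size for {taxon!r} must be > 0")
        for taxon, copies in self.ssu_copy_number.items():
            if not copies >= 1:
                raise ValidationError(f"16S copy number for {taxon!r} must be >= 1")

    @property
    def taxa(self) -> list[str]:
        return sorted(self.genome_size)

    def subset(self, taxa: Iterable[str]) -> "ReferencePanel":
        taxa = list(taxa)
        missing = [t for t in taxa if t not in self.genome_size]
        if missing:
            raise ValidationError(f"taxa missing from reference panel: {missing}")
        return ReferencePanel(
            genome_size={t: self.genome_size[t] for t in taxa},
            ssu_copy_number={t: self.ssu_copy_number[t] for t in taxa},
        )


@dataclass
class DdpcrMeasurements:
    """Replicate ddPCR concentrations (genome copies / uL) per taxon."""

    replicates: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        clean = {}
        for taxon, reps in self.replicates.items():
            arr = np.asarray(reps, dtype=float)
            if arr.size < 2:
                raise ValidationError(f"{taxon!r}: need >= 2 ddPCR replicates")
            if not (arr > 0).all():
                raise ValidationError(f"{taxon!r}: ddPCR replicates must be > 0")
            clean[taxon] = arr
        self.replicates = clean

    @property
    def taxa(self) -> list[str]:
        return sorted(self.replicates)

    def mean(self, taxon: str) -> float:
        return float(self.replicates[taxon].mean())


# ---------------------------------------------------------------------------
# file I/O


def _read_delimited(path: str | Path) -> pd.DataFrame:
    """Read a TSV (primary) or CSV (auto-detected) file."""
    path = Path(path)
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
    sep = "\t" if "\t" in header else ","
    return pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)


def read_abundance_table(
    path: str | Path, units_hint: str | None = None
) -> AbundanceTable:
    """Read an abundance table keyed by ``lab_id``, ``sample_id``.

    Counts are auto-detected (all values integral) unless ``units_hint``
    forces ``"counts"`` or ``"relative"``.
    """
    raw = _read_delimited(path)
    if raw.shape[1] < 3:
        raise ValidationError(f"{path}: need lab_id, sample_id and >= 1 taxon column")
    key_cols = list(raw.columns[:2])
    if [c.lower() for c in key_cols] != ["lab_id", "sample_id"]:
        raise ValidationError(
            f"{path}: first two columns must be lab_id, sample_id, got {key_cols}"
        )
    if raw.empty:
        raise ValidationError(f"{path}: empty table")
    body = raw.iloc[:, 2:].apply(pd.to_numeric)
    values = body.to_numpy(dtype=float)
    if units_hint is None:
        units = "counts" if np.allclose(values, np.round(values)) else "relative"
    elif units_hint in ("counts", "relative"):
        units = units_hint
    else:
        raise ValidationError(f"units_hint must be counts|relative, got {units_hint!r}")
    index = pd.MultiIndex.from_arrays(
        [raw.iloc[:, 0], raw.iloc[:, 1]], names=["lab_id", "sample_id"]
    )
    data = pd.DataFrame(values, index=index, columns=list(body.columns))
    taxa = tuple(TaxonLabel.from_string(c) for c in body.columns)
    return AbundanceTable(data=data, taxa=taxa, units=units)


def write_abundance_table(table: AbundanceTable, path: str | Path) -> None:
    out = table.data.reset_index()
    out.to_csv(path, sep="\t", index=False)


def read_metadata(
    path: str | Path, required: Sequence[str] = ("strategy",)
) -> list[ProtocolMetadata]:
    """Read a protocol questionnaire: one row per lab, columns = parameters.

    Blank cells are recorded as missing answers.  ``complete`` is set per
    the configurable ``required`` parameter list (the original study's
    required-field list is not published, so it is configuration here).
    """
    raw = _read_delimited(path)
    cols_lower = [c.lower() for c in raw.columns]
    if "lab_id" not in cols_lower or "strategy" not in cols_lower:
        raise ValidationError(f"{path}: metadata must have lab_id and strategy columns")
    raw.columns = cols_lower
    if raw["lab_id"].duplicated().any():
        dupes = raw["lab_id"][raw["lab_id"].duplicated()].tolist()
        raise ValidationError(f"{path}: duplicate lab IDs {dupes}")
    param_cols = [c for c in raw.columns if c not in ("lab_id", "strategy")]
    records = []
    for _, row in raw.iterrows():
        answers = {p: row[p] for p in param_cols if str(row[p]).strip() != ""}
        complete = all(str(row.get(p, "")).strip() != "" for p in required)
        records.append(
            ProtocolMetadata(
                lab=row["lab_id"],
                strategy=row["strategy"],
                answers=answers,
                complete=complete,
            )
        )
    return records


def write_metadata(records: Sequence[ProtocolMetadata], path: str | Path) -> None:
    params = sorted({p for r in records for p in r.answers})
    rows = []
    for r in records:
        row = {"lab_id": r.lab, "strategy": r.strategy}
        row.update({p: r.answers.get(p, "") for p in params})
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_reference_panel(path: str | Path) -> ReferencePanel:
    """Columns: taxon, genome_size_bp, ssu_copies."""
    raw = _read_delimited(path)
    need = {"taxon", "genome_size_bp", "ssu_copies"}
    if not need.issubset({c.lower() for c in raw.columns}):
        raise ValidationError(f"{path}: reference panel needs columns {sorted(need)}")
    raw.columns = [c.lower() for c in raw.columns]
    return ReferencePanel(
        genome_size={
            r["taxon"]: float(r["genome_size_bp"]) for _, r in raw.iterrows()
        },
        ssu_copy_number={r["taxon"]: int(r["ssu_copies"]) for _, r in raw.iterrows()},
    )


def write_reference_panel(panel: ReferencePanel, path: str | Path) -> None:
    rows = [
        {
            "taxon": t,
            "genome_size_bp": panel.genome_size[t],
            "ssu_copies": panel.ssu_copy_number[t],
        }
        for t in panel.taxa
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_ddpcr(path: str | Path) -> DdpcrMeasurements:
    """Columns: taxon, replicate, copies_per_ul (long/tidy layout)."""
    raw = _read_delimited(path)
    need = {"taxon", "replicate", "copies_per_ul"}
    if not need.issubset({c.lower() for c in raw.columns}):
        raise ValidationError(f"{path}: ddPCR table needs columns {sorted(need)}")
    raw.columns = [c.lower() for c in raw.columns]
    raw["copies_per_ul"] = raw["copies_per_ul"].astype(float)
    reps = {
        taxon: grp["copies_per_ul"].to_numpy()
        for taxon, grp in raw.groupby("taxon", sort=True)
    }
    return DdpcrMeasurements(replicates=reps)


def write_ddpcr(ddpcr: DdpcrMeasurements, path: str | Path) -> None:
    rows = []
    for taxon in ddpcr.taxa:
        for i, value in enumerate(ddpcr.replicates[taxon], start=1):
            rows.append({"taxon": taxon, "replicate": i, "copies_per_ul": value})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def export_biom_tsv(table: AbundanceTable, path: str | Path) -> None:
    """Export to classic BIOM-TSV layout: taxa as rows, profiles as columns.

    The observation-metadata column carries the lineage string.
    """
    wide = table.data.T
    wide.columns = [f"{lab}:{sample}" for lab, sample in table.data.index]
    out = wide.reset_index().rename(columns={"index": "#OTU ID"})
    out["taxonomy"] = [t.to_string() for t in table.taxa]
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# Constructed from abundance table\n")
        out.to_csv(fh, sep="\t", index=False)
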