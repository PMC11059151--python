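"""Submission- and material-level quality control.

Four checks that precede any between-lab statistics: filtering the
submission roster (incomplete metadata, duplicate datasets), detecting
sample-label transpositions from each lab's position relative to the
other labs' per-sample consensus, quantifying aliquot homogeneity, and
assessing whether the spike-in organisms' ratio is constant within a lab.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import permutations

import numpy as np
import pandas as pd

from .composition import normalize
from .tables_io import AbundanceTable, TaxonLabel, ValidationError

__all__ = [
    "RosterEntry",
    "SubmissionRoster",
    "SpikeinPair",
    "filter_roster",
    "detect_label_transposition",
    "homogeneity",
    "spikein_pair",
    "spikein_constancy",
]


@dataclass(frozen=True)
class RosterEntry:
    lab: str
    dataset_id: str
    complete_metadata: bool = True
    duplicate_of: str | None = None


@dataclass
class SubmissionRoster:
    entries: list[RosterEntry]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for e in self.entries:
            if e.duplicate_of is not None and e.duplicate_of not in seen:
                raise ValidationError(
                    f"{e.dataset_id}: duplicate_of {e.duplicate_of!r} does not "
                    "reference an earlier entry"
                )
            seen.add(e.dataset_id)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "SubmissionRoster":
        entries = [
            RosterEntry(
                lab=str(r["lab"]),
                dataset_id=str(r["dataset_id"]),
                complete_metadata=str(r.get("complete_metadata", "true")).lower()
                in ("true", "1", "yes"),
                duplicate_of=(str(r["duplicate_of"]) or None)
                if "duplicate_of" in frame.columns and str(r["duplicate_of"]).strip()
                else None,
            )
            for _, r in frame.iterrows()
        ]
        return cls(entries=entries)


def filter_roster(roster: SubmissionRoster) -> tuple[list[RosterEntry], pd.DataFrame]:
    """Drop incomplete-metadata entries, then duplicates (keeping the first).

    An entry that is both incomplete and a duplicate counts once, under
    incomplete.  Returns (retained entries, exclusion log).
    """
    retained: list[RosterEntry] = []
    log_rows = []
    kept_ids: set[str] = set()
    for e in roster.entries:
        if not e.complete_metadata:
            log_rows.append(
                {"dataset_id": e.dataset_id, "lab": e.lab, "reason": "incomplete_metadata"}
            )
            continue
        if e.duplicate_of is not None and e.duplicate_of in kept_ids:
            log_rows.append(
                {
                    "dataset_id": e.dataset_id,
                    "lab": e.lab,
                    "reason": f"duplicate_of:{e.duplicate_of}",
                }
            )
            continue
        retained.append(e)
        kept_ids.add(e.dataset_id)
    return retained, pd.DataFrame(log_rows, columns=["dataset_id", "lab", "reason"])


def _bray_curtis_vec(x: np.ndarray, y: np.ndarray) -> float:
    denom = (x + y).sum()
    return float(np.abs(x - y).sum() / denom) if denom > 0 else 0.0


def detect_label_transposition(
    table: AbundanceTable, margin: float = 0.2
) -> list[dict]:
    """Flag labs whose sample labels appear permuted.

    For each lab, its profiles are compared (Bray-Curtis) to
    leave-that-lab-out per-sample centroid profiles; the sample-label
    permutation minimizing the total dissimilarity is found exhaustively.
    A lab is reported when its best permutation is non-identity and
    improves the total by more than ``margin`` (relative).  The reported
    permutation maps each claimed label to the inferred true sample — the
    inverse of the relabeling that produced the data.
    """
    rel = normalize(table) if table.units == "counts" else table
    labs = rel.labs
    samples = rel.samples
    if len(labs) < 3:
        raise ValidationError("need >= 3 labs for leave-one-out centroids")
    n_s = len(samples)
    # dense array (lab, sample, taxon)
    arr = np.stack(
        [
            np.stack([rel.profile(lab, s).to_numpy(dtype=float) for s in samples])
            for lab in labs
        ]
    )
    totals = arr.sum(axis=0)  # per-sample sum over labs
    reports = []
    for li, lab in enumerate(labs):
        centroids = (totals - arr[li]) / (len(labs) - 1)
        # cost[c, t]: dissimilarity of the lab's profile labeled sample c
        # to the consensus centroid of sample t
        cost = np.array(
            [
                [_bray_curtis_vec(arr[li, c], centroids[t]) for t in range(n_s)]
                for c in range(n_s)
            ]
        )
        identity_cost = float(np.trace(cost))
        best_perm, best_cost = tuple(range(n_s)), identity_cost
        for perm in permutations(range(n_s)):
            c = float(cost[np.arange(n_s), perm].sum())
            if c < best_cost:
                best_perm, best_cost = perm, c
        if best_perm == tuple(range(n_s)):
            continue
        improvement = (
            (identity_cost - best_cost) / identity_cost if identity_cost > 0 else 0.0
        )
        if improvement > margin:
            reports.append(
                {
                    "lab": lab,
                    "inferred_permutation": {
                        samples[c]: samples[t] for c, t in enumerate(best_perm)
                    },
                    "score": improvement,
                }
            )
    return reports


def homogeneity(
    replicates: AbundanceTable,
    groups: dict[str, str] | None = None,
    threshold: float = 0.1,
) -> pd.DataFrame:
    """Within-sample dispersion over aliquot replicates of a single lab.

    ``groups`` maps each aliquot's sample_id to its parent sample;
    the default parses ``"<sample>:<aliquot>"`` IDs.  Returns one row per
    sample: mean and max pairwise Bray-Curtis among its aliquots and a
    pass flag against ``threshold`` (on the mean).
    """
    if len(replicates.labs) != 1:
        raise ValidationError("homogeneity expects a single-lab table")
    rel = normalize(replicates) if replicates.units == "counts" else replicates
    if groups is None:
        groups = {s: s.split(":")[0] for s in rel.samples}
    by_sample: dict[str, list[str]] = {}
    for aliquot, sample in groups.items():
        by_sample.setdefault(sample, []).append(aliquot)
    lab = rel.labs[0]
    rows = []
    for sample in sorted(by_sample):
        aliquots = by_sample[sample]
        if len(aliquots) < 2:
            raise ValidationError(f"sample {sample!r} has < 2 aliquots")
        profiles = [rel.profile(lab, a).to_numpy(dtype=float) for a in aliquots]
        d = [
            _bray_curtis_vec(profiles[i], profiles[j])
            for i in range(len(profiles))
            for j in range(i + 1, len(profiles))
        ]
        rows.append(
            {
                "sample": sample,
                "n_aliquots": len(aliquots),
                "mean_bray_curtis": float(np.mean(d)),
                "max_bray_curtis": float(np.max(d)),
                "passed": bool(np.mean(d) <= threshold),
            }
        )
    return pd.DataFrame(rows)


@dataclass
class SpikeinPair:
    """Per-(lab, sample) ratio of the two spike-in organisms.

    ``values`` holds ratios where both taxa were detected; ``nondetects``
    lists (lab, sample, which-taxon-was-zero) rows that are excluded
    rather than pseudocounted — a silently absent spike-in is the finding,
    not a number to impute.
    """

    taxon_a: TaxonLabel
    taxon_b: TaxonLabel
    values: pd.Series
    nondetects: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["lab", "sample", "missing"])
    )


def spikein_pair(
    table: AbundanceTable, taxon_a: str = "Aliivibrio", taxon_b: str = "Leifsonia"
) -> SpikeinPair:
    """Extract the spike-in ratio series from an abundance table."""
    rel = normalize(table) if table.units == "counts" else table
    col_a = col_b = None
    lab_a = lab_b = None
    for col, t in zip(rel.data.columns, rel.taxa):
        if t.name == taxon_a or col == taxon_a:
            col_a, lab_a = col, t
        if t.name == taxon_b or col == taxon_b:
            col_b, lab_b = col, t
    if col_a is None or col_b is None:
        missing = taxon_a if col_a is None else taxon_b
        raise ValidationError(f"spike-in taxon {missing!r} not in table")
    a = rel.data[col_a]
    b = rel.data[col_b]
    detected = (a > 0) & (b > 0)
    nd_rows = []
    for (lab, sample), ok in detected.items():
        if not ok:
            which = []
            if a.loc[(lab, sample)] == 0:
                which.append(taxon_a)
            if b.loc[(lab, sample)] == 0:
                which.append(taxon_b)
            nd_rows.append({"lab": lab, "sample": sample, "missing": "+".join(which)})
    return SpikeinPair(
        taxon_a=lab_a,
        taxon_b=lab_b,
        values=(a[detected] / b[detected]),
        nondetects=pd.DataFrame(nd_rows, columns=["lab", "sample", "missing"]),
    )


def spikein_constancy(pair: SpikeinPair) -> dict:
    """Within-lab constancy of the spike-in log2 ratio across samples.

    For each lab with >= 2 fully detected samples: mean, SD and
    coefficient of variation (SD/|mean|) of log2(a/b).  Labs with any
    nondetect are reported separately with counts, never coerced into
    pseudocounted ratios.
    """
    per_lab_rows = []
    labs = pair.values.index.get_level_values("lab_id").unique()
    for lab in labs:
        vals = pair.values.xs(lab, level="lab_id").to_numpy(dtype=float)
        if vals.size < 2:
            continue
        logs = np.log2(vals)
        mean = float(logs.mean())
        sd = float(logs.std(ddof=1))
        per_lab_rows.append(
            {
                "lab": lab,
                "n_samples": int(vals.size),
                "mean_log2_ratio": mean,
                "sd_log2_ratio": sd,
                "cv_log2_ratio": sd / abs(mean) if mean != 0 else float("inf"),
            }
        )
    nondetect_counts = (
        pair.nondetects.groupby("lab")["sample"].count().to_dict()
        if len(pair.nondetects)
        else {}
    )
    return {
        "per_lab": pd.DataFrame(
            per_lab_rows,
            columns=["lab", "n_samples", "mean_log2_ratio", "sd_log2_ratio", "cv_log2_ratio"],
        ),
        "nondetects": nondetect_counts,
    }
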