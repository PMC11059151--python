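"""Ground-truth pairwise taxa ratios for DNA mock communities, and bias scoring.

ddPCR gives absolute genome copies per taxon.  What a sequencing assay
sees is not genome copies: amplicon signal scales with copies x 16S rRNA
copy number, shotgun signal with copies x genome size.  Scaling the ddPCR
means by the strategy's factor yields the expected relative signal, and
pairwise ratios of those signals are the ground truth an unbiased lab
should report.  Comparing each lab's observed ratios to the truth splits
disagreement into *consensus* (do labs agree with each other?) and
*accuracy* (does their consensus agree with the truth?) — a narrow spread
centred away from the truth is the "consensus with bias" signature.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .composition import aggregate, normalize
from .tables_io import (
    AbundanceTable,
    DdpcrMeasurements,
    ReferencePanel,
    ValidationError,
)

__all__ = [
    "GroundTruthPanel",
    "BiasReport",
    "scale_truth",
    "observed_pair_ratios",
    "bias_report",
]


@dataclass
class GroundTruthPanel:
    """Expected pairwise ratios for one strategy, with replicate-based CIs.

    ``pair_ratios`` has one row per unordered pair (taxon_i < taxon_j) with
    columns truth, ci_low, ci_high (ratio scale).  ``ratio(i, j)`` serves
    both orientations; ratio(i,j) * ratio(j,i) = 1 by construction.
    """

    strategy: str
    taxa: list[str]
    copies: dict
    scaled_abundance: dict  # taxon -> expected relative signal
    pair_ratios: pd.DataFrame
    ci: float

    def ratio(self, taxon_i: str, taxon_j: str) -> tuple[float, float, float]:
        """(truth, ci_low, ci_high) for taxon_i : taxon_j."""
        rows = self.pair_ratios
        hit = rows[(rows.taxon_i == taxon_i) & (rows.taxon_j == taxon_j)]
        if len(hit):
            r = hit.iloc[0]
            return float(r.truth), float(r.ci_low), float(r.ci_high)
        hit = rows[(rows.taxon_i == taxon_j) & (rows.taxon_j == taxon_i)]
        if len(hit):
            r = hit.iloc[0]
            return 1.0 / float(r.truth), 1.0 / float(r.ci_high), 1.0 / float(r.ci_low)
        raise ValidationError(f"pair ({taxon_i}, {taxon_j}) not in panel")


@dataclass
class BiasReport:
    """Per-(lab, pair) bias and per-pair consensus/accuracy summaries.

    ``per_lab`` columns: lab, sample, taxon_i, taxon_j, observed_ratio,
    truth_ratio, bias_log2.  ``per_pair`` columns: sample, taxon_i,
    taxon_j, consensus_center, consensus_spread, accuracy_offset, n_labs,
    consensus_with_bias.
    """

    per_lab: pd.DataFrame
    per_pair: pd.DataFrame
    s_max: float
    ci: float


def scale_truth(
    ddpcr: DdpcrMeasurements,
    panel: ReferencePanel,
    strategy: str,
    ci: float = 0.99,
    method: str = "t",
    n_boot: int = 5000,
    seed: int | None = None,
) -> GroundTruthPanel:
    """Expected pairwise signal ratios for one strategy from ddPCR copies.

    Signal is copies x 16S copy number (amplicon) or copies x genome size
    (shotgun).  The CI on each pair reflects ddPCR replicate variability
    only: by default a t-interval on the log ratio of replicate means
    (delta-method standard errors), or a seeded bootstrap over replicates.
    """
    if strategy not in ("amplicon", "shotgun"):
        raise ValidationError(f"strategy must be amplicon|shotgun, got {strategy!r}")
    taxa = ddpcr.taxa
    missing = [t for t in taxa if t not in panel.genome_size]
    if missing:
        raise ValidationError(f"taxa missing from reference panel: {missing}")
    factor = {
        t: (
            panel.ssu_copy_number[t]
            if strategy == "amplicon"
            else panel.genome_size[t]
        )
        for t in taxa
    }
    copies = {t: ddpcr.mean(t) for t in taxa}
    signal = {t: copies[t] * factor[t] for t in taxa}
    total = sum(signal.values())
    scaled = {t: signal[t] / total for t in taxa}

    rows = []
    rng = np.random.default_rng(seed)
    for ti, tj in combinations(taxa, 2):
        truth = signal[ti] / signal[tj]
        ri, rj = ddpcr.replicates[ti], ddpcr.replicates[tj]
        if method == "t":
            # delta-method SE of log(mean) per taxon, pooled df
            se_i = ri.std(ddof=1) / (np.sqrt(ri.size) * ri.mean())
            se_j = rj.std(ddof=1) / (np.sqrt(rj.size) * rj.mean())
            se = float(np.hypot(se_i, se_j))
            tq = stats.t.ppf((1 + ci) / 2, df=ri.size + rj.size - 2)
            lo, hi = truth * np.exp(-tq * se), truth * np.exp(tq * se)
        elif method == "bootstrap":
            bi = rng.integers(0, ri.size, size=(n_boot, ri.size))
            bj = rng.integers(0, rj.size, size=(n_boot, rj.size))
            boots = (ri[bi].mean(axis=1) * factor[ti]) / (
                rj[bj].mean(axis=1) * factor[tj]
            )
            alpha = (1 - ci) / 2
            lo, hi = np.quantile(boots, [alpha, 1 - alpha])
        else:
            raise ValidationError(f"method must be t|bootstrap, got {method!r}")
        rows.append(
            {
                "taxon_i": ti,
                "taxon_j": tj,
                "truth": truth,
                "ci_low": float(lo),
                "ci_high": float(hi),
            }
        )
    return GroundTruthPanel(
        strategy=strategy,
        taxa=list(taxa),
        copies=copies,
        scaled_abundance=scaled,
        pair_ratios=pd.DataFrame(rows),
        ci=ci,
    )


def observed_pair_ratios(
    table: AbundanceTable,
    panel_taxa: list[str],
    pseudocount: float | None = None,
) -> pd.DataFrame:
    """Per-lab observed ratios for every panel pair, per sample (mixture).

    The table is aggregated to genus and normalized first.  Zero
    abundances are pseudocounted (half the smallest nonzero abundance in
    the profile unless ``pseudocount`` is given) and flagged.
    """
    genus_names = {t.name if t.rank else t.name for t in table.taxa}
    if any(t.rank not in (None, "genus") for t in table.taxa):
        table = aggregate(table, "genus")
        genus_names = {t.name for t in table.taxa}
    missing = [t for t in panel_taxa if t not in genus_names and f"g__{t}" not in set(table.data.columns)]
    if missing:
        raise ValidationError(f"panel taxa absent from table: {missing}")
    rel = normalize(table)
    colmap = {}
    for t in panel_taxa:
        for col, lab_t in zip(rel.data.columns, rel.taxa):
            if lab_t.name == t:
                colmap[t] = col
                break
    rows = []
    for (lab, sample), profile in rel.data.iterrows():
        vals = profile.to_numpy(dtype=float)
        nonzero = vals[vals > 0]
        pc_default = 0.5 * float(nonzero.min()) if nonzero.size else 0.0
        for ti, tj in combinations(panel_taxa, 2):
            a, b = profile[colmap[ti]], profile[colmap[tj]]
            pseudo = a == 0 or b == 0
            if pseudo:
                pc = pseudocount if pseudocount is not None else pc_default
                if pc <= 0:
                    raise ValidationError(
                        f"zero abundance with no pseudocount at ({lab}, {sample})"
                    )
                a, b = a + pc, b + pc
            rows.append(
                {
                    "lab": lab,
                    "sample": sample,
                    "taxon_i": ti,
                    "taxon_j": tj,
                    "ratio": float(a / b),
                    "pseudocounted": bool(pseudo),
                }
            )
    return pd.DataFrame(rows)


def bias_report(
    observed: pd.DataFrame,
    truth_panel: GroundTruthPanel,
    s_max: float = 1.0,
) -> BiasReport:
    """Score observed ratios against the ground truth.

    Per (lab, pair): bias_log2 = log2(observed / truth).  Per pair:
    consensus_center (median of labs' log2 ratios), consensus_spread
    (IQR), accuracy_offset (|median bias|).  A pair is flagged
    ``consensus_with_bias`` when the labs agree tightly
    (spread < ``s_max`` log2 units) yet the truth CI, widened by the
    consensus center's own lab-sampling standard error, excludes the
    center — i.e. the disagreement is not explainable by replicate or
    lab-sampling noise.
    """
    need = {"lab", "sample", "taxon_i", "taxon_j", "ratio"}
    if not need.issubset(observed.columns):
        raise ValidationError(f"observed ratios need columns {sorted(need)}")
    truth_pairs = {
        (r.taxon_i, r.taxon_j) for r in truth_panel.pair_ratios.itertuples()
    }
    obs_pairs = {(r.taxon_i, r.taxon_j) for r in observed.itertuples()}
    unmatched = {
        (i, j) for (i, j) in obs_pairs if (i, j) not in truth_pairs and (j, i) not in truth_pairs
    }
    if unmatched or not obs_pairs:
        raise ValidationError(f"pair keys do not match truth panel: {sorted(unmatched)}")

    lab_rows = []
    for r in observed.itertuples():
        truth, _, _ = truth_panel.ratio(r.taxon_i, r.taxon_j)
        lab_rows.append(
            {
                "lab": r.lab,
                "sample": r.sample,
                "taxon_i": r.taxon_i,
                "taxon_j": r.taxon_j,
                "observed_ratio": r.ratio,
                "truth_ratio": truth,
                "bias_log2": float(np.log2(r.ratio / truth)),
            }
        )
    per_lab = pd.DataFrame(lab_rows)

    pair_rows = []
    for (sample, ti, tj), grp in per_lab.groupby(
        ["sample", "taxon_i", "taxon_j"], sort=True
    ):
        logs = np.log2(grp["observed_ratio"].to_numpy())
        center = float(np.median(logs))
        q75, q25 = np.percentile(logs, [75, 25])
        spread = float(q75 - q25)
        truth, lo, hi = truth_panel.ratio(ti, tj)
        offset = float(abs(np.median(grp["bias_log2"].to_numpy())))
        n = len(grp)
        # half-width of the truth CI plus the center's own sampling error
        hw = 0.5 * float(np.log2(hi / lo))
        if n > 1 and logs.std(ddof=1) > 0:
            se_center = 1.2533 * logs.std(ddof=1) / np.sqrt(n)  # SE of a median
            tq = stats.t.ppf((1 + truth_panel.ci) / 2, df=n - 1)
            hw += float(tq * se_center)
        excluded = abs(center - np.log2(truth)) > hw
        pair_rows.append(
            {
                "sample": sample,
                "taxon_i": ti,
                "taxon_j": tj,
                "consensus_center": center,
                "consensus_spread": spread,
                "accuracy_offset": offset,
                "n_labs": n,
                "consensus_with_bias": bool(spread < s_max and excluded),
            }
        )
    return BiasReport(
        per_lab=per_lab,
        per_pair=pd.DataFrame(pair_rows),
        s_max=s_max,
        ci=truth_panel.ci,
    )
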