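"""Per-parameter effects on a taxa ratio across laboratories.

The measurand is a within-profile taxa ratio (e.g. Firmicutes:Bacteroidetes).
For a protocol parameter level L and one sample, the parameter effect is

    effect_log2 = log2( mean over labs reporting L of ratio
                        / mean over all labs of ratio )

with arithmetic means on the ratio scale, so 0 means "labs choosing L agree
with the overall average".  The overall mean includes the group itself, so
effects of dominant levels shrink toward 0.  Confidence intervals come from
a nonparametric bootstrap that resamples the full lab roster once per
replicate and recomputes both means from the same resample (resampling
group and overall independently would ignore their overlap).  A between-lab
robustness measure compares the spread of log2 ratios within a protocol
group to the spread over all labs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .composition import RatioSeries
from .tables_io import ProtocolMetadata, ValidationError

__all__ = [
    "EffectEstimate",
    "parameter_effect",
    "level_contrast",
    "sweep",
    "robustness",
    "significant_across_samples",
]


@dataclass
class EffectEstimate:
    """One (parameter, level, sample) effect on the taxa ratio."""

    parameter: str
    level: str
    sample: str
    effect_log2: float
    ci_low: float
    ci_high: float
    ci: float
    n_labs: int
    variability_ratio: float
    significant: bool
    ci_defined: bool = True

    def __post_init__(self) -> None:
        if self.ci_defined and not (
            self.ci_low - 1e-12 <= self.effect_log2 <= self.ci_high + 1e-12
        ):
            raise ValidationError("point estimate outside its own CI")


def _mean(values: np.ndarray, scale: str) -> float:
    if scale == "arithmetic":
        return float(values.mean())
    if scale == "geometric":
        return float(np.exp(np.log(values).mean()))
    raise ValidationError(f"mean scale must be arithmetic|geometric, got {scale!r}")


def _collect(
    ratios: RatioSeries,
    metadata: list[ProtocolMetadata],
    sample: str,
) -> tuple[np.ndarray, list[str], dict[str, ProtocolMetadata]]:
    """Ratio vector for one sample, aligned to sorted lab IDs with metadata."""
    by_lab = {m.lab: m for m in metadata}
    series = ratios.for_sample(sample)
    labs = sorted(lab for lab in series.index if lab in by_lab)
    if not labs:
        raise ValidationError(f"no labs with both ratios and metadata for {sample!r}")
    values = series.loc[labs].to_numpy(dtype=float)
    if (values <= 0).any():
        raise ValidationError("nonpositive ratios are not allowed")
    return values, labs, by_lab


def _bootstrap_ci(
    r: np.ndarray,
    in_group: np.ndarray,
    in_denom: np.ndarray,
    ci: float,
    n_boot: int,
    seed,
    scale: str,
) -> tuple[float, float]:
    """Percentile CI for log2(mean[group]/mean[denom]) over lab resamples."""
    rng = np.random.default_rng(seed)
    n = r.size
    idx = rng.integers(0, n, size=(n_boot, n))
    rb = r[idx]
    gb = in_group[idx]
    db = in_denom[idx]
    g_n = gb.sum(axis=1)
    d_n = db.sum(axis=1)
    valid = (g_n > 0) & (d_n > 0)
    if scale == "arithmetic":
        g_mean = (rb * gb).sum(axis=1)[valid] / g_n[valid]
        d_mean = (rb * db).sum(axis=1)[valid] / d_n[valid]
    else:
        logs = np.log(rb)
        g_mean = np.exp((logs * gb).sum(axis=1)[valid] / g_n[valid])
        d_mean = np.exp((logs * db).sum(axis=1)[valid] / d_n[valid])
    boots = np.log2(g_mean / d_mean)
    if boots.size < n_boot / 2:
        raise ValidationError("too few valid bootstrap replicates (group too small)")
    alpha = (1.0 - ci) / 2.0
    lo, hi = np.quantile(boots, [alpha, 1.0 - alpha])
    return float(lo), float(hi)


def parameter_effect(
    ratios: RatioSeries,
    metadata: list[ProtocolMetadata],
    parameter: str,
    level: str,
    sample: str,
    ci: float = 0.99,
    n_boot: int = 2000,
    seed: int | None = None,
    mean_scale: str = "arithmetic",
    ci_method: str = "bootstrap",
) -> EffectEstimate:
    """Effect of one parameter level on the ratio, for one sample.

    Labs missing the parameter's answer stay in the overall mean but join
    no group.  With a single group lab the point estimate is returned with
    an undefined-wide CI (``ci_defined=False``).  ``ci_method="t"`` gives a
    normal-theory cross-check interval on log2 ratios instead of the
    bootstrap; it ignores the overall mean's (smaller) uncertainty.
    """
    values, labs, by_lab = _collect(ratios, metadata, sample)
    in_group = np.array(
        [by_lab[lab].level_of(parameter) == level for lab in labs], dtype=float
    )
    n_group = int(in_group.sum())
    if n_group == 0:
        raise ValidationError(
            f"no lab reports {parameter}={level!r} for sample {sample!r}"
        )
    everyone = np.ones_like(in_group)
    group_mean = _mean(values[in_group > 0], mean_scale)
    overall_mean = _mean(values, mean_scale)
    effect = float(np.log2(group_mean / overall_mean))

    log2_all = np.log2(values)
    log2_group = log2_all[in_group > 0]
    overall_sd = float(np.std(log2_all, ddof=1)) if len(labs) > 1 else float("nan")
    group_sd = float(np.std(log2_group, ddof=1)) if n_group > 1 else float("nan")
    vr = group_sd / overall_sd if n_group > 1 and overall_sd > 0 else float("nan")

    if n_group == 1:
        return EffectEstimate(
            parameter=parameter,
            level=level,
            sample=sample,
            effect_log2=effect,
            ci_low=-np.inf,
            ci_high=np.inf,
            ci=ci,
            n_labs=1,
            variability_ratio=vr,
            significant=False,
            ci_defined=False,
        )

    if ci_method == "bootstrap":
        lo, hi = _bootstrap_ci(values, in_group, everyone, ci, n_boot, seed, mean_scale)
    elif ci_method == "t":
        from scipy import stats

        se = float(np.std(log2_group, ddof=1)) / np.sqrt(n_group)
        tq = stats.t.ppf((1 + ci) / 2, df=n_group - 1)
        center = float(log2_group.mean() - log2_all.mean())
        lo, hi = center - tq * se, center + tq * se
        effect = center if mean_scale == "geometric" else effect
        lo, hi = min(lo, effect), max(hi, effect)
    else:
        raise ValidationError(f"ci_method must be bootstrap|t, got {ci_method!r}")

    return EffectEstimate(
        parameter=parameter,
        level=level,
        sample=sample,
        effect_log2=effect,
        ci_low=min(lo, effect),
        ci_high=max(hi, effect),
        ci=ci,
        n_labs=n_group,
        variability_ratio=vr,
        significant=bool(lo > 0 or hi < 0),
    )


def level_contrast(
    ratios: RatioSeries,
    metadata: list[ProtocolMetadata],
    parameter: str,
    level_a: str,
    level_b: str,
    sample: str,
    ci: float = 0.99,
    n_boot: int = 2000,
    seed: int | None = None,
    mean_scale: str = "arithmetic",
) -> EffectEstimate:
    """log2 of (mean ratio of level-A labs / mean ratio of level-B labs).

    The two-level special case: the contrast of two level effects against
    the same overall mean, bootstrapped jointly over the full lab roster.
    """
    values, labs, by_lab = _collect(ratios, metadata, sample)
    in_a = np.array(
        [by_lab[lab].level_of(parameter) == level_a for lab in labs], dtype=float
    )
    in_b = np.array(
        [by_lab[lab].level_of(parameter) == level_b for lab in labs], dtype=float
    )
    if in_a.sum() == 0 or in_b.sum() == 0:
        raise ValidationError(f"both levels need >= 1 lab for sample {sample!r}")
    effect = float(
        np.log2(_mean(values[in_a > 0], mean_scale) / _mean(values[in_b > 0], mean_scale))
    )
    lo, hi = _bootstrap_ci(values, in_a, in_b, ci, n_boot, seed, mean_scale)
    log2_all = np.log2(values)
    overall_sd = float(np.std(log2_all, ddof=1)) if len(labs) > 1 else float("nan")
    group_sd = (
        float(np.std(log2_all[in_a > 0], ddof=1)) if in_a.sum() > 1 else float("nan")
    )
    return EffectEstimate(
        parameter=parameter,
        level=f"{level_a} vs {level_b}",
        sample=sample,
        effect_log2=effect,
        ci_low=min(lo, effect),
        ci_high=max(hi, effect),
        ci=ci,
        n_labs=int(in_a.sum() + in_b.sum()),
        variability_ratio=group_sd / overall_sd if overall_sd else float("nan"),
        significant=bool(lo > 0 or hi < 0),
    )


def sweep(
    ratios: RatioSeries,
    metadata: list[ProtocolMetadata],
    sample: str,
    stratum: str = "all",
    ci: float = 0.99,
    n_boot: int = 2000,
    seed: int | None = None,
    mean_scale: str = "arithmetic",
) -> list[EffectEstimate]:
    """One effect per (parameter, observed level) within a strategy stratum.

    ``stratum`` restricts both the groups and the overall mean to amplicon
    or shotgun labs (the study's hierarchical gating: downstream choices
    only make sense within one strategy).  Parameters never answered by a
    stratum lab are skipped.  Results are sorted by decreasing |effect|.
    """
    if stratum not in ("amplicon", "shotgun", "all"):
        raise ValidationError(f"stratum must be amplicon|shotgun|all, got {stratum!r}")
    if stratum == "all":
        meta = list(metadata)
    else:
        meta = [m for m in metadata if m.strategy == stratum]
    if not meta:
        raise ValidationError(f"stratum {stratum!r} is empty")
    strat_ratios = ratios.restrict_labs([m.lab for m in meta])

    parameters: dict[str, list[str]] = {}
    if stratum == "all":
        parameters["strategy"] = sorted({m.strategy for m in meta})
    for m in meta:
        for p, lvl in m.answers.items():
            levels = parameters.setdefault(p, [])
            if lvl not in levels:
                levels.append(lvl)

    import zlib

    estimates = []
    for p in sorted(parameters):
        for lvl in sorted(parameters[p]):
            # stable per-(parameter, level) substream: estimates do not
            # depend on sweep order or on which other parameters exist
            child = np.random.SeedSequence(
                entropy=seed if seed is not None else 0,
                spawn_key=(zlib.crc32(f"{p}={lvl}".encode()),),
            )
            estimates.append(
                parameter_effect(
                    strat_ratios,
                    meta,
                    p,
                    lvl,
                    sample,
                    ci=ci,
                    n_boot=n_boot,
                    seed=child,
                    mean_scale=mean_scale,
                )
            )
    estimates.sort(key=lambda e: abs(e.effect_log2), reverse=True)
    return estimates


def robustness(
    ratios: RatioSeries,
    metadata: list[ProtocolMetadata],
    grouping: list[tuple[str, str]],
    sample: str,
) -> dict:
    """Between-lab variability of a protocol group relative to all labs.

    ``grouping`` is a conjunction of (parameter, level) conditions; SDs are
    of log2 ratios.  A variability_ratio well below 1 means the protocol
    combination stabilizes the measurand even if it does not shift it.
    """
    values, labs, by_lab = _collect(ratios, metadata, sample)
    mask = np.array(
        [
            all(by_lab[lab].level_of(p) == lvl for p, lvl in grouping)
            for lab in labs
        ],
        dtype=bool,
    )
    if mask.sum() < 2:
        raise ValidationError(
            f"grouping {grouping} matches {int(mask.sum())} labs; need >= 2"
        )
    log2_all = np.log2(values)
    group_sd = float(np.std(log2_all[mask], ddof=1))
    overall_sd = float(np.std(log2_all, ddof=1))
    return {
        "group_sd": group_sd,
        "overall_sd": overall_sd,
        "variability_ratio": group_sd / overall_sd if overall_sd > 0 else float("nan"),
        "n_labs": int(mask.sum()),
    }


def significant_across_samples(
    estimates: list[EffectEstimate], min_samples: int = 2
) -> list[EffectEstimate]:
    """Keep (parameter, level) pairs significant in >= ``min_samples`` samples.

    The study's replication screen: a level matters only if its CI excludes
    0 for two or more of the stool samples.
    """
    sig_samples: dict[tuple[str, str], set[str]] = {}
    for e in estimates:
        if e.significant:
            sig_samples.setdefault((e.parameter, e.level), set()).add(e.sample)
    keep = {k for k, ss in sig_samples.items() if len(ss) >= min_samples}
    return [e for e in estimates if (e.parameter, e.level) in keep]


def estimates_to_frame(estimates: list[EffectEstimate]) -> pd.DataFrame:
    """Tidy table of effect estimates (one row per parameter/level/sample)."""
    return pd.DataFrame(
        [
            {
                "parameter": e.parameter,
                "level": e.level,
                "sample": e.sample,
                "effect_log2": e.effect_log2,
                "ci_low": e.ci_low,
                "ci_high": e.ci_high,
                "ci": e.ci,
                "n_labs": e.n_labs,
                "variability_ratio": e.variability_ratio,
                "significant": e.significant,
            }
            for e in estimates
        ]
    )
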