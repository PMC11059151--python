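import numpy as np
import pandas as pd
import pytest

from interlab_mgs import (
    EffectEstimate,
    ProtocolMetadata,
    ValidationError,
    level_contrast,
    parameter_effect,
    robustness,
    significant_across_samples,
    sweep,
)
from interlab_mgs.composition import RatioSeries
from interlab_mgs.interlab import estimates_to_frame
from interlab_mgs.tables_io import TaxonLabel


def make_ratios(values_by_lab: dict, sample: str = "S1") -> RatioSeries:
    index = pd.MultiIndex.from_tuples(
        [(lab, sample) for lab in values_by_lab], names=["lab_id", "sample_id"]
    )
    return RatioSeries(
        numerator=TaxonLabel("Firmicutes"),
        denominator=TaxonLabel("Bacteroidetes"),
        values=pd.Series(list(values_by_lab.values()), index=index),
    )


def make_meta(levels_by_lab: dict, parameter: str = "kit") -> list[ProtocolMetadata]:
    return [
        ProtocolMetadata(
            lab,
            "amplicon",
            answers={} if level is None else {parameter: level},
        )
        for lab, level in levels_by_lab.items()
    ]


class TestParameterEffect:
    def test_identical_ratios_give_zero_effect(self):
        ratios = make_ratios({f"L{i}": 3.0 for i in range(6)})
        meta = make_meta({f"L{i}": "a" if i < 3 else "b" for i in range(6)})
        for level in ("a", "b"):
            est = parameter_effect(ratios, meta, "kit", level, "S1", n_boot=200, seed=0)
            assert est.effect_log2 == 0.0

    def test_hand_computed_group_vs_overall(self):
        # group {2, 2}, out-group {1, 1}: overall mean 1.5, effect log2(2/1.5)
        ratios = make_ratios({"L1": 2.0, "L2": 2.0, "L3": 1.0, "L4": 1.0})
        meta = make_meta({"L1": "a", "L2": "a", "L3": "b", "L4": "b"})
        est = parameter_effect(ratios, meta, "kit", "a", "S1", n_boot=200, seed=0)
        assert np.isclose(est.effect_log2, np.log2(2.0 / 1.5), atol=1e-12)
        assert est.n_labs == 2

    def test_missing_answers_stay_in_overall_mean(self):
        ratios = make_ratios({"L1": 2.0, "L2": 2.0, "L3": 1.0, "L4": 4.0})
        meta = make_meta({"L1": "a", "L2": "a", "L3": "b", "L4": None})
        est = parameter_effect(ratios, meta, "kit", "a", "S1", n_boot=200, seed=0)
        # overall mean includes L4 even though it answered nothing
        assert np.isclose(est.effect_log2, np.log2(2.0 / 2.25))

    def test_single_lab_group_flagged_undefined_ci(self):
        ratios = make_ratios({"L1": 2.0, "L2": 1.0, "L3": 1.0})
        meta = make_meta({"L1": "a", "L2": "b", "L3": "b"})
        est = parameter_effect(ratios, meta, "kit", "a", "S1", n_boot=200, seed=0)
        assert est.n_labs == 1 and not est.ci_defined and not est.significant
        assert np.isinf(est.ci_low) and np.isinf(est.ci_high)

    def test_unreported_level_rejected(self):
        ratios = make_ratios({"L1": 2.0, "L2": 1.0})
        meta = make_meta({"L1": "a", "L2": "a"})
        with pytest.raises(ValidationError):
            parameter_effect(ratios, meta, "kit", "zzz", "S1")

    def test_nonpositive_ratio_rejected(self):
        index = pd.MultiIndex.from_tuples(
            [("L1", "S1")], names=["lab_id", "sample_id"]
        )
        with pytest.raises(ValidationError):
            RatioSeries(
                numerator=TaxonLabel("a"),
                denominator=TaxonLabel("b"),
                values=pd.Series([-1.0], index=index),
            )

    def test_invariant_to_lab_ordering(self):
        vals = {"L1": 2.0, "L2": 3.0, "L3": 1.0, "L4": 0.5}
        levels = {"L1": "a", "L2": "a", "L3": "b", "L4": "b"}
        shuffled = dict(reversed(list(vals.items())))
        e1 = parameter_effect(
            make_ratios(vals), make_meta(levels), "kit", "a", "S1", n_boot=500, seed=7
        )
        e2 = parameter_effect(
            make_ratios(shuffled), make_meta(levels), "kit", "a", "S1", n_boot=500, seed=7
        )
        assert e1.effect_log2 == e2.effect_log2
        assert (e1.ci_low, e1.ci_high) == (e2.ci_low, e2.ci_high)

    def test_weighted_mean_constraint_across_levels(self):
        """n_a * mean_a + n_b * mean_b = N * overall mean, on the ratio scale."""
        rng = np.random.default_rng(4)
        vals = {f"L{i}": float(v) for i, v in enumerate(rng.lognormal(0, 0.4, 12))}
        levels = {f"L{i}": "a" if i < 5 else "b" for i in range(12)}
        ratios, meta = make_ratios(vals), make_meta(levels)
        overall = np.mean(list(vals.values()))
        total = 0.0
        for level, n in (("a", 5), ("b", 7)):
            est = parameter_effect(ratios, meta, "kit", level, "S1", n_boot=0, ci_method="t")
            total += n * (2.0**est.effect_log2) * overall
        assert np.isclose(total, 12 * overall)

    def test_geometric_mean_scale_option(self):
        ratios = make_ratios({"L1": 1.0, "L2": 4.0, "L3": 1.0, "L4": 1.0})
        meta = make_meta({"L1": "a", "L2": "a", "L3": "b", "L4": "b"})
        est = parameter_effect(
            ratios, meta, "kit", "a", "S1", n_boot=200, seed=0, mean_scale="geometric"
        )
        gm_group = np.sqrt(1.0 * 4.0)
        gm_all = (1 * 4 * 1 * 1) ** 0.25
        assert np.isclose(est.effect_log2, np.log2(gm_group / gm_all))

    def test_bootstrap_ci_coverage_of_injected_effect(self):
        """Percentile CIs cover the mean-scale injected effect >= 95% of the time."""
        injected = 1.0
        analog = np.log2(2.0 / 1.5)  # mean-scale effect of a +1 log2 group shift
        rng = np.random.default_rng(2024)
        hits = 0
        n_rep = 300
        for _ in range(n_rep):
            noise = rng.lognormal(0.0, 0.25, 50)
            vals = {
                f"L{i}": float((2.0**injected if i < 25 else 1.0) * noise[i])
                for i in range(50)
            }
            levels = {f"L{i}": "a" if i < 25 else "b" for i in range(50)}
            est = parameter_effect(
                make_ratios(vals),
                make_meta(levels),
                "kit",
                "a",
                "S1",
                n_boot=1000,
                seed=int(rng.integers(2**31)),
            )
            if est.ci_low <= analog <= est.ci_high:
                hits += 1
        assert hits / n_rep >= 0.95


class TestLevelContrast:
    def test_contrast_is_difference_of_level_effects(self):
        vals = {"L1": 2.0, "L2": 2.2, "L3": 1.0, "L4": 0.9}
        levels = {"L1": "a", "L2": "a", "L3": "b", "L4": "b"}
        ratios, meta = make_ratios(vals), make_meta(levels)
        ea = parameter_effect(ratios, meta, "kit", "a", "S1", n_boot=0, ci_method="t")
        eb = parameter_effect(ratios, meta, "kit", "b", "S1", n_boot=0, ci_method="t")
        c = level_contrast(ratios, meta, "kit", "a", "b", "S1", n_boot=200, seed=0)
        assert np.isclose(c.effect_log2, ea.effect_log2 - eb.effect_log2)


class TestSweep:
    def test_stratum_restricts_roster(self, default_small_study):
        from interlab_mgs import aggregate, normalize, taxa_ratio

        study = default_small_study
        phy = aggregate(normalize(study.observed), "phylum")
        ratios = taxa_ratio(phy, "Firmicutes", "Bacteroidetes")
        ests = sweep(ratios, study.metadata, "S1", stratum="amplicon", n_boot=100, seed=0)
        n_amp = sum(m.strategy == "amplicon" for m in study.metadata)
        assert all(e.n_labs <= n_amp for e in ests)
        # the amplicon-only parameter appears, and no strategy pseudo-parameter
        assert any(e.parameter == "target_region" for e in ests)
        assert not any(e.parameter == "strategy" for e in ests)

    def test_all_stratum_includes_strategy_and_sign_pattern(self, default_small_study):
        """Amplicon labs biased high on the ratio: +effect for amplicon, - for shotgun."""
        from interlab_mgs import aggregate, normalize, taxa_ratio

        study = default_small_study
        phy = aggregate(normalize(study.observed), "phylum")
        ratios = taxa_ratio(phy, "Firmicutes", "Bacteroidetes")
        ests = sweep(ratios, study.metadata, "S1", stratum="all", n_boot=100, seed=0)
        by = {(e.parameter, e.level): e for e in ests}
        assert by[("strategy", "amplicon")].effect_log2 > 0
        assert by[("strategy", "shotgun")].effect_log2 < 0

    def test_single_level_parameter_has_zero_effect(self):
        ratios = make_ratios({"L1": 2.0, "L2": 3.0, "L3": 1.0})
        meta = make_meta({"L1": "only", "L2": "only", "L3": "only"})
        ests = sweep(ratios, meta, "S1", n_boot=100, seed=0)
        kit = [e for e in ests if e.parameter == "kit"][0]
        assert kit.effect_log2 == 0.0

    def test_empty_stratum_rejected(self):
        ratios = make_ratios({"L1": 2.0})
        meta = make_meta({"L1": "a"})
        with pytest.raises(ValidationError):
            sweep(ratios, meta, "S1", stratum="shotgun")

    def test_sorted_by_absolute_effect(self, default_small_study):
        from interlab_mgs import aggregate, normalize, taxa_ratio

        study = default_small_study
        phy = aggregate(normalize(study.observed), "phylum")
        ratios = taxa_ratio(phy, "Firmicutes", "Bacteroidetes")
        ests = sweep(ratios, study.metadata, "S2", n_boot=100, seed=0)
        mags = [abs(e.effect_log2) for e in ests]
        assert mags == sorted(mags, reverse=True)

    def test_recovers_single_injected_effect_as_largest(self):
        """With one nonzero injected effect, that level tops the sweep."""
        from conftest import balanced_two_level_config

        from interlab_mgs import aggregate, generate_stool_study, normalize, taxa_ratio

        from dataclasses import replace

        from interlab_mgs.synthetic_data import ParameterSpec

        cfg = balanced_two_level_config(effect=1.0, n_per_level=20, seed=13)
        cfg = replace(
            cfg,
            parameters=cfg.parameters
            + (
                ParameterSpec("homogenization", ("shaking", "none"), probabilities=(0.5, 0.5)),
                ParameterSpec("sequencer", ("illumina", "other"), probabilities=(0.8, 0.2)),
            ),
        )
        study = generate_stool_study(cfg)
        phy = aggregate(normalize(study.observed), "phylum")
        ratios = taxa_ratio(phy, "Firmicutes", "Bacteroidetes")
        ests = sweep(ratios, study.metadata, "S1", stratum="amplicon", n_boot=100, seed=0)
        # both levels of the injected parameter shift against the overall
        # mean; every null parameter's levels sit below them
        assert ests[0].parameter == "extraction_kit"
        kitx = [e for e in ests if e.level == "kitX"][0]
        null_mags = [abs(e.effect_log2) for e in ests if e.parameter != "extraction_kit"]
        assert abs(kitx.effect_log2) > max(null_mags)


class TestRobustness:
    def test_group_of_all_labs_is_one(self):
        vals = {f"L{i}": float(v) for i, v in enumerate([1.0, 2.0, 4.0, 0.5])}
        meta = make_meta({lab: "a" for lab in vals})
        out = robustness(make_ratios(vals), meta, [("kit", "a")], "S1")
        assert np.isclose(out["variability_ratio"], 1.0)

    def test_identical_group_ratios_give_zero(self):
        vals = {"L1": 2.0, "L2": 2.0, "L3": 8.0, "L4": 0.5}
        meta = make_meta({"L1": "a", "L2": "a", "L3": "b", "L4": "b"})
        out = robustness(make_ratios(vals), meta, [("kit", "a")], "S1")
        assert out["variability_ratio"] == 0.0

    def test_fewer_than_two_matches_rejected(self):
        vals = {"L1": 2.0, "L2": 1.0}
        meta = make_meta({"L1": "a", "L2": "b"})
        with pytest.raises(ValidationError):
            robustness(make_ratios(vals), meta, [("kit", "a")], "S1")

    def test_noise_halving_level_detected(self):
        """A level built with half the between-lab spread shows ratio ~ 0.5."""
        rng = np.random.default_rng(6)
        n = 200
        vals, levels = {}, {}
        for i in range(n):
            quiet = i < n // 2
            sd = 0.15 if quiet else 0.3
            vals[f"L{i}"] = float(2.0 * 2.0 ** rng.normal(0, sd))
            levels[f"L{i}"] = "quiet" if quiet else "noisy"
        out = robustness(make_ratios(vals), make_meta(levels), [("kit", "quiet")], "S1")
        # overall sd mixes both groups: sqrt((0.15^2 + 0.3^2)/2) ~ 0.237
        assert np.isclose(out["variability_ratio"], 0.15 / 0.237, atol=0.08)


class TestSignificanceScreen:
    def _est(self, parameter, level, sample, sig):
        lo, hi = (0.5, 1.5) if sig else (-0.5, 1.5)
        return EffectEstimate(
            parameter=parameter,
            level=level,
            sample=sample,
            effect_log2=1.0,
            ci_low=lo,
            ci_high=hi,
            ci=0.99,
            n_labs=5,
            variability_ratio=1.0,
            significant=sig,
        )

    def test_two_of_five_samples_retained(self):
        ests = [self._est("kit", "a", f"S{i}", sig=i in (1, 3)) for i in range(5)]
        kept = significant_across_samples(ests, min_samples=2)
        assert {(e.parameter, e.level) for e in kept} == {("kit", "a")}
        assert len(kept) == 5  # all samples of the retained level are returned

    def test_single_sample_dropped(self):
        ests = [self._est("kit", "a", f"S{i}", sig=i == 0) for i in range(5)]
        assert significant_across_samples(ests, min_samples=2) == []

    def test_null_study_retention_rate_is_low(self):
        """With no injected effects the 2-of-5 screen retains almost nothing."""
        from conftest import balanced_two_level_config

        from interlab_mgs import aggregate, generate_stool_study, normalize, taxa_ratio

        retained = 0
        n_seeds = 60
        for seed in range(n_seeds):
            cfg = balanced_two_level_config(
                effect=0.0, n_per_level=10, seed=seed, n_samples=5, depth=20_000
            )
            study = generate_stool_study(cfg)
            phy = aggregate(normalize(study.observed), "phylum")
            ratios = taxa_ratio(phy, "Firmicutes", "Bacteroidetes")
            ests = []
            for sample in study.observed.samples:
                for level in ("kitX", "kitY"):
                    ests.append(
                        parameter_effect(
                            ratios,
                            study.metadata,
                            "extraction_kit",
                            level,
                            sample,
                            n_boot=800,
                            seed=seed,
                        )
                    )
            if significant_across_samples(ests, min_samples=2):
                retained += 1
        # bounded by the marginal error of a single 99% interval plus MC slack
        assert retained / n_seeds <= 0.05

    def test_frame_export_has_tidy_columns(self):
        ests = [self._est("kit", "a", "S1", True)]
        frame = estimates_to_frame(ests)
        assert list(frame.columns) == [
            "parameter",
            "level",
            "sample",
            "effect_log2",
            "ci_low",
            "ci_high",
            "ci",
            "n_labs",
            "variability_ratio",
            "significant",
        ]
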