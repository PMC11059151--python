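"""Synthetic interlab studies with known injected effects.

Two generators mirror the two arms of a multi-lab sequencing comparison:

* :func:`generate_stool_study` — five distinct stool-like compositions
  measured by a roster of amplicon (16S) and shotgun (WGS) labs.  Each lab
  perturbs the true composition multiplicatively in log space: protocol
  choices inject known log2 effects on a designated taxa ratio (split
  +e/2 / -e/2 between the numerator and denominator phyla), a per-taxon
  lab random effect adds between-lab noise, two spike-in organisms enter
  at fixed fractions before closure, and reads are drawn multinomially.
  Because effects act before closure, downstream ratio statistics face the
  same compositional coupling as real profiles.

* :func:`generate_mock_community` — a 13-strain genomic DNA mixture,
  either equigenomic or a tenfold log-dilution series, with ddPCR-style
  lognormal replicate measurements of genome copies and per-lab observed
  profiles whose expected signal is copies x 16S copy number (amplicon)
  or copies x genome size (shotgun).

Everything is deterministic under the config seed; per-lab substreams are
keyed by a CRC of the lab ID, so enlarging the roster never perturbs
existing labs.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np

from .tables_io import (
    AbundanceTable,
    DdpcrMeasurements,
    ProtocolMetadata,
    ReferencePanel,
    ValidationError,
)

__all__ = [
    "ParameterSpec",
    "StudyConfig",
    "SyntheticStudy",
    "MockCommunity",
    "generate_stool_study",
    "generate_mock_community",
    "default_parameters",
    "default_strain_catalog",
]

# genus -> phylum catalog for the stool generator, round-robin over phyla so
# any prefix contains both ratio phyla
_GUT_CATALOG: tuple[tuple[str, str], ...] = (
    ("Blautia", "Firmicutes"),
    ("Bacteroides", "Bacteroidetes"),
    ("Faecalibacterium", "Firmicutes"),
    ("Prevotella", "Bacteroidetes"),
    ("Roseburia", "Firmicutes"),
    ("Escherichia", "Proteobacteria"),
    ("Ruminococcus", "Firmicutes"),
    ("Parabacteroides", "Bacteroidetes"),
    ("Dorea", "Firmicutes"),
    ("Bifidobacterium", "Actinobacteria"),
    ("Coprococcus", "Firmicutes"),
    ("Alistipes", "Bacteroidetes"),
    ("Lachnospira", "Firmicutes"),
    ("Akkermansia", "Verrucomicrobia"),
    ("Oscillibacter", "Firmicutes"),
    ("Odoribacter", "Bacteroidetes"),
    ("Clostridium", "Firmicutes"),
    ("Sutterella", "Proteobacteria"),
    ("Streptococcus", "Firmicutes"),
    ("Butyricimonas", "Bacteroidetes"),
    ("Lactobacillus", "Firmicutes"),
    ("Collinsella", "Actinobacteria"),
    ("Veillonella", "Firmicutes"),
    ("Barnesiella", "Bacteroidetes"),
    ("Dialister", "Firmicutes"),
    ("Bilophila", "Proteobacteria"),
    ("Anaerostipes", "Firmicutes"),
    ("Eggerthella", "Actinobacteria"),
)

#: Spike-in organisms: an exogenous Gram-negative and Gram-positive pair.
SPIKEIN_A = ("Aliivibrio", "Proteobacteria")  # A. fischeri
SPIKEIN_B = ("Leifsonia", "Actinobacteria")  # L. xyli


def _lineage(genus: str, phylum: str) -> str:
    return f"k__Bacteria;p__{phylum};g__{genus}"


@dataclass(frozen=True)
class ParameterSpec:
    """One questionnaire parameter: its levels, prevalences and injected effects.

    ``effects`` maps level -> log2 effect on the designated taxa ratio.
    A parameter named ``strategy`` is special: its level is the lab's
    sequencing strategy rather than sampled.  ``balanced=True`` assigns
    levels round-robin instead of randomly (for controlled experiments).
    """

    name: str
    levels: tuple[str, ...]
    effects: dict = field(default_factory=dict)
    applies_to: str = "both"  # amplicon | shotgun | both
    probabilities: tuple[float, ...] | None = None
    balanced: bool = False

    def __post_init__(self) -> None:
        if self.applies_to not in ("amplicon", "shotgun", "both"):
            raise ValidationError(
                f"parameter {self.name!r}: applies_to must name at least one "
                f"strategy (amplicon|shotgun|both), got {self.applies_to!r}"
            )
        if len(self.levels) < 1:
            raise ValidationError(f"parameter {self.name!r} has no levels")
        if self.probabilities is not None:
            if len(self.probabilities) != len(self.levels):
                raise ValidationError(
                    f"parameter {self.name!r}: probabilities/levels length mismatch"
                )
            if abs(sum(self.probabilities) - 1.0) > 1e-9:
                raise ValidationError(
                    f"parameter {self.name!r}: probabilities must sum to 1"
                )
        unknown = set(self.effects) - set(self.levels)
        if unknown:
            raise ValidationError(
                f"parameter {self.name!r}: effects for unknown levels {unknown}"
            )

    def applies(self, strategy: str) -> bool:
        return self.applies_to in ("both", strategy)


def default_parameters() -> tuple[ParameterSpec, ...]:
    """Default protocol parameters emulating the dominant study effects.

    The amplicon-vs-shotgun choice carries a 2.0 log2 contrast on the
    Firmicutes:Bacteroidetes ratio (16S labs high, WGS labs low); the
    remaining parameters are null by default.
    """
    return (
        ParameterSpec(
            "strategy",
            ("amplicon", "shotgun"),
            effects={"amplicon": 1.0, "shotgun": -1.0},
        ),
        ParameterSpec(
            "extraction_kit", ("kitA", "kitB", "kitC"), probabilities=(0.5, 0.3, 0.2)
        ),
        ParameterSpec(
            "target_region",
            ("V3V4", "V4"),
            applies_to="amplicon",
            probabilities=(0.6, 0.4),
        ),
        ParameterSpec(
            "homogenization",
            ("shaking", "homogenizer", "both", "none"),
            probabilities=(0.35, 0.25, 0.2, 0.2),
        ),
    )


@dataclass
class StudyConfig:
    """Design of a synthetic stool interlab study (defaults = study scale)."""

    n_samples: int = 5
    n_taxa: int = 28
    n_labs_amplicon: int = 30
    n_labs_shotgun: int = 14
    parameters: tuple[ParameterSpec, ...] = field(default_factory=default_parameters)
    lab_noise_sd: float = 0.3  # log2 units, per taxon
    depth: int = 100_000
    spikein_fractions: tuple[float, float] = (0.010, 0.005)
    ratio_numerator: str = "Firmicutes"  # phylum of the measurand's numerator
    ratio_denominator: str = "Bacteroidetes"
    amplicon_detects_spikein_b: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.spikein_fractions, (int, float)):
            self.spikein_fractions = (float(self.spikein_fractions),) * 2
        fa, fb = self.spikein_fractions
        if not (0 <= fa < 0.5 and 0 <= fb < 0.5 and fa + fb < 0.5):
            raise ValidationError("spikein fractions must lie in [0, 0.5) and sum < 0.5")
        if self.depth < 1:
            raise ValidationError("depth must be >= 1")
        if self.n_taxa < 2:
            raise ValidationError("need >= 2 community taxa")
        if self.n_samples < 1:
            raise ValidationError("need >= 1 sample")
        names = [p.name for p in self.parameters]
        if len(names) != len(set(names)):
            raise ValidationError("duplicate parameter names")


@dataclass
class SyntheticStudy:
    """A generated study: truth, per-lab observations, metadata, and the key."""

    truth: AbundanceTable  # lab_id "truth", relative, spike-ins included
    observed: AbundanceTable  # counts per (lab, sample)
    metadata: list[ProtocolMetadata]
    injected_effects: dict  # (parameter, level) -> log2 effect on the ratio
    config: StudyConfig
    seed: int


def _taxon_roster(n_taxa: int) -> list[tuple[str, str]]:
    roster = list(_GUT_CATALOG)
    phyla = ("Firmicutes", "Bacteroidetes", "Proteobacteria", "Actinobacteria")
    k = 0
    while len(roster) < n_taxa:
        roster.append((f"Genus{k:03d}", phyla[k % len(phyla)]))
        k += 1
    return roster[:n_taxa]


def _lab_rng(seed: int, lab: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), zlib.crc32(lab.encode())])
    )


def generate_stool_study(config: StudyConfig) -> SyntheticStudy:
    """Generate truth compositions, per-lab counts and metadata."""
    roster = _taxon_roster(config.n_taxa)
    phylum_of = dict(roster)
    taxa_strings = [_lineage(g, p) for g, p in roster]
    taxa_strings += [_lineage(*SPIKEIN_A), _lineage(*SPIKEIN_B)]
    n_comm = config.n_taxa
    fa, fb = config.spikein_fractions

    # ratio-direction vector: +1 numerator phylum, -1 denominator phylum
    direction = np.array(
        [
            1.0
            if phylum_of[g] == config.ratio_numerator
            else (-1.0 if phylum_of[g] == config.ratio_denominator else 0.0)
            for g, _ in roster
        ]
    )
    if not (direction > 0).any() or not (direction < 0).any():
        raise ValidationError(
            "roster lacks taxa in the designated numerator or denominator phylum"
        )

    # --- sample truths: skewed Dirichlet with per-sample permuted template
    rng_truth = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    base = 0.8 ** np.arange(n_comm)
    samples = [f"S{i + 1}" for i in range(config.n_samples)]
    truth_comm = np.empty((config.n_samples, n_comm))
    for s in range(config.n_samples):
        template = base[rng_truth.permutation(n_comm)]
        alpha = 0.5 * n_comm * template / template.sum()
        truth_comm[s] = rng_truth.dirichlet(alpha)
    truth_full = np.hstack(
        [
            (1.0 - fa - fb) * truth_comm,
            np.full((config.n_samples, 1), fa),
            np.full((config.n_samples, 1), fb),
        ]
    )

    truth = AbundanceTable.from_arrays(
        ["truth"], samples, taxa_strings, truth_full[None, :, :], units="relative"
    )

    # --- labs
    labs = [f"amp{i + 1:03d}" for i in range(config.n_labs_amplicon)]
    labs += [f"wgs{i + 1:03d}" for i in range(config.n_labs_shotgun)]
    strategies = ["amplicon"] * config.n_labs_amplicon + [
        "shotgun"
    ] * config.n_labs_shotgun

    # round-robin counters for balanced parameters, per stratum
    rr_count: dict[tuple[str, str], int] = {}

    observed = np.empty((len(labs), config.n_samples, n_comm + 2))
    metadata: list[ProtocolMetadata] = []
    for li, (lab, strategy) in enumerate(zip(labs, strategies)):
        rng = _lab_rng(config.seed, lab)
        answers: dict[str, str] = {}
        total_effect = 0.0
        for p in sorted(config.parameters, key=lambda p: p.name):
            if not p.applies(strategy):
                continue
            if p.name == "strategy":
                level = strategy
            elif p.balanced:
                key = (p.name, p.applies_to)
                k = rr_count.get(key, 0)
                rr_count[key] = k + 1
                level = p.levels[k % len(p.levels)]
            else:
                probs = p.probabilities
                level = str(rng.choice(list(p.levels), p=probs))
            if p.name != "strategy":
                answers[p.name] = level
            total_effect += float(p.effects.get(level, 0.0))

        lab_effect = rng.normal(0.0, config.lab_noise_sd, size=n_comm)
        log2_shift = 0.5 * total_effect * direction + lab_effect

        spike = np.array([fa, fb])
        if strategy == "amplicon" and not config.amplicon_detects_spikein_b:
            spike = np.array([fa, 0.0])
        for s in range(config.n_samples):
            perturbed = truth_comm[s] * np.exp2(log2_shift)
            perturbed /= perturbed.sum()
            comp = np.concatenate([(1.0 - spike.sum()) * perturbed, spike])
            observed[li, s] = rng.multinomial(config.depth, comp)

        metadata.append(
            ProtocolMetadata(lab=lab, strategy=strategy, answers=answers, complete=True)
        )

    observed_table = AbundanceTable.from_arrays(
        labs, samples, taxa_strings, observed, units="counts"
    )
    injected = {
        (p.name, level): float(p.effects.get(level, 0.0))
        for p in config.parameters
        for level in p.levels
    }
    return SyntheticStudy(
        truth=truth,
        observed=observed_table,
        metadata=metadata,
        injected_effects=injected,
        config=config,
        seed=config.seed,
    )


# ---------------------------------------------------------------------------
# mock communities


#: 13-strain DNA-mixture catalog: (strain, genus, genome size bp, 16S copies)
def default_strain_catalog() -> tuple[tuple[str, str, float, int], ...]:
    return (
        ("Staphylococcus_aureus_A", "Staphylococcus", 2.8e6, 5),
        ("Staphylococcus_aureus_B", "Staphylococcus", 2.8e6, 5),
        ("Pseudomonas_aeruginosa", "Pseudomonas", 6.3e6, 4),
        ("Enterococcus_faecalis", "Enterococcus", 2.9e6, 4),
        ("Salmonella_enterica_A", "Salmonella", 4.9e6, 7),
        ("Salmonella_enterica_B", "Salmonella", 4.9e6, 7),
        ("Escherichia_coli", "Escherichia", 5.5e6, 7),
        ("Staphylococcus_epidermidis", "Staphylococcus", 2.5e6, 5),
        ("Klebsiella_pneumoniae", "Klebsiella", 5.3e6, 8),
        ("Shigella_sonnei", "Shigella", 4.8e6, 7),
        ("Streptococcus_pyogenes", "Streptococcus", 1.85e6, 6),
        ("Corynebacterium_amycolatum", "Corynebacterium", 2.5e6, 3),
        ("Achromobacter_xylosoxidans", "Achromobacter", 6.7e6, 7),
    )


#: Genera with a validated copy-number assay (taxonomically unique at genus level).
DEFAULT_DDPCR_GENERA = ("Enterococcus", "Klebsiella", "Pseudomonas", "Streptococcus")


@dataclass
class MockCommunity:
    """A generated DNA mixture with ground truth and per-lab observations."""

    design: str  # "equigenomic" | "log_dilution"
    sample_id: str
    true_copies: dict  # strain -> genome copies / uL
    true_copies_genus: dict  # genus -> summed copies
    ddpcr: DdpcrMeasurements  # per assayed genus
    observed: AbundanceTable  # genus-level counts per lab
    metadata: list[ProtocolMetadata]
    panel: ReferencePanel  # per strain
    genus_panel: ReferencePanel  # genus-unique subset, keyed by genus
    seed: int


def generate_mock_community(
    design: str,
    n_taxa: int = 13,
    panel: ReferencePanel | None = None,
    seed: int = 0,
    genus_of: dict | None = None,
    n_labs_amplicon: int = 22,
    n_labs_shotgun: int = 14,
    n_replicates: int = 6,
    ddpcr_cv: float = 0.05,
    ddpcr_genera: tuple[str, ...] | None = None,
    lab_noise_sd: float = 0.1,
    depth: int = 100_000,
    base_copies: float = 2500.0,
) -> MockCommunity:
    """Generate one DNA mixture with ddPCR ground truth and lab profiles.

    ``design="equigenomic"`` puts every strain at ``base_copies``;
    ``"log_dilution"`` cycles strains through tenfold tiers spanning three
    orders of magnitude.  ddPCR replicates are lognormal around the true
    genome copies with coefficient of variation ``ddpcr_cv`` (mean exactly
    the truth; CV 0 reproduces the truth).  Expected lab signal is
    copies x 16S copy number for amplicon labs and copies x genome size
    for shotgun labs, times per-strain lab noise, closed and sampled
    multinomially at ``depth``.
    """
    if design not in ("equigenomic", "log_dilution"):
        raise ValidationError(f"design must be equigenomic|log_dilution, got {design!r}")
    if n_taxa < 2:
        raise ValidationError("mock community needs >= 2 taxa")

    if panel is None:
        catalog = default_strain_catalog()
        k = 0
        while len(catalog) < n_taxa:
            catalog += ((f"Strain{k:03d}", f"Genus{k:03d}", 2.0e6 + 3.0e5 * k, (k % 7) + 1),)
            k += 1
        catalog = catalog[:n_taxa]
        strains = [c[0] for c in catalog]
        genus_of = {c[0]: c[1] for c in catalog}
        panel = ReferencePanel(
            genome_size={c[0]: c[2] for c in catalog},
            ssu_copy_number={c[0]: c[3] for c in catalog},
        )
    else:
        strains = panel.taxa
        if len(strains) < n_taxa:
            raise ValidationError("reference panel does not cover all requested taxa")
        strains = strains[:n_taxa]
        panel = panel.subset(strains)
        if genus_of is None:
            genus_of = {s: s for s in strains}

    rng = np.random.default_rng(np.random.SeedSequence([int(seed), zlib.crc32(design.encode())]))

    # --- true genome copies
    if design == "equigenomic":
        copies = {s: base_copies for s in strains}
    else:
        tiers = 4  # tenfold steps spanning 3 orders of magnitude
        copies = {s: base_copies * 10.0 ** (i % tiers) for i, s in enumerate(strains)}

    genera = sorted({genus_of[s] for s in strains})
    copies_genus = {
        g: sum(copies[s] for s in strains if genus_of[s] == g) for g in genera
    }

    # --- ddPCR replicates for the assayed, genus-unique taxa
    if ddpcr_genera is None:
        ddpcr_genera = tuple(g for g in DEFAULT_DDPCR_GENERA if g in genera) or tuple(
            g for g in genera if sum(genus_of[s] == g for s in strains) == 1
        )
    sigma = np.sqrt(np.log1p(ddpcr_cv**2))
    replicates = {}
    for g in ddpcr_genera:
        if g not in copies_genus:
            raise ValidationError(f"ddPCR genus {g!r} not in the mixture")
        mu = np.log(copies_genus[g]) - sigma**2 / 2.0
        replicates[g] = (
            np.full(n_replicates, copies_genus[g])
            if ddpcr_cv == 0
            else np.exp(rng.normal(mu, sigma, size=n_replicates))
        )
    ddpcr = DdpcrMeasurements(replicates=replicates)

    genus_unique = [g for g in genera if sum(genus_of[s] == g for s in strains) == 1]
    strain_of = {genus_of[s]: s for s in strains if genus_of[s] in genus_unique}
    genus_panel = ReferencePanel(
        genome_size={g: panel.genome_size[strain_of[g]] for g in genus_unique},
        ssu_copy_number={g: panel.ssu_copy_number[strain_of[g]] for g in genus_unique},
    )

    # --- per-lab observed genus-level profiles
    sample_id = {"equigenomic": "mix_a", "log_dilution": "mix_b"}[design]
    labs = [f"amp{i + 1:03d}" for i in range(n_labs_amplicon)]
    labs += [f"wgs{i + 1:03d}" for i in range(n_labs_shotgun)]
    strategies = ["amplicon"] * n_labs_amplicon + ["shotgun"] * n_labs_shotgun

    copy_vec = np.array([copies[s] for s in strains])
    ssu_vec = np.array([panel.ssu_copy_number[s] for s in strains], dtype=float)
    size_vec = np.array([panel.genome_size[s] for s in strains], dtype=float)
    genus_idx = {g: i for i, g in enumerate(genera)}
    strain_to_genus = np.array([genus_idx[genus_of[s]] for s in strains])

    observed = np.empty((len(labs), 1, len(genera)))
    metadata = []
    for li, (lab, strategy) in enumerate(zip(labs, strategies)):
        lrng = _lab_rng(seed, f"{design}:{lab}")
        scale = ssu_vec if strategy == "amplicon" else size_vec
        signal = copy_vec * scale * np.exp2(lrng.normal(0.0, lab_noise_sd, len(strains)))
        comp = signal / signal.sum()
        counts = lrng.multinomial(depth, comp)
        by_genus = np.zeros(len(genera))
        np.add.at(by_genus, strain_to_genus, counts)
        observed[li, 0] = by_genus
        metadata.append(ProtocolMetadata(lab=lab, strategy=strategy, complete=True))

    observed_table = AbundanceTable.from_arrays(
        labs,
        [sample_id],
        [f"g__{g}" for g in genera],
        observed,
        units="counts",
    )
    return MockCommunity(
        design=design,
        sample_id=sample_id,
        true_copies=copies,
        true_copies_genus=copies_genus,
        ddpcr=ddpcr,
        observed=observed_table,
        metadata=metadata,
        panel=panel,
        genus_panel=genus_panel,
        seed=seed,
    )
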