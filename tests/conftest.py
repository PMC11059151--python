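import numpy as np
import pytest

from interlab_mgs import AbundanceTable, ProtocolMetadata
from interlab_mgs.synthetic_data import ParameterSpec, StudyConfig, generate_stool_study


@pytest.fixture
def tiny_counts():
    """2 labs x 2 samples x 3 taxa counts table."""
    values = np.array(
        [
            [[10, 20, 70], [30, 30, 40]],
            [[5, 5, 90], [25, 25, 50]],
        ],
        dtype=float,
    )
    return AbundanceTable.from_arrays(
        labs=["labA", "labB"],
        samples=["S1", "S2"],
        taxa=[
            "k__Bacteria;p__Firmicutes;g__Blautia",
            "k__Bacteria;p__Firmicutes;g__Roseburia",
            "k__Bacteria;p__Bacteroidetes;g__Bacteroides",
        ],
        values=values,
        units="counts",
    )


@pytest.fixture
def small_metadata():
    return [
        ProtocolMetadata("labA", "16S", answers={"kit": "x"}),
        ProtocolMetadata("labB", "WGS", answers={"kit": "y"}),
    ]


@pytest.fixture(scope="session")
def default_small_study():
    """A modest study with the default parameter effects, reused read-only."""
    cfg = StudyConfig(
        n_labs_amplicon=10,
        n_labs_shotgun=6,
        n_samples=3,
        depth=30_000,
        seed=11,
    )
    return generate_stool_study(cfg)


def balanced_two_level_config(
    effect: float,
    n_per_level: int = 25,
    seed: int = 0,
    n_samples: int = 1,
    lab_noise_sd: float = 0.3,
    depth: int = 100_000,
) -> StudyConfig:
    """Two-level single-parameter design used by the recovery/null studies."""
    return StudyConfig(
        n_samples=n_samples,
        n_labs_amplicon=2 * n_per_level,
        n_labs_shotgun=0,
        parameters=(
            ParameterSpec(
                "extraction_kit",
                ("kitX", "kitY"),
                effects={"kitX": effect},
                balanced=True,
            ),
        ),
        lab_noise_sd=lab_noise_sd,
        depth=depth,
        seed=seed,
    )
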