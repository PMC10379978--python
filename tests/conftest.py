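import hypothesis
import pandas as pd
import pytest

from haplodyn.ase_bias import BIAS_A, NO_BIAS, classify_trajectory
from haplodyn.synthetic_data import REFERENCE_CATEGORY_COUNTS, SimConfig, simulate

hypothesis.settings.register_profile(
    "ci", deadline=None, derandomize=True, max_examples=60
)
hypothesis.settings.load_profile("ci")


def category_fixture_trajectories() -> pd.DataFrame:
    """Per-gene status triplets whose category multiplicities equal the
    reference bias-dynamics table, classified through the package."""
    rows = []
    g = 0
    for time_h, counts in REFERENCE_CATEGORY_COUNTS.items():
        for cat, n in counts.items():
            letters = "BBB" if cat == "CCC" else cat
            statuses = [BIAS_A if ch == "B" else NO_BIAS for ch in letters]
            for _ in range(n):
                category, resp = classify_trajectory(*statuses)
                rows.append((f"g{g:06d}", time_h, *statuses, category, resp))
                g += 1
    return pd.DataFrame(
        rows,
        columns=[
            "gene_id",
            "time_h",
            "status_control",
            "status_nacl",
            "status_peg",
            "category",
            "responsiveness",
        ],
    )


@pytest.fixture(scope="session")
def table1_trajectories() -> pd.DataFrame:
    return category_fixture_trajectories()


@pytest.fixture(scope="session")
def small_sim():
    """A modest simulated experiment shared across read-only tests."""
    return simulate(SimConfig(n_genes=400, seed=2024, pi_bias=0.3, pi_de=0.1))
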