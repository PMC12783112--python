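import numpy as np
import pandas as pd
import pytest

from gbsmap.config import SimulationConfig
from gbsmap import synthetic


@pytest.fixture
def small_cfg() -> SimulationConfig:
    """A small but complete cross: 3 chromosomes, 8 markers each."""
    return SimulationConfig(
        n_progeny=30, n_chromosomes=3, markers_per_chromosome=8,
        qtl_marker_id="Chr03_M02", random_seed=42,
    )


@pytest.fixture
def small_cross(small_cfg):
    rng = np.random.default_rng(small_cfg.random_seed)
    marker_map = synthetic.build_marker_map(small_cfg, rng)
    geno = synthetic.simulate_cross(marker_map, small_cfg, rng)
    return marker_map, geno


def two_marker_map(d_cm: float, parent1_het: bool = True) -> synthetic.MarkerMap:
    """Two linked markers at map distance d_cm on one chromosome."""
    pos2 = 1_000 + int(d_cm / 4.0 * 1e6) + 1  # 4 cM/Mb
    p1 = "A/G" if parent1_het else "A/A"
    table = pd.DataFrame({
        "marker_id": ["m1", "m2"],
        "chrom": ["Chr01", "Chr01"],
        "pos_bp": [1_000, pos2],
        "pos_cM": [0.0, d_cm],
        "parent1_gt": [p1, p1],
        "parent2_gt": ["A/A", "A/A"],
    })
    return synthetic.MarkerMap(table)
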