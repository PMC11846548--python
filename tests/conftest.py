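import numpy as np
import pytest

from equicast.panel import Panel, RegionYearRecord, Stratum, write_panel
from equicast.synthetic import SyntheticConfig, generate_panel


@pytest.fixture(scope="session")
def default_panel():
    """The default 11-region x 20-year synthetic panel (seed 1)."""
    return generate_panel(SyntheticConfig(seed=1))


@pytest.fixture
def panel_csv(tmp_path, default_panel):
    path = tmp_path / "panel.csv"
    write_panel(default_panel, path)
    return path


@pytest.fixture(scope="session")
def simulate_ar1():
    """AR(1) simulator: simulate_ar1(n, phi, seed, mean) -> ndarray."""

    def _sim(n: int, phi: float, seed: int, mean: float = 10.0) -> np.ndarray:
        rng = np.random.default_rng(seed)
        shocks = rng.normal(0.0, 1.0, n)
        x = np.zeros(n)
        for i in range(1, n):
            x[i] = phi * x[i - 1] + shocks[i]
        return x + mean

    return _sim


def make_record(**overrides) -> RegionYearRecord:
    base = dict(
        region_id="R1",
        year=2003,
        stratum=Stratum.WHOLE,
        population=1_000_000.0,
        area_km2=10_000.0,
        nurses=3190,
        doctors=2500,
        health_technicians=9000,
        beds=7000,
    )
    base.update(overrides)
    return RegionYearRecord(**base)


@pytest.fixture(scope="session")
def noisy_panel():
    """A 3-region panel whose nurse totals are i.i.d. noise (grey-hostile)."""
    rng = np.random.default_rng(42)
    records = []
    for r in range(3):
        for t, year in enumerate(range(2003, 2023)):
            nurses = int(rng.uniform(800, 1200))
            records.append(
                make_record(
                    region_id=f"N{r}",
                    year=year,
                    nurses=nurses,
                    health_technicians=3 * nurses,
                )
            )
    return Panel.build(records, provenance="noise fixture")


def random_share_panel(rng: np.random.Generator):
    """Random (weights, resources) pair: 2-50 regions, log-normal densities."""
    n = int(rng.integers(2, 51))
    weights = np.exp(rng.normal(0.0, 1.0, n))
    densities = np.exp(rng.normal(0.0, 1.0, n))
    resources = weights * densities
    return weights, resources
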