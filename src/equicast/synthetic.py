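"""Synthetic yearbook-like panels and exact-ground-truth fixtures.

The generator emulates the shape of a provincial statistical-yearbook
panel — a handful of regions observed yearly over two decades, with
near-exponential nurse growth, heterogeneous populations and areas, and
configurable between-region inequality in per-capita nurse density — so
every analysis stage can be exercised without external data.  Fixture
helpers produce inputs whose equity/grey statistics are known in closed
form, independent of the estimators under test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DomainError, LengthError
from .panel import Panel, RegionYearRecord, Stratum


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the panel generator.

    Defaults echo an 11-region, 2003-2022 panel with ~7.8%/yr average
    nurse growth; they make no claim of reproducing any real province.
    All scale parameters must be positive; ``seed`` is mandatory.
    """

    seed: int
    n_regions: int = 11
    start_year: int = 2003
    end_year: int = 2022
    mean_growth: float = 0.078          # mean annual nurse growth rate
    growth_sd: float = 0.008            # between-region s.d. of the rate
    density_sigma: float = 0.4          # s.d. of log per-capita nurse density
    base_density_per_1000: float = 1.0  # median nurses per 1,000 pop, year 1
    pop_median: float = 3.0e6           # median region population
    pop_sigma: float = 0.5              # s.d. of log population
    area_median: float = 1.5e4          # median region area, km^2
    area_sigma: float = 0.4             # s.d. of log area
    noise_sd: float = 0.01              # s.d. of multiplicative log-noise
    nurse_share_start: float = 0.33     # nurses / health technicians, year 1
    nurse_share_end: float = 0.50
    nurses_per_doctor_start: float = 0.70
    nurses_per_doctor_end: float = 1.27
    nurses_per_bed_start: float = 0.41
    nurses_per_bed_end: float = 0.46
    integer_counts: bool = True

    def __post_init__(self) -> None:
        if self.seed is None:
            raise DomainError("seed is mandatory")
        if self.n_regions < 1:
            raise DomainError("n_regions must be >= 1")
        if self.end_year < self.start_year:
            raise DomainError("end_year must be >= start_year")
        for name in (
            "base_density_per_1000", "pop_median", "pop_sigma",
            "area_median", "area_sigma",
            "nurse_share_start", "nurse_share_end",
            "nurses_per_doctor_start", "nurses_per_doctor_end",
            "nurses_per_bed_start", "nurses_per_bed_end",
        ):
            if getattr(self, name) <= 0:
                raise DomainError(f"{name} must be > 0")
        for name in ("growth_sd", "density_sigma", "noise_sd"):
            if getattr(self, name) < 0:
                raise DomainError(f"{name} must be >= 0")

    @property
    def years(self) -> np.ndarray:
        return np.arange(self.start_year, self.end_year + 1)


def _linear_trajectory(start: float, end: float, n: int) -> np.ndarray:
    return np.linspace(start, end, n)


def generate_panel(config: SyntheticConfig) -> Panel:
    """Generate a whole-stratum panel from ``config``, deterministically.

    Region nurse counts follow ``count_r(t) = count_r(0) * (1+g_r)**t``
    with multiplicative log-normal noise; doctors, beds and health
    technicians are derived from linearly interpolated ratio
    trajectories.  One seed drives a per-region substream, so adding a
    region does not perturb the others' draws.
    """
    n_years = len(config.years)
    streams = np.random.SeedSequence(config.seed).spawn(config.n_regions)
    share_t = _linear_trajectory(
        config.nurse_share_start, config.nurse_share_end, n_years
    )
    npd_t = _linear_trajectory(
        config.nurses_per_doctor_start, config.nurses_per_doctor_end, n_years
    )
    npb_t = _linear_trajectory(
        config.nurses_per_bed_start, config.nurses_per_bed_end, n_years
    )

    records: list[RegionYearRecord] = []
    width = len(str(config.n_regions))
    for r in range(config.n_regions):
        rng = np.random.default_rng(streams[r])
        region_id = f"R{r + 1:0{width}d}"
        population = config.pop_median * np.exp(rng.normal(0.0, config.pop_sigma))
        area = config.area_median * np.exp(rng.normal(0.0, config.area_sigma))
        density0 = config.base_density_per_1000 * np.exp(
            rng.normal(0.0, config.density_sigma)
        )
        growth = rng.normal(config.mean_growth, config.growth_sd)
        noise = (
            rng.normal(0.0, config.noise_sd, size=n_years)
            if config.noise_sd > 0
            else np.zeros(n_years)
        )
        base_nurses = population / 1000.0 * density0
        for t, year in enumerate(config.years):
            nurses = base_nurses * (1.0 + growth) ** t * np.exp(noise[t])
            doctors = nurses / npd_t[t]
            beds = nurses / npb_t[t]
            technicians = nurses / share_t[t]
            if config.integer_counts:
                nurses_i = int(round(nurses))
                doctors_i = int(round(doctors))
                beds_i = int(round(beds))
                technicians_i = max(int(round(technicians)), nurses_i)
            else:
                # exact-ground-truth mode: keep counts continuous
                nurses_i, doctors_i, beds_i, technicians_i = (
                    nurses, doctors, beds, max(technicians, nurses),
                )
            records.append(
                RegionYearRecord(
                    region_id=region_id,
                    year=int(year),
                    stratum=Stratum.WHOLE,
                    population=float(population),
                    area_km2=float(area),
                    nurses=nurses_i,
                    doctors=doctors_i,
                    health_technicians=technicians_i,
                    beds=beds_i,
                )
            )
    return Panel.build(
        records,
        provenance=f"synthetic(seed={config.seed}, n_regions={config.n_regions})",
        strict=True,
    )


def make_two_point_fixture(
    w: float, s: float
) -> tuple[list[tuple[float, float]], float]:
    """Two aggregate regions with an exactly known Gini coefficient.

    The poorer region holds basis share ``w`` and resource share
    ``s <= w``, so the Lorenz curve is the polyline (0,0)-(w,s)-(1,1)
    and the Gini coefficient is ``w - s`` exactly (trapezoid geometry).

    Returns ``(regions, expected_gini)`` where ``regions`` is a list of
    (basis_weight, resource) pairs ready for :func:`equity.build_lorenz`.
    """
    if not 0.0 < w < 1.0:
        raise DomainError(f"w must lie in (0, 1), got {w}")
    if not 0.0 <= s <= w:
        raise DomainError(
            f"s must lie in [0, w]; got s={s}, w={w} "
            "(regions must sort ascending by density)"
        )
    regions = [(w, s), (1.0 - w, 1.0 - s)]
    return regions, w - s


def make_grey_consistent_series(
    a: float, u: float, x1_init: float, n: int, alpha: float = 0.5
) -> np.ndarray:
    """Series exactly satisfying the grey difference equation.

    Inverts ``x0(k) + a * z1(k) = u`` (background coefficient ``alpha``)
    from ``x0(1) = x1_init`` forward, so ``fit_gm11`` must recover
    ``(a, u)`` to machine precision and fit with zero residual.

    Raises
    ------
    DomainError
        if ``|a| <= 1e-8``, or the parameters produce a non-positive
        value anywhere in the series.
    LengthError
        if ``n < 4``.
    """
    if n < 4:
        raise LengthError(f"need n >= 4, got {n}")
    if abs(a) <= 1e-8:
        raise DomainError("a is numerically zero; grey equation degenerate")
    if x1_init <= 0:
        raise DomainError("x1_init must be > 0")
    denom = 1.0 + alpha * a
    if denom == 0:
        raise DomainError("1 + alpha*a must be nonzero")
    beta = (1.0 - (1.0 - alpha) * a) / denom
    gamma = u / denom
    x1 = np.empty(n)
    x1[0] = x1_init
    for k in range(1, n):
        x1[k] = beta * x1[k - 1] + gamma
    x0 = np.diff(x1, prepend=0.0)
    x0[0] = x1_init
    if np.any(x0 <= 0):
        raise DomainError(
            "parameter combination produces non-positive values; "
            "pick smaller |a| or larger u/x1_init"
        )
    return x0


def make_noise_series(
    n: int = 20, seed: int = 0, low: float = 80.0, high: float = 120.0
) -> np.ndarray:
    """I.i.d. positive noise with no trend (a deliberately grey-hostile
    series: GM(1,1) fits it badly and should grade 3-4)."""
    if n < 4:
        raise LengthError(f"need n >= 4, got {n}")
    if not 0 < low < high:
        raise DomainError("need 0 < low < high")
    rng = np.random.default_rng(seed)
    return rng.uniform(low, high, size=n)
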