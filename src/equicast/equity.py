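"""Lorenz curves, Gini coefficients and Theil-index decomposition.

Two independent Gini routes are provided on purpose:

* :func:`gini_summation` — the rank-based share summation
  ``G = 1 - sum_i W_i * (2 V_i - Y_i)`` over regions sorted ascending by
  per-basis density, with ``W_i`` the basis (population or area) share,
  ``Y_i`` the resource share and ``V_i`` the cumulative resource share.
* :func:`gini_trapezoid` — ``G = 1 - 2B`` with ``B`` the trapezoid area
  under the Lorenz polyline.

They are algebraically identical (``2 V_i - Y_i = V_i + V_{i-1}``) and
each serves as the oracle for the other in the test suite.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

import numpy as np

from .errors import DegenerateInputError, DomainError, GroupingError

__all__ = [
    "Basis",
    "FairnessLabel",
    "LorenzCurve",
    "GiniResult",
    "TheilResult",
    "build_lorenz",
    "gini_summation",
    "gini_trapezoid",
    "classify_gini",
    "theil_total",
    "theil_decompose",
    "lorenz_from_panel",
    "gini_for_year",
]


class Basis(str, Enum):
    """What the cumulative X-axis of a Lorenz curve measures."""

    POPULATION = "population"
    AREA = "area"


class FairnessLabel(str, Enum):
    ABSOLUTE_FAIRNESS = "absolute_fairness"
    MODERATE_FAIRNESS = "moderate_fairness"
    RELATIVE_FAIRNESS = "relative_fairness"
    INEQUALITY_WARNING = "inequality_warning"
    HIGH_INEQUALITY = "high_inequality"


@dataclass(frozen=True)
class LorenzCurve:
    """Ordered cumulative-share points from (0,0) to (1,1).

    ``points`` is an ``(n+1, 2)`` array; column 0 is the cumulative basis
    share, column 1 the cumulative resource share.  Regions are sorted
    ascending by resource density, so the curve is convex and lies on or
    below the diagonal.
    """

    basis: Basis
    points: np.ndarray
    region_order: tuple[str, ...]

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        object.__setattr__(self, "points", pts)
        if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 2:
            raise DomainError("Lorenz curve needs an (m, 2) array with m >= 2")
        if not (np.allclose(pts[0], [0.0, 0.0]) and np.allclose(pts[-1], [1.0, 1.0])):
            raise DomainError("Lorenz curve must run from (0,0) to (1,1)")
        if np.any(np.diff(pts[:, 0]) < -1e-12) or np.any(np.diff(pts[:, 1]) < -1e-12):
            raise DomainError("Lorenz curve coordinates must be non-decreasing")

    @property
    def basis_shares(self) -> np.ndarray:
        """W_i: per-region basis shares (differences of the X column)."""
        return np.diff(self.points[:, 0])

    @property
    def resource_shares(self) -> np.ndarray:
        """Y_i: per-region resource shares (differences of the Y column)."""
        return np.diff(self.points[:, 1])

    @property
    def cumulative_resource_shares(self) -> np.ndarray:
        """V_i: cumulative resource shares (Y column, excluding the origin)."""
        return self.points[1:, 1]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            self.points, columns=["cum_basis_share", "cum_resource_share"]
        )


@dataclass(frozen=True)
class GiniResult:
    value: float
    basis: Basis
    fairness_label: FairnessLabel
    year: int | None = None


@dataclass(frozen=True)
class TheilResult:
    """Total Theil index with its within/between-group decomposition.

    ``total == within + between`` to 1e-12.  Contribution rates are None
    when ``total == 0`` (perfect equality; rates are undefined).
    ``per_group`` lists (group label, group resource share, group Theil).
    """

    total: float
    within: float
    between: float
    contribution_within: float | None
    contribution_between: float | None
    per_group: tuple[tuple[str, float, float], ...]


def build_lorenz(
    regions: Sequence[tuple[float, float]],
    basis: Basis | str = Basis.POPULATION,
    labels: Sequence[str] | None = None,
) -> LorenzCurve:
    """Build a Lorenz curve from (basis_weight, resource) pairs.

    Regions are sorted ascending by density ``resource / basis_weight``
    (ties broken by label, so results are reproducible), cumulative
    shares are computed, and the origin (0,0) is prepended.

    Raises
    ------
    DomainError
        for fewer than 2 regions, non-positive weights or negative
        resources.
    DegenerateInputError
        when the total resource is zero.
    """
    basis = Basis(basis)
    weights = np.asarray([r[0] for r in regions], dtype=float)
    resources = np.asarray([r[1] for r in regions], dtype=float)
    n = len(weights)
    if n < 2:
        raise DomainError(f"need at least 2 regions, got {n}")
    if np.any(weights <= 0):
        raise DomainError("all basis weights must be strictly positive")
    if np.any(resources < 0):
        raise DomainError("resources must be non-negative")
    if resources.sum() <= 0:
        raise DegenerateInputError("total resource is zero; Lorenz curve undefined")
    if labels is None:
        labels = [f"region_{i}" for i in range(n)]
    labels = [str(x) for x in labels]
    if len(labels) != n:
        raise DomainError("labels must match regions in length")

    density = resources / weights
    order = sorted(range(n), key=lambda i: (density[i], labels[i]))
    w = weights[order] / weights.sum()
    y = resources[order] / resources.sum()
    points = np.zeros((n + 1, 2))
    points[1:, 0] = np.cumsum(w)
    points[1:, 1] = np.cumsum(y)
    points[-1] = [1.0, 1.0]  # kill accumulated rounding at the endpoint
    return LorenzCurve(
        basis=basis, points=points, region_order=tuple(labels[i] for i in order)
    )


def gini_summation(curve: LorenzCurve) -> float:
    """Gini coefficient via the ranked share summation.

    ``G = 1 - sum_i W_i (2 V_i - Y_i)`` with regions already ranked
    ascending by density inside ``curve``.
    """
    w = curve.basis_shares
    y = curve.resource_shares
    v = curve.cumulative_resource_shares
    g = 1.0 - float(np.sum(w * (2.0 * v - y)))
    return max(g, 0.0)


def gini_trapezoid(curve: LorenzCurve) -> float:
    """Gini coefficient as A/(A+B) with B by trapezoid integration.

    A is the area between the diagonal and the Lorenz polyline, B the
    area under the polyline; A + B = 1/2, hence ``G = 1 - 2B``.
    Independent oracle for :func:`gini_summation`.
    """
    x = curve.points[:, 0]
    y = curve.points[:, 1]
    b_area = float(np.trapezoid(y, x))
    return max(1.0 - 2.0 * b_area, 0.0)


#: Fairness bands: left-closed, right-open up to 0.4; [0.4, 0.6] is the
#: inequality warning band and (0.6, 1) high inequality, so the bands
#: cover [0, 1) without overlap.
_GINI_BANDS = (
    (0.2, FairnessLabel.ABSOLUTE_FAIRNESS),
    (0.3, FairnessLabel.MODERATE_FAIRNESS),
    (0.4, FairnessLabel.RELATIVE_FAIRNESS),
)


def classify_gini(value: float) -> FairnessLabel:
    """Map a Gini coefficient to its fairness band.

    Bands: [0, 0.2) absolute fairness, [0.2, 0.3) moderate, [0.3, 0.4)
    relative, [0.4, 0.6] inequality warning, (0.6, 1) high inequality.
    """
    if not (0.0 <= value < 1.0):
        raise DomainError(f"Gini coefficient must lie in [0, 1), got {value}")
    for upper, label in _GINI_BANDS:
        if value < upper:
            return label
    if value <= 0.6:
        return FairnessLabel.INEQUALITY_WARNING
    return FairnessLabel.HIGH_INEQUALITY


def _theil_terms(counts: np.ndarray, mean: float) -> np.ndarray:
    """Per-region (y/mean) ln(y/mean) terms with the 0 ln 0 -> 0 convention."""
    ratio = counts / mean
    terms = np.zeros_like(ratio)
    positive = ratio > 0
    terms[positive] = ratio[positive] * np.log(ratio[positive])
    return terms


def theil_total(counts: Iterable[float], weights: Iterable[float] | None = None) -> float:
    """Theil index over per-region counts.

    Default is the unweighted city-count form
    ``T = (1/n) sum_i (Y_i / ybar) ln(Y_i / ybar)`` with ``ybar`` the
    mean count; zero-count regions contribute 0 (limit convention).
    Passing ``weights`` (e.g. populations) switches to the weighted form
    ``T = sum_i s_i ln((Y_i/ybar_w) )`` generalisation where region i
    carries weight share ``w_i`` and ``ybar_w`` is the weighted mean —
    off by default.

    Raises
    ------
    DomainError
        for fewer than 2 regions or negative counts.
    DegenerateInputError
        when all counts are zero.
    """
    counts = np.asarray(list(counts), dtype=float)
    if counts.size < 2:
        raise DomainError(f"need at least 2 regions, got {counts.size}")
    if np.any(counts < 0):
        raise DomainError("counts must be non-negative")
    if counts.sum() <= 0:
        raise DegenerateInputError("all counts are zero; Theil index undefined")
    if weights is None:
        w = np.full(counts.size, 1.0 / counts.size)
    else:
        w = np.asarray(list(weights), dtype=float)
        if w.shape != counts.shape or np.any(w <= 0):
            raise DomainError("weights must be positive and match counts")
        w = w / w.sum()
    mean = float(np.sum(w * counts))
    return max(float(np.sum(w * _theil_terms(counts, mean))), 0.0)


def theil_decompose(
    counts: Iterable[float],
    groups: Iterable[str],
    labels: Sequence[str] | None = None,
) -> TheilResult:
    """Decompose the Theil index into within- and between-group parts.

    With group resource shares ``S_p``, group size shares ``P_p = n_p/n``
    and within-group indices ``T_p``:

    * between: ``T_B = sum_p S_p ln(S_p / P_p)``
    * within:  ``T_w = sum_p S_p T_p``

    and ``T = T_w + T_B`` exactly (checked to 1e-12).  Contribution
    rates ``T_w/T`` and ``T_B/T`` are reported when ``T > 0``.

    Parameters
    ----------
    counts : per-region resource counts.
    groups : group label for each region, aligned with ``counts``.
    labels : optional region labels (used in error messages only).
    """
    counts = np.asarray(list(counts), dtype=float)
    group_list = [None if g is None else str(g) for g in groups]
    if len(group_list) != counts.size:
        raise GroupingError(
            f"groups ({len(group_list)}) must align with counts ({counts.size})"
        )
    for i, g in enumerate(group_list):
        if g is None or g == "":
            name = labels[i] if labels is not None else f"index {i}"
            raise GroupingError(f"region {name} has no group assignment")

    total = theil_total(counts)
    grand_total = counts.sum()
    grand_mean = counts.mean()
    n = counts.size

    between = 0.0
    within = 0.0
    per_group: list[tuple[str, float, float]] = []
    for g in sorted(set(group_list)):
        mask = np.asarray([x == g for x in group_list])
        sub = counts[mask]
        share = float(sub.sum() / grand_total)  # S_p
        size_share = float(sub.size / n)  # P_p
        if share > 0:
            between += share * math.log(share / size_share)
            sub_mean = sub.mean()
            t_p = float(np.mean(_theil_terms(sub, sub_mean))) if sub_mean > 0 else 0.0
            t_p = max(t_p, 0.0)
            within += share * t_p
        else:
            t_p = 0.0
        per_group.append((g, share, t_p))

    between = max(between, 0.0)
    within = max(within, 0.0)
    if total > 0:
        cw: float | None = within / total
        cb: float | None = between / total
    else:
        cw = cb = None
    assert abs(total - (within + between)) < 1e-9 * max(1.0, total), (
        "decomposition identity violated"
    )
    return TheilResult(
        total=total,
        within=within,
        between=between,
        contribution_within=cw,
        contribution_between=cb,
        per_group=tuple(per_group),
    )


def lorenz_from_panel(panel, year: int, basis: Basis | str, resource: str = "nurses"):
    """Lorenz curve for one panel year (whole-stratum records)."""
    from .panel import Stratum

    basis = Basis(basis)
    recs = [
        r
        for r in panel.records
        if r.year == year and r.stratum is Stratum.WHOLE
    ]
    if len(recs) < 2:
        raise DomainError(
            f"year {year}: need >= 2 whole-stratum regions, got {len(recs)}"
        )
    weight_of = (
        (lambda r: r.population) if basis is Basis.POPULATION else (lambda r: r.area_km2)
    )
    pairs = [(weight_of(r), float(getattr(r, resource))) for r in recs]
    return build_lorenz(pairs, basis=basis, labels=[r.region_id for r in recs])


def gini_for_year(
    panel, year: int, basis: Basis | str, resource: str = "nurses"
) -> GiniResult:
    """Gini coefficient (with fairness label) for one panel year."""
    curve = lorenz_from_panel(panel, year, basis, resource)
    value = gini_summation(curve)
    return GiniResult(
        value=value,
        basis=Basis(basis),
        fairness_label=classify_gini(value),
        year=year,
    )
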