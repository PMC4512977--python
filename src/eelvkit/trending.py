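"""Trending ability: four-quadrant concordance and polar-plot statistics.

For each animal, changes in EELV between *consecutive* measurements give
one delta pair ``(d_ct, d_wiwo)``.  On the four-quadrant plot the two
agreement quadrants are those where both methods change in the same
direction; the concordance rate is the percentage of pairs falling there,
after excluding pairs whose mean change is smaller than an exclusion
threshold (small changes reflect measurement noise, not trending).

The polar plot is the four-quadrant plot rotated 45 degrees clockwise so
the line of identity lies along the horizontal axis: the polar angle of a
pair is its angular deviation from perfect agreement, and the radius is
the mean change ``(d_ct + d_wiwo)/2``.  Pairs in which both methods
decrease appear on the left half; their deviation is measured from the
180-degree axis.  Summary statistics are the *angular bias* (mean signed
deviation, with SD) and the *radial limits of agreement* (the symmetric
sector containing 95% of absolute deviations).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from eelvkit.errors import DegenerateDataError, DomainError
from eelvkit.study_data import PairedSeries

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DeltaPair:
    """Consecutive change for one animal, in both methods."""

    animal_id: str
    from_index: int
    to_index: int
    d_ct: float      # mL
    d_wiwo: float    # mL

    @property
    def radius(self) -> float:
        """Mean change of the two methods, mL (may be negative)."""
        return (self.d_ct + self.d_wiwo) / 2.0

    @property
    def theta(self) -> float:
        """Polar angle in degrees, in (-180, 180]; see :func:`polar_transform`."""
        return polar_transform(self.d_ct, self.d_wiwo)[1]

    @property
    def deviation(self) -> float:
        """Signed angular deviation (degrees) from the agreement axis.

        Right-half points (positive direction) are measured from 0 deg,
        left-half points (both methods decreasing) from the 180-deg axis.
        """
        theta = self.theta
        if abs(theta) <= 90.0:
            return theta
        # left half: deviation from the 180-degree axis
        return theta - 180.0 if theta > 0 else theta + 180.0


@dataclass(frozen=True)
class TrendingResult:
    """Trending summary at one exclusion threshold."""

    concordance_rate: float    # %
    angular_bias: float        # degrees, mean signed deviation
    angular_sd: float          # degrees
    radial_loa: float          # +/- degrees, 95th percentile of |deviation|
    radial_loa_parametric: float  # +/- degrees, 1.96 x angular SD
    n_deltas: int              # retained after exclusion
    n_total: int               # before exclusion
    exclusion_threshold: float  # mL

    def to_dict(self) -> dict:
        return {
            "exclusion_threshold_mL": self.exclusion_threshold,
            "concordance_rate_pct": self.concordance_rate,
            "angular_bias_deg": self.angular_bias,
            "angular_sd_deg": self.angular_sd,
            "radial_loa_deg": self.radial_loa,
            "radial_loa_parametric_deg": self.radial_loa_parametric,
            "n_deltas": self.n_deltas,
            "n_total": self.n_total,
        }


# ---------------------------------------------------------------------------
# operations


def consecutive_deltas(series: PairedSeries) -> list[DeltaPair]:
    """One delta pair per adjacent paired row within each animal.

    Rows are adjacent in the per-animal timeline of *paired* rows (the
    single experimental sequence: onset, PEEP trial, V_T ladder); deltas
    never span animals.  Animals with fewer than two paired rows
    contribute nothing (logged at DEBUG).
    """
    deltas: list[DeltaPair] = []
    frame = series.frame
    for animal, grp in frame.groupby("animal_id", sort=False):
        grp = grp.sort_values("order_index")
        if len(grp) < 2:
            logger.debug("animal %s has %d paired row(s); no deltas", animal, len(grp))
            continue
        idx = grp["order_index"].to_numpy()
        ct = grp["eelv_ct_mL"].to_numpy(dtype=float)
        wiwo = grp["eelv_wiwo_mL"].to_numpy(dtype=float)
        for k in range(1, len(grp)):
            deltas.append(
                DeltaPair(
                    animal_id=str(animal),
                    from_index=int(idx[k - 1]),
                    to_index=int(idx[k]),
                    d_ct=float(ct[k] - ct[k - 1]),
                    d_wiwo=float(wiwo[k] - wiwo[k - 1]),
                )
            )
    return deltas


def polar_transform(d_ct: float, d_wiwo: float) -> tuple[float, float]:
    """Polar coordinates of one delta pair: ``(radius, theta_degrees)``.

    ``theta`` is the four-quadrant angle rotated 45 degrees clockwise
    (identity line -> 0 degrees), wrapped to (-180, 180].  ``radius`` is
    the mean change; its sign places the pair on the right (increases) or
    left (decreases) half of the polar plot.
    """
    if d_ct == 0 and d_wiwo == 0:
        raise DomainError("polar angle undefined for a (0, 0) delta pair")
    theta = np.degrees(np.arctan2(d_wiwo, d_ct)) - 45.0
    theta = _wrap_angle(theta)
    radius = (d_ct + d_wiwo) / 2.0
    return float(radius), float(theta)


def _wrap_angle(theta: float) -> float:
    """Wrap to (-180, 180]."""
    wrapped = (theta + 180.0) % 360.0 - 180.0
    if wrapped == -180.0:
        wrapped = 180.0
    return float(wrapped)


def _retained(deltas, exclusion_threshold, rule="mean"):
    if rule == "mean":
        return [p for p in deltas if abs(p.radius) >= exclusion_threshold]
    if rule == "max":
        return [
            p
            for p in deltas
            if max(abs(p.d_ct), abs(p.d_wiwo)) >= exclusion_threshold
        ]
    raise DomainError(f"unknown exclusion rule {rule!r}")


def concordance_rate(
    deltas: list[DeltaPair],
    exclusion_threshold: float = 0.0,
    rule: str = "mean",
) -> float:
    """Percentage of retained delta pairs with same-direction changes.

    Pairs whose exclusion statistic (default: |mean change|) is below the
    threshold are removed first.  A pair with either component exactly
    zero has no defined direction and is counted as discordant
    (conservative).
    """
    retained = _retained(deltas, exclusion_threshold, rule)
    if not retained:
        raise DegenerateDataError(
            f"no delta pairs retained at exclusion threshold {exclusion_threshold} mL"
        )
    agree = sum(1 for p in retained if p.d_ct * p.d_wiwo > 0)
    n_zero = sum(1 for p in retained if p.d_ct == 0 or p.d_wiwo == 0)
    if n_zero:
        logger.debug("%d delta pair(s) with a zero component counted discordant", n_zero)
    return 100.0 * agree / len(retained)


def angular_stats(
    deltas: list[DeltaPair],
    exclusion_threshold: float = 0.0,
    rule: str = "mean",
) -> tuple[float, float, float]:
    """Angular bias, its SD, and the radial limits of agreement (degrees).

    The angular bias is the arithmetic mean of signed deviations from the
    agreement axis (left-half pairs measured from 180 degrees); the
    radial limits of agreement are the half-angle of the symmetric sector
    containing 95% of absolute deviations (95th percentile, linear
    interpolation).  Deviations live well inside +/-180 degrees, so plain
    arithmetic (rather than circular) moments are used.
    """
    retained = _retained(deltas, exclusion_threshold, rule)
    if len(retained) < 5:
        raise DegenerateDataError(
            f"angular statistics need >= 5 retained pairs, got {len(retained)}"
        )
    dev = np.array([p.deviation for p in retained], dtype=float)
    bias = float(np.mean(dev))
    sd = float(np.std(dev, ddof=1))
    radial_loa = float(np.percentile(np.abs(dev), 95.0, method="linear"))
    return bias, sd, radial_loa


def trending_analysis(
    series: PairedSeries,
    exclusion_threshold: float = 0.0,
    rule: str = "mean",
) -> TrendingResult:
    """Full trending summary of a paired series at one exclusion threshold."""
    deltas = consecutive_deltas(series)
    retained = _retained(deltas, exclusion_threshold, rule)
    bias, sd, radial = angular_stats(deltas, exclusion_threshold, rule)
    return TrendingResult(
        concordance_rate=concordance_rate(deltas, exclusion_threshold, rule),
        angular_bias=bias,
        angular_sd=sd,
        radial_loa=radial,
        radial_loa_parametric=1.96 * sd,
        n_deltas=len(retained),
        n_total=len(deltas),
        exclusion_threshold=exclusion_threshold,
    )


def plot_polar(deltas: list[DeltaPair], path, exclusion_threshold: float = 0.0) -> None:
    """Polar trending plot (agreement axis horizontal)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    retained = _retained(deltas, exclusion_threshold)
    thetas = np.radians([p.theta for p in retained])
    radii = np.abs([p.radius for p in retained])
    fig = plt.figure(figsize=(5, 5))
    ax = fig.add_subplot(projection="polar")
    ax.scatter(thetas, radii, s=14, alpha=0.7)
    ax.set_title(f"exclusion {exclusion_threshold:g} mL", fontsize=9)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
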