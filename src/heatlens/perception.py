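"""The quadratic heat-perception model and its derived statistics.

Daily attention T is regressed on daily maximum temperature ω by ordinary
least squares:

    T = a0 + a1·ω + a2·ω² + ε

The quadratic captures the U-shape of heat discourse: attention falls as
days warm toward the comfort zone, then rises steeply past it. From a fitted
convex curve four statistics are derived per region:

* **vertex temperature** −a1/(2a2): where attention is lowest — the comfort
  point at which attention stops falling and starts rising;
* **heat sensitivity** a2: the curvature — how steeply attention reacts to
  temperature change;
* **heat tolerance**: the right (upper) intersection of the region's mean
  attention level M with the fitted curve — above it, attention is
  abnormally high for that region;
* **heat perception threshold**: the average daily maximum temperature on
  the occasions heat-related posts were made (each post contributes its
  day's temperature once).

Non-convex fits (a2 ≤ 0) or curves that never reach M yield flagged
undefined values rather than errors, so national tables degrade gracefully.
"""
from __future__ import annotations

import datetime as dt
import math
from collections.abc import Iterable, Sequence
from dataclasses import dataclass, field

import numpy as np

from .records import AttentionRecord, PostRecord, RegionDayTemp

#: Reason codes for undefined derived statistics.
NON_CONVEX = "non-convex"
NO_INTERSECTION = "no-intersection"


@dataclass(frozen=True)
class PerceptionObservation:
    """One region-day pair of daily maximum temperature (°C) and daily
    attention index."""

    region: str
    date: dt.date
    omega: float
    t_attn: float


@dataclass
class PerceptionFit:
    """A fitted per-region quadratic with its derived perception statistics.

    ``tolerance_c`` and ``vertex_c`` are ``None`` when undefined; ``flags``
    then carries machine-readable reason codes.
    """

    region: str
    a0: float
    a1: float
    a2: float
    n_obs: int
    r2: float
    mean_attention: float
    sensitivity: float = 0.0
    vertex_c: float | None = None
    tolerance_c: float | None = None
    threshold_c: float | None = None
    flags: tuple[str, ...] = field(default_factory=tuple)


def build_observations(
    attention: Iterable[AttentionRecord],
    temps: Iterable[RegionDayTemp],
) -> list[PerceptionObservation]:
    """Join daily attention with region-day temperatures on (region, date).

    Region-days present in only one of the two inputs are dropped — a day
    with no temperature reading cannot enter the regression.
    """
    temp_by_key = {(t.region, t.date): t.tmax_c for t in temps}
    out = []
    for a in attention:
        if a.date is None:
            continue
        key = (a.region, a.date)
        if key in temp_by_key:
            out.append(
                PerceptionObservation(
                    region=a.region, date=a.date,
                    omega=temp_by_key[key], t_attn=a.index,
                )
            )
    return out


def fit_perception_model(
    obs: Sequence[PerceptionObservation] | None = None,
    *,
    omega: Sequence[float] | None = None,
    t_attn: Sequence[float] | None = None,
    region: str = "",
) -> PerceptionFit:
    """OLS fit of attention on (1, ω, ω²) with derived statistics.

    Accepts either observation records or bare ``omega``/``t_attn`` arrays.
    Requires at least three distinct temperatures; a rank-deficient design is
    an error.
    """
    if obs is not None:
        omega = [o.omega for o in obs]
        t_attn = [o.t_attn for o in obs]
        if not region and obs:
            region = obs[0].region
    w = np.asarray(omega, dtype=float)
    t = np.asarray(t_attn, dtype=float)
    if w.shape != t.shape or w.ndim != 1:
        raise ValueError("omega and t_attn must be paired 1-d sequences")
    if len(np.unique(w)) < 3:
        raise ValueError(
            f"need >= 3 distinct temperature values, got {len(np.unique(w))}"
        )
    X = np.column_stack([np.ones_like(w), w, w * w])
    coef, _, rank, _ = np.linalg.lstsq(X, t, rcond=None)
    if rank < 3:
        raise ValueError("collinear design: quadratic fit is not identified")
    resid = t - X @ coef
    ss_res = float(resid @ resid)
    ss_tot = float(((t - t.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    fit = PerceptionFit(
        region=region,
        a0=float(coef[0]), a1=float(coef[1]), a2=float(coef[2]),
        n_obs=len(w), r2=r2, mean_attention=float(t.mean()),
    )
    return derive_statistics(fit)


def derive_statistics(fit: PerceptionFit) -> PerceptionFit:
    """Fill sensitivity, vertex and tolerance (with reason flags) in place."""
    flags: list[str] = []
    fit.sensitivity = heat_sensitivity(fit)
    fit.vertex_c = vertex_temperature(fit)
    if fit.vertex_c is None:
        flags.append(NON_CONVEX)
        fit.tolerance_c = None
    else:
        fit.tolerance_c = heat_tolerance(fit)
        if fit.tolerance_c is None:
            flags.append(NO_INTERSECTION)
    fit.flags = tuple(flags)
    return fit


def vertex_temperature(fit: PerceptionFit) -> float | None:
    """Temperature minimising the fitted quadratic: −a1/(2·a2) for a2 > 0;
    undefined (None, reason "non-convex") otherwise."""
    if fit.a2 <= 0:
        return None
    return -fit.a1 / (2.0 * fit.a2)


def heat_sensitivity(fit: PerceptionFit) -> float:
    """The quadratic coefficient a2, verbatim: the curvature of the
    attention–temperature response."""
    return fit.a2


def heat_tolerance(fit: PerceptionFit) -> float | None:
    """Right intersection of the mean attention level with the fitted curve.

    Solves a2ω² + a1ω + (a0 − M) = 0 for the larger root, M being the
    region's mean attention. Undefined for non-convex fits or when the curve
    never comes back down to M (negative discriminant).
    """
    if fit.a2 <= 0:
        return None
    disc = fit.a1 * fit.a1 - 4.0 * fit.a2 * (fit.a0 - fit.mean_attention)
    if disc < 0:
        return None
    return (-fit.a1 + math.sqrt(disc)) / (2.0 * fit.a2)


def heat_perception_threshold(
    posts: Iterable[PostRecord],
    temps: Iterable[RegionDayTemp],
    region: str,
) -> float:
    """Post-count-weighted mean daily maximum temperature over a region's
    posting days: each post contributes its day's ω once."""
    temp_by_date = {t.date: t.tmax_c for t in temps if t.region == region}
    values = [
        temp_by_date[p.date]
        for p in posts
        if p.region == region and p.date in temp_by_date
    ]
    if not values:
        raise ValueError(
            f"no posts in region {region!r} match a region-day temperature"
        )
    return float(np.mean(values))


def fit_all_regions(
    obs: Iterable[PerceptionObservation],
    posts: Iterable[PostRecord] | None = None,
    temps: Iterable[RegionDayTemp] | None = None,
) -> list[PerceptionFit]:
    """Fit the perception model for every region present in ``obs``; when
    posts and temperatures are supplied the perception threshold is filled
    in too. Regions failing the fit preconditions are skipped."""
    by_region: dict[str, list[PerceptionObservation]] = {}
    for o in obs:
        by_region.setdefault(o.region, []).append(o)
    posts = list(posts) if posts is not None else None
    temps = list(temps) if temps is not None else None
    fits = []
    for region in sorted(by_region):
        try:
            fit = fit_perception_model(by_region[region])
        except ValueError:
            continue
        if posts is not None and temps is not None:
            try:
                fit.threshold_c = heat_perception_threshold(posts, temps, region)
            except ValueError:
                fit.threshold_c = None
        fits.append(fit)
    return fits
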