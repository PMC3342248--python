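"""Diameter-class binning and size–frequency / size–biomass fits.

Metabolic scaling theory predicts that stem abundance falls off with stem
radius as ``Δn ∝ r⁻²`` and that individual mass grows as ``m ∝ r^(8/3)``,
so the total biomass held in a radius class scales as ``M_bin ∝ r^(2/3)``.
This module bins stems into 5 cm diameter classes (2.5 cm radius classes),
fits those fixed-exponent forms (only the constant is free), and fits the
empirical alternative — a negative-exponential abundance curve
``Δn = a·exp(−b·dbh)`` — for comparison.

Fits are least squares on the untransformed per-bin values by default: on
the arithmetic scale the variance is dominated by the large-diameter bins,
which is exactly where the scaling forms succeed or fail.  A log-scale
option is exposed for sensitivity analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import curve_fit

from .stand_model import StemRecord

__all__ = ["DiameterBins", "ScalingFit", "bin_diameters", "fit_scaling"]

_MODELS = ("wbe_frequency", "wbe_biomass", "negative_exponential")


@dataclass(frozen=True)
class DiameterBins:
    """5 cm diameter classes: first bin [1, 5) cm, then 5 cm steps.

    ``radius_cm`` holds the class centers expressed as stem radius
    (midpoint diameter / 2); counts and biomass are conserved exactly.
    """

    edges_cm: np.ndarray
    counts: np.ndarray
    biomass_mg: np.ndarray

    @property
    def centers_dbh_cm(self) -> np.ndarray:
        return (self.edges_cm[:-1] + self.edges_cm[1:]) / 2.0

    @property
    def radius_cm(self) -> np.ndarray:
        return self.centers_dbh_cm / 2.0

    @property
    def n_bins(self) -> int:
        return len(self.counts)


@dataclass(frozen=True)
class ScalingFit:
    """A fitted abundance or biomass model over diameter bins."""

    model: str
    constants: tuple[float, ...]
    r_squared: float
    predicted: np.ndarray
    observed: np.ndarray
    log_scale: bool = False


def bin_diameters(
    stems: Sequence[StemRecord],
    biomass_kg_by_tag: dict[str, float] | None = None,
) -> DiameterBins:
    """Bin stems into half-open 5 cm diameter classes.

    Bins are [1,5), [5,10), [10,15), ... up to the largest occupied bin;
    interior empty bins are kept (count 0) but no zero tail is appended
    beyond the data.  ``biomass_kg_by_tag`` fills the per-bin biomass
    (Mg); without it biomass is zero.
    """
    dbh = np.array([s.dbh_cm for s in stems], dtype=float)
    if len(dbh) == 0:
        return DiameterBins(edges_cm=np.array([1.0, 5.0]),
                            counts=np.zeros(1, dtype=int),
                            biomass_mg=np.zeros(1))
    if dbh.min() < 1.0:
        raise ValueError("all stems must have dbh >= 1 cm")
    top = float(dbh.max())
    last_edge = 5.0 if top < 5.0 else (np.floor(top / 5.0) + 1.0) * 5.0
    edges = np.concatenate([[1.0], np.arange(5.0, last_edge + 0.5, 5.0)])
    # np.histogram closes the last bin; the largest stem defines last_edge
    # strictly above it, so every bin behaves as half-open.
    counts, _ = np.histogram(dbh, bins=edges)
    if biomass_kg_by_tag is not None:
        masses = np.array([biomass_kg_by_tag.get(s.tag, 0.0) for s in stems]) / 1000.0
        biomass, _ = np.histogram(dbh, bins=edges, weights=masses)
    else:
        biomass = np.zeros(len(counts))
    return DiameterBins(edges_cm=edges, counts=counts, biomass_mg=biomass)


def _r2(observed: np.ndarray, predicted: np.ndarray) -> float:
    ss_res = float(np.sum((observed - predicted) ** 2))
    ss_tot = float(np.sum((observed - observed.mean()) ** 2))
    if ss_tot == 0.0:
        return 0.0 if ss_res > 0 else 1.0
    return max(0.0, 1.0 - ss_res / ss_tot)   # floored at 0 for reporting


def fit_scaling(bins: DiameterBins, model: str, log_scale: bool = False) -> ScalingFit:
    """Fit one of the three size-distribution models to binned data.

    ``wbe_frequency`` (Δn = c·r⁻²) and ``wbe_biomass`` (M = c·r^(2/3)) have
    their exponent fixed by scaling theory, so only the constant c is
    estimated — by closed-form least squares on the (by default
    untransformed) bin values.  ``negative_exponential`` fits (a, b) in
    Δn = a·exp(−b·dbh) by nonlinear least squares on the counts against the
    bin-center diameters.
    """
    if model not in _MODELS:
        raise ValueError(f"unknown model {model!r}; expected one of {_MODELS}")
    if bins.n_bins < 3:
        raise ValueError("need at least 3 bins to fit")
    r = bins.radius_cm
    if model == "wbe_biomass":
        y = bins.biomass_mg.astype(float)
    else:
        y = bins.counts.astype(float)
    if not np.any(y > 0):
        raise ValueError("all bins are empty; nothing to fit")

    if model == "negative_exponential":
        d = bins.centers_dbh_cm
        lo, hi = bins.edges_cm[:-1], bins.edges_cm[1:]
        # predicted count integrates the density a·e^(−b·x) over each bin,
        # which keeps the unequal-width first bin ([1,5) vs 5 cm) unbiased
        def bin_counts(_x, a, b):
            return a / b * (np.exp(-b * lo) - np.exp(-b * hi))

        pos = y > 0
        b0 = max(1e-4, -np.polyfit(d[pos], np.log(y[pos]), 1)[0])
        a0 = float(b0 * y.sum()
                   / (np.exp(-b0 * lo[0]) - np.exp(-b0 * hi[-1])))
        if log_scale:
            popt, _ = curve_fit(
                lambda x, la, b: np.log(bin_counts(x, np.exp(la), b))[pos],
                d, np.log(y[pos]), p0=[np.log(a0), b0], maxfev=20000)
            a, b = float(np.exp(popt[0])), float(popt[1])
        else:
            popt, _ = curve_fit(bin_counts, d, y, p0=[a0, b0], maxfev=20000)
            a, b = float(popt[0]), float(popt[1])
        pred = bin_counts(d, a, b)
        if log_scale:
            r2 = _r2(np.log(y[pos]), np.log(pred[pos]))
        else:
            r2 = _r2(y, pred)
        return ScalingFit(model=model, constants=(a, b), r_squared=r2,
                          predicted=pred, observed=y, log_scale=log_scale)

    exponent = -2.0 if model == "wbe_frequency" else 2.0 / 3.0
    x = r ** exponent
    if log_scale:
        pos = y > 0
        # log-scale fixed-exponent fit: intercept-only regression of
        # log y - e*log r, i.e. geometric-mean constant
        log_c = float(np.mean(np.log(y[pos]) - exponent * np.log(r[pos])))
        c = float(np.exp(log_c))
        pred = c * x
        r2 = _r2(np.log(y[pos]), np.log(pred[pos]))
    else:
        c = float(np.sum(y * x) / np.sum(x * x))   # closed-form LSQ constant
        pred = c * x
        r2 = _r2(y, pred)
    return ScalingFit(model=model, constants=(c,), r_squared=r2,
                      predicted=pred, observed=y, log_scale=log_scale)
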