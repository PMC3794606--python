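"""Cooperative binding-curve fitting for fluorescence-polarization titrations.

A titration holds the polarization (or derived fraction bound) of a fixed
concentration of fluorescein-labelled RE DNA (typically 50 nM) against a
protein dilution series (typically 18 points, 0 to 20 000 nM).  Raw
polarization is converted linearly to fraction bound between the free- and
bound-DNA endpoints, and the curve is fitted to the Hill equation

    f(c) = f0 + (fmax - f0) * c^h / (EC50^h + c^h)

by unweighted nonlinear least squares.  The EC50 is reported as the
dissociation constant Kd under the stoichiometry assumption of one dimer
per half-site / one tetramer per full site; h > 1 indicates cooperative
binding.  Curves that never approach saturation within the titrated range
are censored: the fit reports only a lower bound on Kd equal to the top
concentration tested.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "BindingCurve",
    "HillFit",
    "AffinityRatio",
    "fraction_bound",
    "hill_fraction",
    "fit_hill",
    "affinity_ratio",
]

_HILL_BOUNDS_H = (0.2, 5.0)
#: Multiplicative jitters applied to the EC50 initial guess (multi-start).
_EC50_STARTS = (0.2, 0.5, 1.0, 2.0, 5.0)
#: A curve is censored when the largest observed response covers less than
#: this fraction of the fitted span, or the fitted EC50 exceeds the top
#: tested concentration.
_CENSOR_SPAN_FRACTION = 0.6


@dataclass(frozen=True)
class BindingCurve:
    """One titration: concentrations (nM) with per-replicate responses.

    ``response`` has shape (n_points, n_replicates); ``is_fraction`` marks
    whether responses are already fraction bound (else raw polarization,
    convertible with :func:`fraction_bound`).
    """

    concentrations: tuple[float, ...]
    response: tuple[tuple[float, ...], ...]
    dna_conc: float = 50.0
    stoichiometry: str = "tetramer_per_fullsite"
    is_fraction: bool = True

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.concentrations):
            raise ValueError("concentrations must be non-negative")
        if len(self.response) != len(self.concentrations):
            raise ValueError("one response row per concentration required")
        if self.stoichiometry not in ("dimer_per_halfsite", "tetramer_per_fullsite"):
            raise ValueError(f"unknown stoichiometry {self.stoichiometry!r}")
        if self.is_fraction:
            flat = [r for row in self.response for r in row]
            if any(not -0.1 <= r <= 1.1 for r in flat):
                raise ValueError("fraction-bound values must lie in [-0.1, 1.1]")

    def pooled(self) -> tuple[np.ndarray, np.ndarray]:
        """Replicate-pooled (conc, response) arrays sorted by concentration."""
        conc, resp = [], []
        for c, row in zip(self.concentrations, self.response):
            for r in row:
                conc.append(c)
                resp.append(r)
        order = np.argsort(conc, kind="stable")
        return np.asarray(conc)[order], np.asarray(resp)[order]


@dataclass(frozen=True)
class HillFit:
    """Fitted Hill parameters; EC50 is reported as Kd.

    When ``censored`` the point estimate is unreliable and ``kd_lower_bound``
    (the top concentration tested) is the reportable quantity, mirroring
    the "Kd > top of titration" convention for unsaturated curves.
    """

    ec50: float
    hill: float
    f0: float
    fmax: float
    se: tuple[float, float, float, float]  # (ec50, hill, f0, fmax)
    rss: float
    censored: bool
    kd_lower_bound: Optional[float] = None

    def __post_init__(self) -> None:
        if self.ec50 <= 0 or self.hill <= 0:
            raise ValueError("ec50 and hill must be positive")
        if not self.f0 < self.fmax:
            raise ValueError("f0 must be below fmax")


@dataclass(frozen=True)
class AffinityRatio:
    """Fold difference in Kd, optionally a bound when a side is censored."""

    value: float
    qualifier: Optional[str] = None  # None, '>=' or '<='


def fraction_bound(polarization: float, p_free: float, p_bound: float) -> tuple[float, bool]:
    """Linear conversion of polarization to fraction bound.

    Returns ``(fraction, clipped)``: the value is clipped into [0, 1] and
    the flag records whether clipping occurred (noise can push raw values
    slightly past the endpoints).
    """
    if p_bound == p_free:
        raise ValueError("free and bound endpoints must differ")
    f = (polarization - p_free) / (p_bound - p_free)
    clipped = not 0.0 <= f <= 1.0
    return min(max(f, 0.0), 1.0), clipped


def hill_fraction(conc, ec50: float, hill: float, f0: float, fmax: float):
    """Hill equation: fraction bound at total protein concentration ``conc``.

    Scalar or array ``conc`` >= 0; at conc = 0 the value is exactly ``f0``.
    """
    if ec50 <= 0 or hill <= 0:
        raise ValueError("ec50 and hill must be positive")
    c = np.asarray(conc, dtype=float)
    if np.any(c < 0):
        raise ValueError("concentrations must be non-negative")
    with np.errstate(divide="ignore"):
        ch = np.where(c > 0, np.exp(hill * np.log(np.where(c > 0, c, 1.0))), 0.0)
    out = f0 + (fmax - f0) * ch / (ec50 ** hill + ch)
    return float(out) if np.isscalar(conc) or out.ndim == 0 else out


def _depletion_fraction(conc, kd: float, f0: float, fmax: float, dna: float):
    """Ligand-depletion (quadratic) 1:1 binding isotherm on total protein."""
    c = np.asarray(conc, dtype=float)
    s = c + dna + kd
    bound = (s - np.sqrt(s * s - 4.0 * c * dna)) / (2.0 * dna)
    out = f0 + (fmax - f0) * bound
    return float(out) if np.isscalar(conc) or out.ndim == 0 else out


def _initial_guess(conc: np.ndarray, resp: np.ndarray) -> tuple[float, float, float, float]:
    f0 = float(resp.min())
    fmax = float(resp.max())
    half = (f0 + fmax) / 2.0
    pos = conc > 0
    c_pos, r_pos = conc[pos], resp[pos]
    ec50 = float(np.median(c_pos))
    above = np.nonzero(r_pos >= half)[0]
    if above.size and above[0] > 0:
        i = above[0]
        c0, c1 = c_pos[i - 1], c_pos[i]
        r0, r1 = r_pos[i - 1], r_pos[i]
        if r1 != r0:  # linear interpolation of the half-max crossing
            ec50 = float(c0 + (half - r0) * (c1 - c0) / (r1 - r0))
    elif above.size:
        ec50 = float(c_pos[0])
    return max(ec50, 1e-6), 1.0, f0, fmax


def fit_hill(curve: BindingCurve, depletion: bool = False) -> HillFit:
    """Fit the Hill model to a titration by multi-start least squares.

    Replicates are pooled and fitted unweighted.  The EC50 start is the
    interpolated half-max crossing, jittered multiplicatively over five
    starts; h starts at 1 and is bounded in [0.2, 5]; EC50 is bounded
    between one tenth of the smallest positive concentration and 100x the
    largest.  The zero-concentration anchor constrains f0.  Standard errors
    come from the local curvature (Jacobian) at the optimum.  With
    ``depletion`` a quadratic ligand-depletion isotherm (h fixed at 1,
    using ``curve.dna_conc``) replaces the Hill model.

    Raises ``ValueError`` on fewer than 5 distinct concentrations and
    ``RuntimeError`` (carrying the start set) if no start converges.
    """
    conc, resp = curve.pooled()
    if np.unique(conc).size < 5:
        raise ValueError("need at least 5 distinct concentrations")
    pos = conc[conc > 0]
    if pos.size == 0:
        raise ValueError("need at least one positive concentration")
    ec50_0, h0, f00, fmax0 = _initial_guess(conc, resp)
    lo_ec, hi_ec = float(pos.min()) / 10.0, float(conc.max()) * 100.0
    ec50_0 = min(max(ec50_0, lo_ec), hi_ec)

    span = max(fmax0 - f00, 0.05)
    lo = [lo_ec, _HILL_BOUNDS_H[0], f00 - span, f00 + 1e-6]
    hi = [hi_ec, _HILL_BOUNDS_H[1], fmax0, fmax0 + span]

    if depletion:
        def model(c, kd, f0, fmax):
            return _depletion_fraction(c, kd, f0, fmax, curve.dna_conc)
        lo_d = [lo[0], lo[2], lo[3]]
        hi_d = [hi[0], hi[2], hi[3]]
    else:
        model = hill_fraction

    best = None
    starts = []
    for mult in _EC50_STARTS:
        ec_start = min(max(ec50_0 * mult, lo_ec), hi_ec)
        if depletion:
            p0 = [ec_start, f00, (f00 + fmax0 + span) / 2 if fmax0 <= f00 else fmax0]
            bounds = (lo_d, hi_d)
        else:
            p0 = [ec_start, h0, f00, fmax0 if fmax0 > f00 else f00 + span]
            p0[3] = min(max(p0[3], lo[3] + 1e-9), hi[3])
            bounds = (lo, hi)
        starts.append(tuple(p0))
        try:
            popt, pcov = curve_fit(
                model, conc, resp, p0=p0, bounds=bounds,
                method="trf", xtol=1e-12, ftol=1e-12, gtol=1e-12,
                maxfev=20000,
            )
        except (RuntimeError, ValueError):
            continue
        rss = float(np.sum((model(conc, *popt) - resp) ** 2))
        if best is None or rss < best[2]:
            best = (popt, pcov, rss)
    if best is None:
        raise RuntimeError(
            f"Hill fit did not converge from any start; starts tried: {starts}"
        )
    popt, pcov, rss = best
    se = np.sqrt(np.clip(np.diag(pcov), 0.0, np.inf))
    if depletion:
        ec50, f0, fmax = popt
        hill_coef = 1.0
        se_full = (float(se[0]), 0.0, float(se[1]), float(se[2]))
    else:
        ec50, hill_coef, f0, fmax = popt
        se_full = tuple(float(s) for s in se)

    top = float(conc.max())
    approached = bool(resp.max() >= f0 + _CENSOR_SPAN_FRACTION * (fmax - f0))
    censored = (not approached) or bool(ec50 > top)
    if fmax <= f0:  # degenerate flat fit: report as censored with tiny span
        fmax = f0 + 1e-9
        censored = True
    return HillFit(
        ec50=float(ec50),
        hill=float(hill_coef),
        f0=float(f0),
        fmax=float(fmax),
        se=se_full,
        rss=rss,
        censored=censored,
        kd_lower_bound=top if censored else None,
    )


def affinity_ratio(fit_a: HillFit, fit_b: HillFit) -> AffinityRatio:
    """Fold difference Kd_b / Kd_a (how much tighter a binds than b).

    A censored fit contributes its Kd lower bound, turning the ratio into
    a one-sided bound: censored ``fit_b`` gives '>= bound_b/Kd_a', censored
    ``fit_a`` gives '<= Kd_b/bound_a'.  Both censored -> the ratio is
    undefined and a ``ValueError`` is raised.
    """
    if fit_a.censored and fit_b.censored:
        raise ValueError("both fits censored: ratio undefined")
    if fit_b.censored:
        return AffinityRatio(fit_b.kd_lower_bound / fit_a.ec50, ">=")
    if fit_a.censored:
        return AffinityRatio(fit_b.ec50 / fit_a.kd_lower_bound, "<=")
    return AffinityRatio(fit_b.ec50 / fit_a.ec50, None)
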