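"""Magnetic-tweezers twist analysis.

A torsionally constrained DNA tether shortens when over- or underwound; the
turn count ``N_max`` at which its extension is maximal marks the torsionally
relaxed state and is found by fitting the full rotation-extension curve with
a Gaussian.  The twist change between an ionic condition and the reference
condition follows from the shift of ``N_max``:

    dTw = 360 deg * (N_max - N_max,ref) / n_bp            (n_bp = 7900)

The concentration dependence of dTw is modelled either as a power law
``dTw = A c^B + C`` or as a straight line in log10(c); models are compared
by reduced chi-square.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field

import numpy as np
from lmfit import Parameters, minimize as lm_minimize

from .model import ConcSeries, RotExtCurve

#: tether length (bp) of the reference magnetic-tweezers construct
TETHER_BP = 7900

# ---------------------------------------------------------------------------
# Gaussian center finding
# ---------------------------------------------------------------------------


@dataclass
class GaussianFit:
    """Result of fitting z(n) = z0 + a exp(-(n - N_max)^2 / (2 w^2))."""

    n_max: float
    width: float
    amplitude: float
    offset: float
    covar: np.ndarray | None
    window: tuple[float, float]
    reduced_chi2: float | None = None
    weighted: bool = True

    @property
    def n_max_se(self) -> float | None:
        if self.covar is None:
            return None
        return float(np.sqrt(self.covar[0, 0]))


class FitError(RuntimeError):
    """Nonlinear fit failed to converge or the data admit no peak."""


def gaussian_fit(curve: RotExtCurve, window: float | None = None) -> GaussianFit:
    """Locate the torsionally relaxed point of a rotation-extension curve.

    Weighted least squares of a Gaussian over the full curve (the default
    protocol); ``window`` optionally restricts the fit to ``n_max_guess +/-
    window`` turns since plectonemic wings are not Gaussian.  Falls back to
    unweighted residuals when the curve carries no per-point SDs.
    """
    turns = curve.turns
    ext = curve.ext_um
    if len(turns) < 5:
        raise ValueError("need at least 5 points")
    imax = int(np.argmax(ext))
    if imax == 0 or imax == len(turns) - 1:
        raise FitError("extension is monotonic over the scanned turns: no peak to fit")
    guess_center = turns[imax]
    mask = np.ones_like(turns, dtype=bool)
    if window is not None:
        mask = np.abs(turns - guess_center) <= window
        if mask.sum() < 5:
            raise ValueError("fit window contains fewer than 5 points")
    t, z = turns[mask], ext[mask]
    weighted = curve.ext_sd is not None and np.all(np.isfinite(curve.ext_sd)) and np.all(curve.ext_sd > 0)
    sd = curve.ext_sd[mask] if weighted else np.ones_like(z)

    span = t[-1] - t[0]
    params = Parameters()
    params.add("n_max", value=float(guess_center), min=float(t[0]), max=float(t[-1]))
    params.add("width", value=float(span / 4.0), min=1e-6)
    params.add("amplitude", value=float(z.max() - z.min()), min=1e-12)
    params.add("offset", value=float(z.min()))

    def resid(p):
        model = p["offset"] + p["amplitude"] * np.exp(
            -((t - p["n_max"]) ** 2) / (2.0 * p["width"] ** 2)
        )
        return (z - model) / sd

    out = lm_minimize(resid, params)
    if not out.success:
        raise FitError(f"Gaussian fit did not converge: {out.message}")
    v = out.params.valuesdict()
    covar = out.covar if out.covar is not None else None
    if covar is not None:
        order = ["n_max", "width", "amplitude", "offset"]
        names = list(out.var_names)
        perm = [names.index(k) for k in order if k in names]
        covar = covar[np.ix_(perm, perm)]
    redchi = float(out.redchi) if weighted else None
    return GaussianFit(
        n_max=float(v["n_max"]),
        width=float(v["width"]),
        amplitude=float(v["amplitude"]),
        offset=float(v["offset"]),
        covar=covar,
        window=(float(t[0]), float(t[-1])),
        reduced_chi2=redchi,
        weighted=weighted,
    )


def delta_twist(n_max: float, n_max_ref: float, n_bp: int = TETHER_BP) -> float:
    """Twist change per bp (deg) from the shift of the relaxed turn count.

    Positive values mean overwinding (the relaxed point moved to positive
    turns relative to the reference condition).
    """
    if n_bp <= 0:
        raise ValueError("n_bp must be positive")
    return 360.0 * (n_max - n_max_ref) / n_bp


# ---------------------------------------------------------------------------
# Concentration-response models
# ---------------------------------------------------------------------------


@dataclass
class ConcModelFit:
    """A fitted concentration-response model with its reduced chi-square."""

    model: str  # "power_law" | "log_linear"
    params: dict[str, float]
    reduced_chi2: float
    n_points: int
    n_free: int
    fixed: dict[str, float] = field(default_factory=dict)
    data_hash: str = ""

    def predict(self, conc_mM: np.ndarray) -> np.ndarray:
        c = np.asarray(conc_mM, dtype=float)
        if self.model == "power_law":
            return self.params["A"] * np.power(c, self.params["B"]) + self.params["C"]
        return self.params["slope"] * np.log10(c) + self.params["intercept"]


def _series_hash(series: ConcSeries) -> str:
    h = hashlib.sha256()
    for a in (series.conc_mM, series.dtw_deg_bp, series.sigma):
        h.update(np.ascontiguousarray(a).tobytes())
    return h.hexdigest()[:16]


def fit_power_law(series: ConcSeries, fix_B: float | None = None) -> ConcModelFit:
    """Weighted least squares of dTw = A c^B + C.

    The exponent is multi-started over B in {0.1, ..., 1.0} to avoid the
    A-B degeneracy trapping the fit in a local minimum (ties broken by
    lowest chi-square, then smallest B); ``fix_B`` freezes the exponent.
    """
    c, y, sd = series.conc_mM, series.dtw_deg_bp, series.sigma
    k = 2 if fix_B is not None else 3
    if len(c) <= k:
        raise ValueError(f"need more than {k} points for a {k}-parameter fit")

    def resid(p):
        return (y - (p["A"] * np.power(c, p["B"]) + p["C"])) / sd

    best = None
    starts = [fix_B] if fix_B is not None else list(np.arange(0.1, 1.01, 0.1))
    for b0 in starts:
        params = Parameters()
        scale = max(abs(y.max() - y.min()), 1e-6)
        params.add("A", value=scale / np.power(c.max(), b0))
        params.add("B", value=float(b0), min=1e-3, max=5.0, vary=fix_B is None)
        params.add("C", value=float(y.min()))
        out = lm_minimize(resid, params)
        if not out.success:
            continue
        chisqr = float(out.chisqr)
        bval = float(out.params["B"].value)
        key = (round(chisqr, 12), bval)
        if best is None or key < best[0]:
            best = (key, out)
    if best is None:
        raise FitError("power-law fit did not converge from any start")
    out = best[1]
    v = out.params.valuesdict()
    dof = len(c) - k
    return ConcModelFit(
        model="power_law",
        params={"A": float(v["A"]), "B": float(v["B"]), "C": float(v["C"])},
        reduced_chi2=float(out.chisqr / dof),
        n_points=len(c),
        n_free=k,
        fixed={} if fix_B is None else {"B": float(fix_B)},
        data_hash=_series_hash(series),
    )


def fit_log_linear(series: ConcSeries) -> ConcModelFit:
    """Weighted linear regression of dTw on log10(c), closed form.

    Solves the 2-parameter weighted normal equations directly; raises on
    fewer than 3 points or a rank-deficient design (identical
    concentrations).
    """
    c, y, sd = series.conc_mM, series.dtw_deg_bp, series.sigma
    if len(c) < 3:
        raise ValueError("need at least 3 points")
    x = np.log10(c)
    if np.ptp(x) < 1e-12:
        raise np.linalg.LinAlgError("identical concentrations: design is rank-deficient")
    w = 1.0 / sd**2
    X = np.stack([x, np.ones_like(x)], axis=1)
    A = X.T @ (w[:, None] * X)
    b = X.T @ (w * y)
    slope, intercept = np.linalg.solve(A, b)
    resid = (y - (slope * x + intercept)) / sd
    dof = len(c) - 2
    return ConcModelFit(
        model="log_linear",
        params={"slope": float(slope), "intercept": float(intercept)},
        reduced_chi2=float(np.sum(resid**2) / dof),
        n_points=len(c),
        n_free=2,
        data_hash=_series_hash(series),
    )


#: reduced-chi-square ratio below which two fits are flagged indistinguishable
TIE_RATIO = 1.5


def compare_models(fits: list[ConcModelFit]) -> list[ConcModelFit]:
    """Rank fits of the same data by reduced chi-square (best first).

    Raises if the fits were made on different data; warns when the two best
    fits differ by less than :data:`TIE_RATIO` in reduced chi-square.
    """
    if not fits:
        raise ValueError("no fits to compare")
    if len(fits) == 1:
        return list(fits)
    hashes = {f.data_hash for f in fits if f.data_hash}
    if len(hashes) > 1:
        raise ValueError("fits were made on different data series")
    ranked = sorted(fits, key=lambda f: f.reduced_chi2)
    best, second = ranked[0].reduced_chi2, ranked[1].reduced_chi2
    if best <= 0:
        if second <= 0:
            warnings.warn("tied fits: both reduced chi-squares are zero", stacklevel=2)
    elif second / best < TIE_RATIO:
        warnings.warn(
            f"fits are statistically indistinguishable (chi2 ratio {second / best:.2f} < {TIE_RATIO})",
            stacklevel=2,
        )
    return ranked


def molecule_average(dtw_values) -> tuple[float, float]:
    """Mean and SD of per-molecule twist changes at one condition."""
    v = np.asarray(list(dtw_values), dtype=float)
    if v.size < 2:
        return float(v.mean()), 0.0
    return float(v.mean()), float(v.std(ddof=1))
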