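"""EMSA quantification and quadratic single-site binding fits.

NELF release from the paused elongation complex (PEC) is read out on native
gels as the appearance of the Pol II-DSIF band.  Plotting the released
fraction against eRNA concentration yields a pseudo-binding curve; because
eRNA and PEC concentrations are comparable, the ligand-depletion (quadratic)
form of the single-site model is fitted rather than the hyperbolic one:

    f(L) = A * (R + L + Kd - sqrt((R + L + Kd)^2 - 4 R L)) / (2 R)

with R the total PEC concentration (0.1 uM in the standard assay), L the
total eRNA concentration, A the amplitude and Kd the apparent dissociation
constant.  Kd is "apparent": the curve is a dissociation readout, not an
equilibrium titration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

#: eRNA concentration series of the standard release assay, in uM.
STANDARD_CONCENTRATIONS = (0.15, 0.3, 0.6, 0.9, 1.2, 1.8)
#: Total PEC concentration of the standard assay, in uM.
STANDARD_RECEPTOR_TOTAL = 0.1


@dataclass
class BindingCurve:
    """Released fractions observed over an eRNA concentration series."""

    concentrations: np.ndarray
    fractions: np.ndarray
    receptor_total: float = STANDARD_RECEPTOR_TOTAL

    def __post_init__(self) -> None:
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        self.fractions = np.asarray(self.fractions, dtype=float)
        if self.concentrations.shape != self.fractions.shape:
            raise ValueError("concentrations and fractions must have equal length")
        if self.concentrations.ndim != 1:
            raise ValueError("curve data must be one-dimensional")
        if np.any(self.concentrations <= 0):
            raise ValueError("ligand concentrations must be positive")
        if np.any(np.diff(self.concentrations) <= 0):
            raise ValueError("concentrations must be strictly increasing")
        if np.any((self.fractions < 0) | (self.fractions > 1)):
            raise ValueError("fractions must lie in [0, 1]")
        if self.receptor_total <= 0:
            raise ValueError("receptor_total must be positive")


@dataclass
class BindingFit:
    """Result of a quadratic single-site fit."""

    kd: float
    amplitude: float
    residual_sum: float
    converged: bool
    kd_stderr: float = float("nan")
    message: str = ""


@dataclass
class LaneQuant:
    """Densitometry of one gel lane: band intensities plus a target band."""

    intensities: np.ndarray
    target_index: int = 0

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if np.any(self.intensities < 0):
            raise ValueError("band intensities must be >= 0")
        if not 0 <= self.target_index < self.intensities.size:
            raise IndexError("target_index out of range")

    @property
    def total(self) -> float:
        return float(self.intensities.sum())

    @property
    def target_fraction(self) -> float:
        """Target-band intensity over total lane intensity (nan if empty lane)."""
        if self.total == 0:
            warnings.warn("lane has zero total intensity; fraction undefined")
            return float("nan")
        return float(self.intensities[self.target_index] / self.total)


def release_fraction(i_poldsif: float, i_pec: float) -> float:
    """Released (Pol II-DSIF) fraction from the two band intensities.

    fraction = (Pol II-DSIF) / ((Pol II-DSIF) + (Pol II-DSIF-NELF))
    """
    if i_poldsif < 0 or i_pec < 0:
        raise ValueError("band intensities must be >= 0")
    total = i_poldsif + i_pec
    if total == 0:
        warnings.warn("both bands empty; release fraction undefined")
        return float("nan")
    return i_poldsif / total


def quadratic_model(ligand_total, kd: float, amplitude: float = 1.0,
                    receptor_total: float = STANDARD_RECEPTOR_TOTAL):
    """Ligand-depletion single-site binding model.

    Returns the bound (= released) fraction for total ligand concentration(s)
    ``ligand_total``; vectorized over ``ligand_total``.
    """
    L = np.asarray(ligand_total, dtype=float)
    if np.any(L < 0):
        raise ValueError("ligand concentrations must be >= 0")
    if kd <= 0:
        raise ValueError("kd must be positive")
    if receptor_total <= 0:
        raise ValueError("receptor_total must be positive")
    s = receptor_total + L + kd
    disc = s * s - 4.0 * receptor_total * L
    if np.any(disc < 0):  # impossible for valid inputs; guards rounding bugs
        raise FloatingPointError("negative discriminant in quadratic model")
    occupancy = (s - np.sqrt(disc)) / (2.0 * receptor_total)
    out = amplitude * occupancy
    return float(out) if np.isscalar(ligand_total) else out


def fit_binding(curve: BindingCurve, fix_amplitude: float | None = None,
                max_amplitude: float = 1.2, n_multistart: int = 5) -> BindingFit:
    """Nonlinear least-squares fit of (Kd, amplitude) to a release curve.

    Amplitude is fitted by default (gels rarely reach complete conversion);
    pass ``fix_amplitude=1.0`` for the constrained variant.  Initialization
    uses the concentration nearest half-maximal release, refined by a
    multistart over log-spaced Kd values; the best residual wins.
    """
    L = curve.concentrations
    y = curve.fractions
    if L.size < 3:
        raise ValueError("need at least 3 concentration points to fit")
    if np.ptp(y) == 0.0:
        return BindingFit(float("nan"), float("nan"), float("nan"), False,
                          message="flat curve: Kd unidentifiable")

    R = curve.receptor_total
    ymax = float(y.max())
    half = ymax / 2.0
    kd0 = float(L[np.argmin(np.abs(y - half))])
    kd_starts = [kd0] + list(np.geomspace(L.min() / 10.0, L.max() * 10.0,
                                          n_multistart))
    amp0 = min(max(ymax, 1e-3), max_amplitude)

    def residuals(params):
        kd = params[0]
        amp = params[1] if fix_amplitude is None else fix_amplitude
        return quadratic_model(L, kd, amp, R) - y

    best = None
    for kd_start in kd_starts:
        if fix_amplitude is None:
            x0 = [kd_start, amp0]
            bounds = ([1e-9, 1e-6], [np.inf, max_amplitude])
        else:
            x0 = [kd_start]
            bounds = ([1e-9], [np.inf])
        try:
            res = least_squares(residuals, x0, bounds=bounds,
                                xtol=1e-14, ftol=1e-14, gtol=1e-14)
        except Exception:  # a bad start must not kill the multistart
            continue
        if res.success and (best is None or res.cost < best.cost):
            best = res

    if best is None:
        return BindingFit(float("nan"), float("nan"), float("nan"), False,
                          message="no multistart converged")

    kd_hat = float(best.x[0])
    amp_hat = float(best.x[1]) if fix_amplitude is None else float(fix_amplitude)
    rss = float(2.0 * best.cost)
    kd_stderr = _kd_stderr(best.jac, best.fun, L.size,
                           2 if fix_amplitude is None else 1)
    return BindingFit(kd_hat, amp_hat, rss, True, kd_stderr=kd_stderr,
                      message=best.message)


def _kd_stderr(jac: np.ndarray, resid: np.ndarray, n: int, p: int) -> float:
    """Standard error of Kd from the Jacobian curvature at the optimum."""
    dof = n - p
    if dof <= 0:
        return float("nan")
    try:
        jtj_inv = np.linalg.inv(jac.T @ jac)
    except np.linalg.LinAlgError:
        return float("nan")
    sigma2 = float(resid @ resid) / dof
    var = sigma2 * jtj_inv[0, 0]
    return float(np.sqrt(var)) if var >= 0 else float("nan")


def fit_binding_replicates(curves: list[BindingCurve],
                           mode: str = "mean", **kwargs) -> BindingFit:
    """Fit replicate curves, either on the pointwise mean or pooled.

    ``mode='mean'`` matches quantification that plots the mean of
    experimental replicates before fitting; ``mode='pooled'`` stacks all
    observations into one residual vector.
    """
    if not curves:
        raise ValueError("no curves supplied")
    ref = curves[0]
    for c in curves[1:]:
        if not np.array_equal(c.concentrations, ref.concentrations):
            raise ValueError("replicate curves must share the concentration series")
        if c.receptor_total != ref.receptor_total:
            raise ValueError("replicate curves must share receptor_total")
    if mode == "mean":
        mean_y = np.mean([c.fractions for c in curves], axis=0)
        merged = BindingCurve(ref.concentrations, mean_y, ref.receptor_total)
        return fit_binding(merged, **kwargs)
    if mode == "pooled":
        # replicate points at the same L: sort stably to keep concentrations valid
        L = np.concatenate([c.concentrations for c in curves])
        y = np.concatenate([c.fractions for c in curves])
        order = np.argsort(L, kind="stable")
        L, y = L[order], y[order]
        # BindingCurve requires strictly increasing L; fit directly instead.
        curve = BindingCurve.__new__(BindingCurve)
        curve.concentrations = L
        curve.fractions = y
        curve.receptor_total = ref.receptor_total
        return fit_binding(curve, **kwargs)
    raise ValueError(f"unknown replicate mode {mode!r}")


def pause_release_timecourse(lanes: list[LaneQuant], times) -> "pd.DataFrame":
    """Released fraction per time point of a pause-release assay.

    Per lane the intensity of the first band above the pause site is divided
    by the total intensity of that lane.
    """
    import pandas as pd

    times = np.asarray(times, dtype=float)
    if times.size != len(lanes):
        raise ValueError("need exactly one lane per time point")
    if np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")
    fractions = [lane.target_fraction for lane in lanes]
    return pd.DataFrame({"time_min": times, "released_fraction": fractions})
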