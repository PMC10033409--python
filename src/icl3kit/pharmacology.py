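"""Receptor pharmacology: binding and dose-response curve fits and assay
signal processing.

Covers the quantitative readouts used to characterize ICL3 mutants and
chimeras:

* saturation radioligand binding, bound = Bmax * L / (Kd + L);
* one- and two-site competition (displacement) of a tracer by an unlabelled
  ligand on a log10 concentration axis, with the Cheng-Prusoff conversion
  Ki = IC50 / (1 + L/KD);
* the four-parameter Hill dose-response
  E = (Emax - Emin) / (1 + 10^((logEC50 - logL) * NH)) + Emin,
  with agonist efficacy summarized as log10(Emax / EC50);
* difference metrics for ratiometric FRET / HTRF assays (treated minus
  buffer means), pulldown percent-bound, luciferase kinetic-trace smoothing
  and normalization, and the |Z| > 3 outlier rule applied to flagged
  replicates only.

Concentrations are molar unless a function says otherwise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "SaturationFit",
    "CompetitionFit",
    "HillFit",
    "KineticResult",
    "fit_saturation",
    "fit_competition",
    "cheng_prusoff",
    "fit_hill",
    "delta_metric",
    "fret_ratio",
    "percent_bound",
    "process_kinetic_trace",
    "zscore_outlier_filter",
]


@dataclass
class SaturationFit:
    Bmax: float
    Kd: float
    flags: list[str] = field(default_factory=list)


@dataclass
class CompetitionFit:
    """One- or two-site displacement fit on log10 competitor concentration.

    For two-site fits ``F1`` is the fraction of sites with affinity
    ``IC50_1`` and ``ic50`` holds the weighted-average IC50 used for
    comparisons and Ki conversion.
    """

    Bmax: float
    Bmin: float
    sites: int
    ic50: float
    F1: float | None = None
    ic50_1: float | None = None
    ic50_2: float | None = None
    Ki: float | None = None
    flags: list[str] = field(default_factory=list)


@dataclass
class HillFit:
    Emax: float
    Emin: float
    ec50: float
    hill: float
    flags: list[str] = field(default_factory=list)

    @property
    def efficacy(self) -> float:
        """log10(Emax / EC50), the coupling-efficiency summary statistic."""
        if self.Emax <= 0:
            raise ValueError("efficacy undefined for Emax <= 0")
        return float(np.log10(self.Emax / self.ec50))


@dataclass
class KineticResult:
    smoothed: np.ndarray
    normalized: np.ndarray
    plateau: float
    specific_signal: float
    windows: tuple[int, int]
    flags: list[str] = field(default_factory=list)


def fit_saturation(L: Sequence[float], bound: Sequence[float]) -> SaturationFit:
    """Fit specific binding to bound = Bmax * L / (Kd + L)."""
    L = np.asarray(L, dtype=float)
    bound = np.asarray(bound, dtype=float)
    if L.size < 4:
        raise ValueError("need at least 4 tracer concentrations")

    def model(x, bmax, kd):
        return bmax * x / (kd + x)

    p0 = (max(bound.max(), 1e-12), np.median(L))
    popt, _ = curve_fit(model, L, bound, p0=p0, bounds=([0, 0], [np.inf, np.inf]),
                        maxfev=10000)
    fit = SaturationFit(Bmax=float(popt[0]), Kd=float(popt[1]))
    if not (L.min() / 100 <= fit.Kd <= L.max() * 100):
        fit.flags.append("Kd outside tested range x100")
    return fit


def _one_site(A, bmax, bmin, log_ic50):
    return (bmax - bmin) / (1.0 + 10.0 ** (A - log_ic50)) + bmin


def _two_site(A, bmax, bmin, f1, log_ic50_1, log_ic50_2):
    span = bmax - bmin
    return (
        f1 * span / (1.0 + 10.0 ** (A - log_ic50_1))
        + (1.0 - f1) * span / (1.0 + 10.0 ** (A - log_ic50_2))
        + bmin
    )


def fit_competition(
    A: Sequence[float],
    Y: Sequence[float],
    sites: int = 1,
    tracer_L: float | None = None,
    tracer_KD: float | None = None,
    weighted_average: str = "linear",
) -> CompetitionFit:
    """Fit a displacement curve; A is log10 molar competitor concentration,
    Y the percentage of tracer bound.

    Two-site fits report F1, both IC50s, and a weighted-average IC50
    (linear weighting F1*IC50_1 + (1-F1)*IC50_2 by default, or on the log
    scale with ``weighted_average="log"``). If tracer concentration and KD
    are given, Ki is attached via Cheng-Prusoff.
    """
    A = np.asarray(A, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if sites not in (1, 2):
        raise ValueError("sites must be 1 or 2")
    bmax0, bmin0 = float(Y.max()), float(Y.min())
    mid0 = float(A[np.argmin(np.abs(Y - (bmax0 + bmin0) / 2))])

    if sites == 1:
        popt, _ = curve_fit(
            _one_site, A, Y, p0=(bmax0, bmin0, mid0),
            bounds=([-np.inf, -np.inf, A.min() - 6], [np.inf, np.inf, A.max() + 6]),
            maxfev=20000,
        )
        fit = CompetitionFit(
            Bmax=float(popt[0]), Bmin=float(popt[1]), sites=1, ic50=10.0 ** popt[2]
        )
    else:
        popt, _ = curve_fit(
            _two_site, A, Y, p0=(bmax0, bmin0, 0.5, mid0 - 1.5, mid0 + 1.5),
            bounds=(
                [-np.inf, -np.inf, 0.0, A.min() - 6, A.min() - 6],
                [np.inf, np.inf, 1.0, A.max() + 6, A.max() + 6],
            ),
            maxfev=40000,
        )
        f1 = float(popt[2])
        ic1, ic2 = 10.0 ** popt[3], 10.0 ** popt[4]
        if ic1 > ic2:  # report the high-affinity site first
            ic1, ic2, f1 = ic2, ic1, 1.0 - f1
        if weighted_average == "linear":
            ic50 = f1 * ic1 + (1.0 - f1) * ic2
        elif weighted_average == "log":
            ic50 = 10.0 ** (f1 * np.log10(ic1) + (1.0 - f1) * np.log10(ic2))
        else:
            raise ValueError("weighted_average must be 'linear' or 'log'")
        fit = CompetitionFit(
            Bmax=float(popt[0]), Bmin=float(popt[1]), sites=2,
            ic50=float(ic50), F1=f1, ic50_1=float(ic1), ic50_2=float(ic2),
        )
        if f1 < 0.01 or f1 > 0.99:
            fit.flags.append("F1 pinned near 0/1; a one-site fit is recommended")
    if tracer_L is not None and tracer_KD is not None:
        fit.Ki = cheng_prusoff(fit.ic50, tracer_L, tracer_KD)
    return fit


def cheng_prusoff(ic50: float, L: float, KD: float) -> float:
    """Ki = IC50 / (1 + L/KD), all on the same (molar) concentration scale."""
    if ic50 <= 0 or L <= 0 or KD <= 0:
        raise ValueError("ic50, L and KD must be positive")
    return ic50 / (1.0 + L / KD)


def fit_hill(L: Sequence[float], E: Sequence[float]) -> HillFit:
    """Fit the four-parameter Hill dose-response on a molar concentration grid.

    E = (Emax - Emin) / (1 + 10^((logEC50 - logL) * NH)) + Emin.
    """
    L = np.asarray(L, dtype=float)
    E = np.asarray(E, dtype=float)
    if L.size < 5:
        raise ValueError("need at least 5 concentrations")
    if np.any(L <= 0):
        raise ValueError("concentrations must be positive")
    logL = np.log10(L)

    def model(x, emax, emin, log_ec50, nh):
        return (emax - emin) / (1.0 + 10.0 ** ((log_ec50 - x) * nh)) + emin

    p0 = (float(E.max()), float(E.min()), float(np.median(logL)), 1.0)
    popt, _ = curve_fit(
        model, logL, E, p0=p0,
        bounds=([-np.inf, -np.inf, logL.min() - 6, 0.05],
                [np.inf, np.inf, logL.max() + 6, 10.0]),
        maxfev=20000,
    )
    fit = HillFit(Emax=float(popt[0]), Emin=float(popt[1]),
                  ec50=10.0 ** popt[2], hill=float(popt[3]))
    if not (L.min() / 100 <= fit.ec50 <= L.max() * 100):
        fit.flags.append("EC50 extrapolated outside tested range x100")
    return fit


def fret_ratio(donor: float, acceptor: float) -> float:
    """Acceptor/donor emission ratio of a ratiometric FRET or HTRF reading."""
    if donor <= 0:
        raise ValueError("donor emission must be positive")
    return acceptor / donor


def delta_metric(treated: Sequence[float], reference: Sequence[float]) -> float:
    """mean(treated) - mean(reference): the dFRET / InsP1 / cAMP difference
    metric (treated condition minus its matched no-drug or buffer arm)."""
    treated = np.asarray(treated, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if treated.size == 0 or reference.size == 0:
        raise ValueError("both arms need at least one measurement")
    return float(treated.mean() - reference.mean())


def percent_bound(total_peak: float, supernatant_peaks: Sequence[float]) -> float:
    """Pulldown percent bound: 100 * (total - mean(supernatant)) / total.

    Values outside [0, 100] are reported as-is with a warning (depleted or
    noisy supernatants), never clamped.
    """
    if total_peak <= 0:
        raise ValueError("total_peak must be positive")
    sup = np.asarray(supernatant_peaks, dtype=float)
    pct = 100.0 * (total_peak - sup.mean()) / total_peak
    if not 0.0 <= pct <= 100.0:
        warnings.warn(f"percent bound {pct:.1f} outside [0, 100]")
    return float(pct)


def _moving_average(x: np.ndarray, window: int) -> np.ndarray:
    if x.size == 0:
        return x
    kernel = np.ones(window) / window
    # centred window with shrunken edges (pandas-style min_periods=1)
    padded = np.convolve(x, kernel, mode="same")
    # fix edge normalization
    counts = np.convolve(np.ones_like(x), kernel, mode="same")
    return padded / counts


def process_kinetic_trace(
    time: Sequence[float],
    luminescence: Sequence[float],
    drug_addition_index: int,
    control_value: float,
    pre_window: int = 3,
    post_window: int = 8,
    stability_tol: float = 0.05,
) -> KineticResult:
    """Smooth, normalize and summarize a luciferase-complementation trace.

    The pre-drug equilibration is smoothed with a ``pre_window``-point moving
    average and the post-drug phase with a ``post_window``-point one; the
    whole trace is divided by the last smoothed pre-drug point. The plateau
    is the maximum smoothed post-drug value whose next three smoothed points
    stay within ``stability_tol`` (relative); the specific signal is plateau
    minus ``control_value`` (the matched no-peptide construct).
    """
    t = np.asarray(time, dtype=float)
    y = np.asarray(luminescence, dtype=float)
    if t.shape != y.shape:
        raise ValueError("time and luminescence must match")
    if np.any(np.diff(t) <= 0):
        raise ValueError("time must be strictly increasing")
    if not 0 < drug_addition_index < t.size:
        raise ValueError("drug_addition_index out of range")
    n_post = t.size - drug_addition_index
    if n_post < post_window:
        raise ValueError(f"need >= {post_window} points after drug addition")

    pre = _moving_average(y[:drug_addition_index], pre_window)
    post = _moving_average(y[drug_addition_index:], post_window)
    smoothed = np.concatenate([pre, post])
    baseline = pre[-1]
    if baseline <= 0:
        raise ValueError("non-positive pre-drug baseline")
    normalized = smoothed / baseline

    post_norm = normalized[drug_addition_index:]
    flags: list[str] = []
    plateau = None
    for i in range(post_norm.size - 3):
        v = post_norm[i]
        follow = post_norm[i + 1 : i + 4]
        if v != 0 and np.all(np.abs(follow - v) / abs(v) < stability_tol):
            plateau = v if plateau is None else max(plateau, v)
    if plateau is None:
        plateau = float(post_norm[-1])
        flags.append("no stable plateau found; using last smoothed point")
    specific = float(plateau) - control_value
    if specific < 0:
        flags.append("negative specific signal")
    return KineticResult(
        smoothed=smoothed,
        normalized=normalized,
        plateau=float(plateau),
        specific_signal=specific,
        windows=(pre_window, post_window),
        flags=flags,
    )


def zscore_outlier_filter(
    values: Sequence[float], flags: Sequence[bool], threshold: float = 3.0
) -> tuple[np.ndarray, np.ndarray]:
    """Drop flagged replicates that are |Z| > threshold outliers.

    Only samples flagged as suspect (e.g. poorly matched cell density or
    expression) are eligible for removal; the Z-score of each candidate is
    computed against the other replicates (leave-one-out mean and sd). With
    zero variance among comparators nothing is removed. Returns the retained
    values and a boolean keep-mask.
    """
    vals = np.asarray(values, dtype=float)
    flg = np.asarray(flags, dtype=bool)
    if vals.shape != flg.shape:
        raise ValueError("values and flags must have the same length")
    keep = np.ones(vals.size, dtype=bool)
    for i in np.flatnonzero(flg):
        others = np.delete(vals, i)
        if others.size < 2:
            warnings.warn("too few comparators for a Z-score; keeping sample")
            continue
        sd = others.std(ddof=1)
        if sd == 0:
            warnings.warn("zero variance among comparators; keeping sample")
            continue
        if abs((vals[i] - others.mean()) / sd) > threshold:
            keep[i] = False
    return vals[keep], keep
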