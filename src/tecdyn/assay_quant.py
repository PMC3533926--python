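"""Quantification of in vitro transcription readouts from tabular data.

Three assay families are covered:

* **Bulk elongation**: runoff RNA accumulation sampled at a few time points
  (typically 5, 10, 20, 40 s) is fit with a single-phase rising exponential
  ``f(t) = A (1 - exp(-k t))``; the rate constant ``k`` (1/s) and its
  asymptotic standard error summarize elongation speed, usually reported
  relative to wild type.
* **Competition fidelity**: a limiting correct NTP competes with an excess
  incorrect NTP; the misincorporated fraction is read from gel band
  intensities of correct (e.g. G10) vs error (e.g. A*10) products.
* **Exonuclease III footprinting**: pre- and post-translocated band
  intensities give the translocation-state fractions of a stalled complex,
  and the fold change upon adding the incoming NTP measures NTP-driven
  stabilization of the post-translocated state (e.g. the post fraction
  moving from 25% to 51% is a 2.04-fold increase).

Band backgrounds are assumed pre-subtracted.  All fractions and ratios are
invariant to rescaling every intensity in a lane by a common factor.

Input tables are delimited text: ``(enzyme, time_s, fraction)`` for runoff
courses and ``(lane, band, intensity)`` for gels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "RunoffCourse",
    "BandTable",
    "RunoffFit",
    "fit_runoff_exponential",
    "relative_elongation_rate",
    "misincorporation_ratio",
    "translocation_state_fractions",
    "ntp_stimulation",
    "read_runoff_courses",
    "read_band_tables",
]


@dataclass
class RunoffCourse:
    """A runoff accumulation time course for one enzyme."""

    times: np.ndarray  # s, strictly increasing
    runoff_fraction: np.ndarray  # in [0, 1]
    enzyme: str = ""

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.runoff_fraction = np.asarray(self.runoff_fraction, dtype=float)
        if self.times.shape != self.runoff_fraction.shape:
            raise ValueError("times and fractions must have equal length")
        if len(self.times) > 1 and not np.all(np.diff(self.times) > 0):
            raise ValueError("times must be strictly increasing")
        if np.any((self.runoff_fraction < 0) | (self.runoff_fraction > 1)):
            raise ValueError("runoff fractions must lie in [0, 1]")


@dataclass
class BandTable:
    """Quantified band intensities for one gel lane."""

    lane: str
    bands: dict  # band label -> nonnegative intensity

    def __post_init__(self):
        if len(self.bands) < 2:
            raise ValueError("a band table needs at least two bands")
        for k, v in self.bands.items():
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"band {k!r}: intensity must be finite and nonnegative")


@dataclass
class RunoffFit:
    k: float  # 1/s
    amplitude: float
    k_stderr: float
    amplitude_stderr: float
    residual: float  # sum of squared residuals
    flagged: bool = False  # k <= 0 or otherwise degenerate
    message: str = ""

    def predict(self, t):
        return self.amplitude * (1.0 - np.exp(-self.k * np.asarray(t, float)))


def _runoff_model(t, A, k):
    return A * (1.0 - np.exp(-k * t))


def fit_runoff_exponential(
    course: RunoffCourse,
    fix_amplitude: float | None = None,
    noise_sigma: float | None = None,
) -> RunoffFit:
    """Least-squares single-phase exponential fit of a runoff time course.

    Returns the rate ``k`` with the amplitude free by default
    (``fix_amplitude`` pins it, e.g. to 1).  Standard errors come from the
    asymptotic fit covariance; with only a few time points the residual-based
    noise estimate is poor, so ``noise_sigma`` lets a known measurement error
    be used instead (absolute-sigma covariance).  A non-positive or boundary
    rate is returned flagged rather than raised; genuine non-convergence
    raises RuntimeError with scipy's diagnostics.
    """
    t = course.times
    y = course.runoff_fraction
    if len(t) < 3:
        raise ValueError("need at least 3 time points for an exponential fit")
    if np.allclose(y, 0):
        return RunoffFit(0.0, 0.0, np.nan, np.nan, 0.0, flagged=True,
                         message="all fractions zero: rate undetermined")
    # Initial guess: amplitude from the plateau, rate from the earliest rise.
    a0 = max(float(y.max()), 1e-3)
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.clip(y / a0, None, 0.999)
        k0s = -np.log(1.0 - frac) / t
    k0 = float(np.nanmedian(k0s[np.isfinite(k0s) & (k0s > 0)])) if np.any(k0s > 0) else 0.1

    sigma_kw = {}
    if noise_sigma is not None:
        sigma_kw = {"sigma": np.full(len(t), noise_sigma), "absolute_sigma": True}
    if fix_amplitude is not None:
        def model(tt, k):
            return _runoff_model(tt, fix_amplitude, k)

        popt, pcov = curve_fit(model, t, y, p0=[k0], maxfev=10000, **sigma_kw)
        k = float(popt[0])
        A, a_err = float(fix_amplitude), 0.0
        k_err = float(np.sqrt(pcov[0, 0]))
        resid = float(np.sum((y - model(t, k)) ** 2))
    else:
        popt, pcov = curve_fit(_runoff_model, t, y, p0=[a0, k0], maxfev=10000, **sigma_kw)
        A, k = (float(v) for v in popt)
        a_err, k_err = (float(np.sqrt(pcov[i, i])) for i in (0, 1))
        resid = float(np.sum((y - _runoff_model(t, A, k)) ** 2))
    flagged = k <= 0
    return RunoffFit(k, A, k_err, a_err, resid, flagged=flagged,
                     message="non-positive rate at optimum" if flagged else "")


def relative_elongation_rate(mutant: RunoffFit, wildtype: RunoffFit):
    """k_mut / k_wt with first-order error propagation.

    Returns (ratio, ratio_stderr).
    """
    if wildtype.flagged or abs(wildtype.k) < 1e-12:
        raise ValueError("wild-type rate is zero or degenerate; ratio undefined")
    ratio = mutant.k / wildtype.k
    rel_var = 0.0
    if np.isfinite(mutant.k_stderr) and mutant.k != 0:
        rel_var += (mutant.k_stderr / mutant.k) ** 2
    if np.isfinite(wildtype.k_stderr):
        rel_var += (wildtype.k_stderr / wildtype.k) ** 2
    return ratio, abs(ratio) * float(np.sqrt(rel_var))


def misincorporation_ratio(
    bands: BandTable, correct: str = "G10", error: str = "A*10"
) -> float:
    """Error fraction error/(error+correct) from a competition-assay lane.

    Raises KeyError for missing bands and ValueError when both are zero
    (undefined fraction).
    """
    for b in (correct, error):
        if b not in bands.bands:
            raise KeyError(f"lane {bands.lane!r}: band {b!r} not present")
    c = bands.bands[correct]
    e = bands.bands[error]
    if c + e == 0:
        raise ValueError(f"lane {bands.lane!r}: both bands zero, error fraction undefined")
    return e / (e + c)


def translocation_state_fractions(
    bands: BandTable, pre: str = "pre", post: str = "post"
):
    """Normalized (pre, post) fractions from an exonuclease III lane."""
    for b in (pre, post):
        if b not in bands.bands:
            raise KeyError(f"lane {bands.lane!r}: band {b!r} not present")
    p, q = bands.bands[pre], bands.bands[post]
    total = p + q
    if total == 0:
        raise ValueError(f"lane {bands.lane!r}: zero total intensity")
    return p / total, q / total


def ntp_stimulation(post_without_ntp: float, post_with_ntp: float):
    """Fold change and percent increase of the post-translocated fraction
    upon adding the incoming NTP.

    ``ntp_stimulation(0.25, 0.51)`` -> (2.04, 104.0): the post fraction
    roughly doubles.
    """
    for name, v in (("post_without_ntp", post_without_ntp), ("post_with_ntp", post_with_ntp)):
        if not (0 < v <= 1):
            raise ValueError(f"{name} must lie in (0, 1], got {v}")
    fold = post_with_ntp / post_without_ntp
    percent = 100.0 * (post_with_ntp - post_without_ntp) / post_without_ntp
    return fold, percent


# ---------------------------------------------------------------------------
# Tabular I/O
# ---------------------------------------------------------------------------

def read_runoff_courses(path, sep: str = "\t") -> list[RunoffCourse]:
    """Read (enzyme, time_s, fraction) delimited text into courses."""
    df = pd.read_csv(path, sep=sep)
    required = {"enzyme", "time_s", "fraction"}
    if not required <= set(df.columns):
        raise ValueError(f"runoff table must have columns {sorted(required)}")
    out = []
    for enzyme, grp in df.groupby("enzyme", sort=False):
        grp = grp.sort_values("time_s")
        out.append(
            RunoffCourse(
                times=grp["time_s"].to_numpy(),
                runoff_fraction=grp["fraction"].to_numpy(),
                enzyme=str(enzyme),
            )
        )
    return out


def read_band_tables(path, sep: str = "\t") -> list[BandTable]:
    """Read (lane, band, intensity) delimited text into band tables."""
    df = pd.read_csv(path, sep=sep)
    required = {"lane", "band", "intensity"}
    if not required <= set(df.columns):
        raise ValueError(f"band table must have columns {sorted(required)}")
    out = []
    for lane, grp in df.groupby("lane", sort=False):
        out.append(
            BandTable(lane=str(lane), bands=dict(zip(grp["band"], grp["intensity"])))
        )
    return out
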