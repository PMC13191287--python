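"""Reader-domain binding quantification.

Fluorescence-polarization (FP) titrations are converted to anisotropy
(A = 2P / (3 - P)) and fitted with the hyperbolic single-site law

    A([L]) = Af + (Ab - Af) * [L] / (Kd + [L]),

where Af/Ab are the free/bound-probe anisotropies and [L] the protein
concentration.  Ligand depletion is neglected: the labelled probe (40 nM)
sits far below the Kd regime of these reader domains, so the total protein
concentration stands in for the free concentration.

Competition series (unlabelled peptide displacing a labelled probe) are
fitted with a four-parameter logistic on log10 competitor concentration;
the IC50 ranking across competitors is the primary readout, with an
optional Cheng-Prusoff conversion to Ki.

Peptide-array spot intensities are reduced to per-combination binding
relative to a reference combination, and flanking-modification effects are
classified as *switches* (abolish recognition), *rheostats* (graded
enhancement) or neutral.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.stats import spearmanr
from sklearn.base import BaseEstimator

__all__ = [
    "polarization_to_anisotropy",
    "anisotropy_to_polarization",
    "single_site_anisotropy",
    "SingleSiteBinding",
    "fit_single_site",
    "predict_anisotropy",
    "CompetitionCurve",
    "fit_competition",
    "cheng_prusoff_ki",
    "ModEffect",
    "quantify_array",
    "classify_mod_effect",
]


def polarization_to_anisotropy(P):
    """Convert fluorescence polarization P to anisotropy A = 2P/(3 - P)."""
    P = np.asarray(P, dtype=float)
    if np.any(P >= 3):
        raise ValueError("polarization must be < 3")
    out = 2.0 * P / (3.0 - P)
    return float(out) if out.ndim == 0 else out


def anisotropy_to_polarization(A):
    """Inverse conversion, P = 3A/(2 + A)."""
    A = np.asarray(A, dtype=float)
    out = 3.0 * A / (2.0 + A)
    return float(out) if out.ndim == 0 else out


def single_site_anisotropy(conc, kd, af, ab):
    """Hyperbolic single-site law Af + (Ab - Af) * c / (Kd + c)."""
    conc = np.asarray(conc, dtype=float)
    out = af + (ab - af) * conc / (kd + conc)
    return float(out) if out.ndim == 0 else out


class SingleSiteBinding(BaseEstimator):
    """Nonlinear least-squares fit of the single-site anisotropy law.

    Parameters
    ----------
    flat_tol : float
        Minimum anisotropy amplitude (max - min) below which the series is
        considered flat and Kd unidentifiable (raises ``ValueError``).
    init : tuple or None
        Optional (kd, af, ab) starting point; by default Af = min(A),
        Ab = max(A) and Kd = the concentration nearest mid-anisotropy.

    Fitted attributes
    -----------------
    kd_, af_, ab_ : float
        Dissociation constant (M) and anisotropy floor/ceiling.
    rss_ : float
        Residual sum of squares.
    converged_ : bool
    """

    def __init__(self, flat_tol: float = 1e-3, init=None, maxfev: int = 10000):
        self.flat_tol = flat_tol
        self.init = init
        self.maxfev = maxfev

    def fit(self, conc, A):
        conc = np.asarray(conc, dtype=float).ravel()
        A = np.asarray(A, dtype=float).ravel()
        if conc.shape != A.shape:
            raise ValueError("conc and A must have equal length")
        if len(conc) < 4:
            raise ValueError("need at least 4 titration points")
        if np.any(conc <= 0):
            raise ValueError("concentrations must be strictly positive")
        if conc.max() / conc.min() < 10:
            raise ValueError("titration must span at least one decade of concentration")
        amplitude = A.max() - A.min()
        if amplitude < self.flat_tol:
            raise ValueError(
                "flat titration series: Kd unidentifiable (non-binder or saturated probe)"
            )
        if self.init is not None:
            p0 = list(self.init)
        else:
            mid = 0.5 * (A.min() + A.max())
            kd0 = conc[np.argmin(np.abs(A - mid))]
            p0 = [kd0, A.min(), A.max()]
        try:
            popt, _ = curve_fit(
                single_site_anisotropy,
                conc,
                A,
                p0=p0,
                bounds=([1e-15, -np.inf, -np.inf], [np.inf, np.inf, np.inf]),
                maxfev=self.maxfev,
            )
            self.converged_ = True
        except RuntimeError:
            popt = np.asarray(p0, dtype=float)
            self.converged_ = False
        self.kd_, self.af_, self.ab_ = map(float, popt)
        resid = A - single_site_anisotropy(conc, *popt)
        self.rss_ = float(resid @ resid)
        return self

    def predict(self, conc):
        if not hasattr(self, "kd_"):
            raise AttributeError("estimator is not fitted")
        conc = np.asarray(conc, dtype=float)
        if np.any(conc < 0):
            raise ValueError("concentration must be non-negative")
        return single_site_anisotropy(conc, self.kd_, self.af_, self.ab_)


def fit_single_site(conc, A, **kwargs) -> SingleSiteBinding:
    """Functional wrapper over :class:`SingleSiteBinding`."""
    return SingleSiteBinding(**kwargs).fit(conc, A)


def predict_anisotropy(kd, af, ab, conc):
    """Anisotropy predicted by a (kd, af, ab) single-site fit at ``conc``."""
    conc = np.asarray(conc, dtype=float)
    if np.any(conc < 0):
        raise ValueError("concentration must be non-negative")
    return single_site_anisotropy(conc, kd, af, ab)


def _logistic4(logc, log_ic50, hill, top, bottom):
    return bottom + (top - bottom) / (1.0 + 10.0 ** (hill * (logc - log_ic50)))


class CompetitionCurve(BaseEstimator):
    """Four-parameter logistic fit of an FP competition series.

    The model is ``A = bottom + (top - bottom) / (1 + 10^(hill*(log c - log IC50)))``
    on log10 competitor concentration; a competitor displaces the probe, so
    anisotropy falls with concentration (hill > 0).  Series that do not fall
    (Spearman rho >= 0, or negligible fitted amplitude) are flagged
    ``non_competing_`` and carry NaN parameters.

    Fitted attributes: ``ic50_`` (M), ``hill_``, ``top_``, ``bottom_``,
    ``non_competing_``, ``converged_``, ``rss_``.
    """

    def __init__(self, amplitude_tol: float = 1e-3, maxfev: int = 10000):
        self.amplitude_tol = amplitude_tol
        self.maxfev = maxfev

    def fit(self, conc, A):
        conc = np.asarray(conc, dtype=float).ravel()
        A = np.asarray(A, dtype=float).ravel()
        if len(conc) < 5:
            raise ValueError("need at least 5 competition points")
        if np.any(conc <= 0):
            raise ValueError("competitor concentrations must be strictly positive")
        order = np.argsort(conc)
        conc, A = conc[order], A[order]
        self.non_competing_ = False
        self.converged_ = False
        self.ic50_ = self.hill_ = self.top_ = self.bottom_ = self.rss_ = float("nan")
        if A.max() - A.min() < self.amplitude_tol:
            self.non_competing_ = True
            return self
        rho = spearmanr(conc, A).statistic
        if not (rho < 0):
            self.non_competing_ = True
            return self
        logc = np.log10(conc)
        mid = 0.5 * (A.max() + A.min())
        log_ic50_0 = logc[np.argmin(np.abs(A - mid))]
        p0 = [log_ic50_0, 1.0, A.max(), A.min()]
        try:
            popt, _ = curve_fit(
                _logistic4,
                logc,
                A,
                p0=p0,
                bounds=([logc.min() - 3, 0.05, -np.inf, -np.inf], [logc.max() + 3, 20.0, np.inf, np.inf]),
                maxfev=self.maxfev,
            )
        except RuntimeError:
            return self
        log_ic50, hill, top, bottom = popt
        if top - bottom < self.amplitude_tol:
            self.non_competing_ = True
            return self
        self.converged_ = True
        self.ic50_ = float(10.0 ** log_ic50)
        self.hill_ = float(hill)
        self.top_ = float(top)
        self.bottom_ = float(bottom)
        resid = A - _logistic4(logc, *popt)
        self.rss_ = float(resid @ resid)
        return self

    def predict(self, conc):
        if self.non_competing_ or not self.converged_:
            raise AttributeError("no competition fit available")
        return _logistic4(
            np.log10(np.asarray(conc, dtype=float)),
            np.log10(self.ic50_),
            self.hill_,
            self.top_,
            self.bottom_,
        )


def fit_competition(conc, A, **kwargs) -> CompetitionCurve:
    """Functional wrapper over :class:`CompetitionCurve`."""
    return CompetitionCurve(**kwargs).fit(conc, A)


def cheng_prusoff_ki(ic50: float, probe_conc: float, probe_kd: float) -> float:
    """Ki = IC50 / (1 + [probe]/Kd_probe); a derived quantity, labelled as such."""
    if min(ic50, probe_conc, probe_kd) <= 0:
        raise ValueError("all arguments must be positive")
    return ic50 / (1.0 + probe_conc / probe_kd)


@dataclass(frozen=True)
class ModEffect:
    """Relative binding of one modification combination vs the reference."""

    combo: str
    relative_binding: float
    n: int
    sd: float
    classification: str


def quantify_array(
    table: pd.DataFrame,
    reference: str,
    subtract_background: bool = False,
    background_combo: str = "empty",
    switch_max: float = 0.5,
    rheostat_min: float = 1.5,
) -> pd.DataFrame:
    """Per-combination relative binding from peptide-array spot intensities.

    ``table`` needs columns ``combo``, ``replicate``, ``intensity`` (and
    ``slide`` when ``subtract_background`` is on).  Relative binding is
    mean(combo) / mean(reference) over replicates, invariant to global
    multiplicative scaling.  With ``subtract_background``, the per-slide
    median intensity of ``background_combo`` spots is subtracted first
    (exposed because printed relative percentages may or may not have been
    background-corrected).
    """
    table = table.copy()
    required = {"combo", "intensity"}
    if not required.issubset(table.columns):
        raise ValueError(f"array table needs columns {sorted(required)}")
    if subtract_background:
        if "slide" not in table.columns:
            raise ValueError("background subtraction needs a 'slide' column")
        bg = (
            table[table["combo"] == background_combo]
            .groupby("slide")["intensity"]
            .median()
        )
        table["intensity"] = table["intensity"] - table["slide"].map(bg).fillna(0.0)
        table = table[table["combo"] != background_combo]
    groups = table.groupby("combo")["intensity"]
    means = groups.mean()
    if reference not in means.index:
        raise ValueError(f"reference combo {reference!r} absent from array table")
    ref_mean = means[reference]
    if not ref_mean > 0:
        raise ValueError("reference combo has non-positive mean intensity")
    out = pd.DataFrame(
        {
            "combo": means.index,
            "relative_binding": (means / ref_mean).to_numpy(),
            "n": groups.size().to_numpy(),
            "sd": groups.std(ddof=1).fillna(0.0).to_numpy() / ref_mean,
        }
    ).reset_index(drop=True)
    out["classification"] = [
        classify_mod_effect(r, switch_max=switch_max, rheostat_min=rheostat_min)
        for r in out["relative_binding"]
    ]
    return out


def classify_mod_effect(
    relative_binding: float, switch_max: float = 0.5, rheostat_min: float = 1.5
) -> str:
    """Classify a flanking-modification effect by its relative binding.

    <= ``switch_max`` of the reference: *switch* (recognition turned off);
    >= ``rheostat_min``: *rheostat* (graded enhancement); otherwise neutral.
    """
    if switch_max <= 0 or rheostat_min <= 0 or not switch_max < 1 < rheostat_min:
        raise ValueError("thresholds must satisfy 0 < switch_max < 1 < rheostat_min")
    if relative_binding <= switch_max:
        return "switch"
    if relative_binding >= rheostat_min:
        return "rheostat"
    return "neutral"
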