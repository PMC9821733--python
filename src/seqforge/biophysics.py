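"""Binding-biophysics models: 1:1 SPR kinetics, CD difference spectra,
two-state thermal melting, refolding similarity, stoichiometric aggregation
inhibition, ELISA normalization, and average protein mass.

The SPR model is the closed-form 1:1 Langmuir interaction.  During analyte
injection at concentration C,

    R(t) = Rmax * C/(C + KD) * (1 - exp(-(ka*C + kd) * t)),

and after the injection ends the complex decays as R(t) = R(t_assoc) *
exp(-kd * (t - t_assoc)).  A multi-cycle dataset (one sensorgram per analyte
concentration) is fitted globally with ka, kd and Rmax shared across cycles;
KD = kd/ka.

Thermal melting follows a two-state (folded/unfolded) transition with linear
pre- and post-transition baselines and a van't Hoff enthalpy; Tm is the
midpoint of the fitted transition.

Stoichiometric inhibition assumes sequestrins bind monomeric peptide 1:1, so
free aggregation-competent peptide is max(0, total - n * inhibitor).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from Bio.SeqUtils import molecular_weight
from lmfit import Parameters, minimize
from sklearn.isotonic import IsotonicRegression

__all__ = [
    "KineticParams",
    "Sensorgram",
    "KineticFitResult",
    "CDSpectrum",
    "MeltingCurve",
    "TmFitResult",
    "NoTransitionError",
    "simulate_sensorgram",
    "fit_kinetics",
    "kd_over_ka",
    "cd_difference",
    "estimate_tm",
    "refolding_score",
    "refolding_label",
    "stoichiometric_free_peptide",
    "endpoint_from_standard",
    "elisa_normalize",
    "average_mass",
    "yield_ratio",
]

GAS_CONSTANT = 8.314462618e-3        # kJ/(mol*K)
WATER_AVERAGE_MASS = 18.015


class NoTransitionError(ValueError):
    """Raised when a melting signal shows no detectable two-state transition."""


@dataclass(frozen=True)
class KineticParams:
    """1:1 interaction rate constants; KD = kd/ka by construction."""

    ka: float            # 1/(M*s)
    kd: float            # 1/s
    Rmax: float = 100.0  # RU

    def __post_init__(self):
        if self.ka <= 0 or self.kd <= 0 or self.Rmax <= 0:
            raise ValueError("ka, kd and Rmax must be positive")

    @property
    def KD(self) -> float:
        """Equilibrium dissociation constant, molar."""
        return self.kd / self.ka

    @property
    def KD_nM(self) -> float:
        return kd_over_ka(self.ka, self.kd)


@dataclass
class Sensorgram:
    """One injection cycle: response vs time at a single analyte concentration."""

    analyte_concentration: float    # molar
    times: np.ndarray               # s, strictly increasing
    response: np.ndarray            # RU
    association_end: float = 200.0  # s
    dissociation_end: float = 800.0

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.response = np.asarray(self.response, dtype=float)
        if self.times.size != self.response.size:
            raise ValueError("times and response must have equal length")
        if (np.diff(self.times) <= 0).any():
            raise ValueError("times must be strictly increasing")
        if self.association_end >= self.dissociation_end:
            raise ValueError("association must end before dissociation ends")


@dataclass
class KineticFitResult:
    """Outcome of a global 1:1 fit across a multi-cycle sensorgram set."""

    params: KineticParams | None
    success: bool
    message: str
    cost: float
    n_points: int
    residual_rms: float = math.nan

    @property
    def KD_nM(self) -> float:
        if self.params is None:
            raise ValueError("fit failed; no parameters")
        return self.params.KD_nM


@dataclass
class CDSpectrum:
    """A circular-dichroism wavelength scan."""

    wavelengths: np.ndarray         # nm
    ellipticity: np.ndarray         # millidegree
    label: str = ""
    concentration: float = 0.0      # molar

    def __post_init__(self):
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.ellipticity = np.asarray(self.ellipticity, dtype=float)
        if self.wavelengths.size != self.ellipticity.size:
            raise ValueError("wavelength and ellipticity grids differ in length")


@dataclass
class MeltingCurve:
    """Thermal melt monitored at a single wavelength (221 nm in this assay)."""

    temperatures: np.ndarray        # deg C, increasing
    signal: np.ndarray              # millidegree

    def __post_init__(self):
        self.temperatures = np.asarray(self.temperatures, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.temperatures.size != self.signal.size:
            raise ValueError("temperature and signal grids differ in length")
        if (np.diff(self.temperatures) <= 0).any():
            raise ValueError("temperatures must be increasing")


@dataclass
class TmFitResult:
    tm: float                       # deg C
    dh_vant_hoff: float             # kJ/mol
    baselines: dict = field(default_factory=dict)
    amplitude: float = math.nan     # baseline separation at Tm, same units as signal
    residual_rms: float = math.nan


def simulate_sensorgram(params: KineticParams, concentration: float,
                        times: np.ndarray, association_end: float = 200.0,
                        dissociation_end: float = 800.0) -> Sensorgram:
    """Noise-free 1:1 Langmuir sensorgram on an arbitrary time grid."""
    if concentration < 0:
        raise ValueError("concentration must be >= 0")
    times = np.asarray(times, dtype=float)
    response = _langmuir_response(params.ka, params.kd, params.Rmax,
                                  concentration, times, association_end)
    return Sensorgram(concentration, times, response,
                      association_end=association_end,
                      dissociation_end=dissociation_end)


def _langmuir_response(ka: float, kd: float, rmax: float, conc: float,
                       times: np.ndarray, t_assoc: float) -> np.ndarray:
    if conc == 0:
        return np.zeros_like(times)
    kobs = ka * conc + kd
    req = rmax * conc / (conc + kd / ka)
    assoc = req * (1.0 - np.exp(-kobs * np.minimum(times, t_assoc)))
    r_end = req * (1.0 - math.exp(-kobs * t_assoc))
    dissoc = r_end * np.exp(-kd * (times - t_assoc))
    return np.where(times <= t_assoc, assoc, dissoc)


def fit_kinetics(sensorgrams: list[Sensorgram],
                 log_ka_starts=(3.0, 4.5, 6.0),
                 log_kd_starts=(-5.0, -3.5, -2.0)) -> KineticFitResult:
    """Global nonlinear least squares: ka, kd, Rmax shared across cycles.

    Parameters are fitted on a log scale from a multi-start grid; the best
    converged start wins.  Residuals are unweighted (single-surface
    assumption).  A set with no measurable signal is flagged as a failure.
    """
    if len({sg.analyte_concentration for sg in sensorgrams if sg.analyte_concentration > 0}) < 2:
        raise ValueError("global fit needs sensorgrams at >= 2 analyte concentrations")
    peak = max(float(np.max(np.abs(sg.response))) for sg in sensorgrams)
    n_points = sum(sg.times.size for sg in sensorgrams)
    if peak < 1e-6:
        return KineticFitResult(None, False, "no measurable response in sensorgram set",
                                math.inf, n_points)

    def residual(p):
        ka, kd, rmax = 10 ** p["log_ka"].value, 10 ** p["log_kd"].value, p["rmax"].value
        parts = [sg.response - _langmuir_response(ka, kd, rmax, sg.analyte_concentration,
                                                  sg.times, sg.association_end)
                 for sg in sensorgrams]
        return np.concatenate(parts)

    best = None
    for lka in log_ka_starts:
        for lkd in log_kd_starts:
            p = Parameters()
            p.add("log_ka", value=lka, min=0.0, max=9.0)
            p.add("log_kd", value=lkd, min=-8.0, max=1.0)
            p.add("rmax", value=max(peak * 1.5, 1e-3), min=1e-6)
            try:
                res = minimize(residual, p, method="leastsq", ftol=1e-12, xtol=1e-12)
            except Exception:
                continue
            if res.success and (best is None or res.chisqr < best.chisqr):
                best = res
    if best is None:
        return KineticFitResult(None, False, "no start converged", math.inf, n_points)
    ka = 10 ** best.params["log_ka"].value
    kd = 10 ** best.params["log_kd"].value
    rmax = best.params["rmax"].value
    return KineticFitResult(
        params=KineticParams(ka=ka, kd=kd, Rmax=rmax),
        success=True, message="converged", cost=float(best.chisqr),
        n_points=n_points,
        residual_rms=float(np.sqrt(best.chisqr / n_points)),
    )


def kd_over_ka(ka: float, kd: float) -> float:
    """KD in nM, rounded to 3 significant figures for table comparison."""
    if ka <= 0 or kd <= 0:
        raise ValueError("rate constants must be positive")
    kd_nm = kd / ka * 1e9
    return float(f"{kd_nm:.3g}")


def cd_difference(complex_spectrum: CDSpectrum,
                  free_spectra: list[CDSpectrum]) -> CDSpectrum:
    """Difference spectrum: complex minus the sum of the free interactants.

    A nonzero difference indicates a change in secondary-structure content
    upon binding.  All spectra must share one wavelength grid.
    """
    delta = complex_spectrum.ellipticity.copy()
    for free in free_spectra:
        if free.wavelengths.size != complex_spectrum.wavelengths.size or \
                not np.allclose(free.wavelengths, complex_spectrum.wavelengths):
            raise ValueError("wavelength grid mismatch between spectra")
        delta = delta - free.ellipticity
    return CDSpectrum(complex_spectrum.wavelengths.copy(), delta,
                      label=f"{complex_spectrum.label} - sum(free)")


def difference_norm(spectrum: CDSpectrum) -> float:
    """RMS magnitude of a (difference) spectrum, millidegree."""
    return float(np.sqrt(np.mean(spectrum.ellipticity ** 2)))


def _two_state_signal(T, tm, dh, af, bf, au, bu):
    TK = T + 273.15
    tmK = tm + 273.15
    lnK = dh / GAS_CONSTANT * (1.0 / tmK - 1.0 / TK)
    frac_unfolded = 1.0 / (1.0 + np.exp(-lnK))
    return (af + bf * T) * (1.0 - frac_unfolded) + (au + bu * T) * frac_unfolded


def estimate_tm(curve: MeltingCurve, min_amplitude_fraction: float = 0.1) -> TmFitResult:
    """Fit a two-state melt with linear baselines; Tm is the midpoint.

    Raises NoTransitionError when the fitted transition amplitude is below
    `min_amplitude_fraction` of the signal range (baseline-only signal), or
    when the signal carries no usable variation at all.
    """
    T, y = curve.temperatures, curve.signal
    if T.size < 10:
        raise ValueError("need at least 10 points spanning the transition")
    span = float(np.ptp(y))
    if span <= 0 or not np.isfinite(span):
        raise NoTransitionError("signal has no variation")

    # initialization: steepest smoothed slope locates the transition
    k = max(3, T.size // 15)
    kernel = np.ones(k) / k
    smooth = np.convolve(y, kernel, mode="same")
    slope = np.gradient(smooth, T)
    interior = slice(k, T.size - k)
    tm0 = float(T[interior][np.argmax(np.abs(slope[interior]))])
    n_edge = max(3, T.size // 10)
    bf0, af0 = np.polyfit(T[:n_edge], y[:n_edge], 1)
    bu0, au0 = np.polyfit(T[-n_edge:], y[-n_edge:], 1)

    p = Parameters()
    p.add("tm", value=tm0, min=float(T.min()), max=float(T.max()))
    p.add("dh", value=300.0, min=10.0, max=3000.0)
    p.add("af", value=af0)
    p.add("bf", value=bf0)
    p.add("au", value=au0)
    p.add("bu", value=bu0)

    def residual(p):
        return y - _two_state_signal(T, p["tm"].value, p["dh"].value, p["af"].value,
                                     p["bf"].value, p["au"].value, p["bu"].value)

    res = minimize(residual, p, method="leastsq", ftol=1e-12, xtol=1e-12)
    v = res.params
    tm = v["tm"].value
    amplitude = abs((v["au"].value + v["bu"].value * tm) - (v["af"].value + v["bf"].value * tm))
    if amplitude < min_amplitude_fraction * span:
        raise NoTransitionError(
            f"transition amplitude {amplitude:.3g} below {min_amplitude_fraction:.0%} of signal range"
        )
    return TmFitResult(
        tm=float(tm),
        dh_vant_hoff=float(v["dh"].value),
        baselines={"folded": (v["af"].value, v["bf"].value),
                   "unfolded": (v["au"].value, v["bu"].value)},
        amplitude=float(amplitude),
        residual_rms=float(np.sqrt(res.chisqr / T.size)),
    )


def refolding_score(spectrum_before: CDSpectrum, spectrum_after: CDSpectrum) -> float:
    """Similarity of spectra before/after heat denaturation, in [0, 1].

    1 - RMS(after - before) / RMS(before), clipped; 1.0 means identical
    spectra (full refolding), 0.0 total signal loss.
    """
    if spectrum_before.wavelengths.size != spectrum_after.wavelengths.size or \
            not np.allclose(spectrum_before.wavelengths, spectrum_after.wavelengths):
        raise ValueError("wavelength grid mismatch between spectra")
    rms_before = np.sqrt(np.mean(spectrum_before.ellipticity ** 2))
    if rms_before == 0:
        raise ValueError("reference spectrum is identically zero")
    rms_diff = np.sqrt(np.mean((spectrum_after.ellipticity - spectrum_before.ellipticity) ** 2))
    return float(np.clip(1.0 - rms_diff / rms_before, 0.0, 1.0))


def refolding_label(score: float, yes_threshold: float = 0.9,
                    partly_threshold: float = 0.5) -> str:
    """Map a refolding score to the qualitative Yes / Partly / No call."""
    if score >= yes_threshold:
        return "Yes"
    if score >= partly_threshold:
        return "Partly"
    return "No"


def stoichiometric_free_peptide(total_peptide_um: float, sequestrin_um: float,
                                stoichiometry: float = 1.0) -> float:
    """Free aggregation-competent peptide under n:1 stoichiometric depletion.

    With tight 1:1 binding of inhibitor to monomeric peptide, each inhibitor
    molecule removes `stoichiometry` peptide equivalents: max(0, total - n*I).
    """
    if total_peptide_um < 0 or sequestrin_um < 0 or stoichiometry < 0:
        raise ValueError("concentrations and stoichiometry must be >= 0")
    return max(0.0, total_peptide_um - stoichiometry * sequestrin_um)


def endpoint_from_standard(free_peptide_um: float, standard,
                           background: float = 0.0) -> float:
    """Predict an endpoint fluorescence from a concentration standard curve.

    `standard` is a sequence of (concentration_um, endpoint_fluorescence)
    pairs.  Piecewise-linear interpolation; free concentrations below the
    lowest standard clip to `background`.  A non-monotone standard triggers a
    warning and an isotonic-regression repair.
    """
    pts = sorted((float(c), float(f)) for c, f in standard)
    if len(pts) < 2:
        raise ValueError("standard curve needs at least 2 points")
    conc = np.array([c for c, _ in pts])
    fluor = np.array([f for _, f in pts])
    if (np.diff(fluor) < 0).any():
        warnings.warn("standard curve is not monotone; applying isotonic repair")
        fluor = IsotonicRegression(increasing=True).fit_transform(conc, fluor)
    if free_peptide_um < conc[0]:
        return float(background)
    return float(np.interp(free_peptide_um, conc, fluor))


def elisa_normalize(signal_target: float, signal_target_background: float,
                    signal_display: float, signal_display_background: float) -> float:
    """Display-normalized target ELISA signal.

    Background-subtracted target signal divided by the background-subtracted
    display-level (HSA/ABD) signal; negative numerators clip to 0.
    """
    display = signal_display - signal_display_background
    if display <= 0:
        raise ValueError("display signal must exceed its background")
    return max(0.0, signal_target - signal_target_background) / display


def average_mass(protein_sequence: str, modifications: float = 0.0) -> float:
    """Average molecular mass (Da) of a protein plus fixed modification deltas.

    For example a single disulfide bond contributes modifications = -2.016.
    """
    if not protein_sequence:
        return WATER_AVERAGE_MASS + modifications
    try:
        mass = molecular_weight(protein_sequence, seq_type="protein", monoisotopic=False)
    except ValueError as exc:
        raise ValueError(f"unknown residue in sequence: {exc}") from exc
    return float(mass) + modifications


def yield_ratio(yield_mg: float, reference_yield_mg: float) -> float:
    """Fold-improved expression vs a reference construct, one decimal."""
    if reference_yield_mg <= 0:
        raise ValueError("reference yield must be positive")
    return round(yield_mg / reference_yield_mg, 1)
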