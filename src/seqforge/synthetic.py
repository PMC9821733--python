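"""Synthetic-data generators for every input the pipeline consumes.

Each generator emulates the statistical structure of one wet-lab output so
the downstream stage can be tested end to end without instrument data: Sanger
reads of library clones at the naive class mixture (72% sequestrin / 24%
monomer / 4% dummy), multi-cycle 1:1 sensorgrams on the instrument's time
design, three-basis CD spectra, two-state melting curves, and logistic
thioflavin-T aggregation traces whose plateau scales with stoichiometrically
free peptide.

The CD basis curves and the logistic ThT shape are explicit stand-ins chosen
for testability: they carry the qualitative signatures (helix double minimum
at 208/222 nm, sheet minimum near 218 nm, coil minimum below 200 nm; lag /
growth / plateau phases) without claiming instrument realism.

A single top-level seed fans out to per-generator independent streams via
``numpy`` SeedSequence spawn keys, so adding a generator never perturbs the
fixtures another generator produces.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from scipy.optimize import nnls

from .biophysics import (
    CDSpectrum,
    KineticParams,
    MeltingCurve,
    Sensorgram,
    _two_state_signal,
    simulate_sensorgram,
    stoichiometric_free_peptide,
)
from .library_design import LibraryDesign, sample_clones

__all__ = [
    "GeneratorSpec",
    "MeltingTruth",
    "ThTTruth",
    "ThTSeries",
    "gen_library_reads",
    "gen_sensorgram_set",
    "gen_cd_spectrum",
    "gen_melting_curve",
    "gen_tht_series",
    "secondary_structure_unmix",
    "default_concentration_series",
]

# fixed spawn keys: one independent stream per generator
_STREAMS = {"reads": 1, "spr": 2, "cd": 3, "melt": 4, "tht": 5}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(_STREAMS[stream],)))


@dataclass(frozen=True)
class MeltingTruth:
    """Ground truth for a two-state melt at 221 nm."""

    tm: float = 42.0                 # deg C
    dh: float = 300.0                # kJ/mol van't Hoff
    folded_intercept: float = -12.0  # mdeg
    folded_slope: float = 0.01       # mdeg / deg C
    unfolded_intercept: float = -4.0
    unfolded_slope: float = 0.005

    @property
    def amplitude(self) -> float:
        return abs((self.unfolded_intercept + self.unfolded_slope * self.tm)
                   - (self.folded_intercept + self.folded_slope * self.tm))


@dataclass(frozen=True)
class ThTTruth:
    """Ground truth for a logistic aggregation trace."""

    lag_h: float = 15.0              # midpoint of the growth phase, h
    growth_per_h: float = 0.5        # logistic rate, 1/h
    plateau_per_um: float = 100.0    # endpoint AU per uM free peptide
    baseline: float = 0.0            # AU


@dataclass
class ThTSeries:
    """A thioflavin-T fluorescence time course and its sample composition."""

    times_h: np.ndarray
    fluorescence: np.ndarray         # AU, >= 0
    total_peptide_um: float
    sequestrin_um: float

    @property
    def endpoint(self) -> float:
        return float(self.fluorescence[-1])

    @property
    def ratio(self) -> float:
        if self.total_peptide_um == 0:
            return np.inf
        return self.sequestrin_um / self.total_peptide_um


@dataclass(frozen=True)
class GeneratorSpec:
    """All noise levels, mixtures and ground-truth parameters in one place.

    Defaults are the study conditions: the naive library class mixture, the
    highest-affinity clone's rate constants, its free-protein melting
    midpoint, and the 92-h aggregation design.
    """

    seed: int = 0
    class_mixture: tuple[float, float, float] = (0.72, 0.24, 0.04)
    read_error_rate: float = 0.001       # substitutions per base
    spr_sigma: float = 1.0               # RU
    cd_sigma: float = 0.2                # mdeg
    melt_sigma: float = 0.02             # fraction of transition amplitude
    tht_sigma: float = 2.0               # AU
    kinetics: KineticParams = field(default_factory=lambda: KineticParams(1.63e4, 1.70e-5, 100.0))
    melting: MeltingTruth = field(default_factory=MeltingTruth)
    tht: ThTTruth = field(default_factory=ThTTruth)

    def __post_init__(self):
        if abs(sum(self.class_mixture) - 1.0) > 1e-9:
            raise ValueError("class mixture must sum to 1")
        for name in ("read_error_rate", "spr_sigma", "cd_sigma", "melt_sigma", "tht_sigma"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def gen_library_reads(design: LibraryDesign, n: int, spec: GeneratorSpec,
                      monomer_length: int = 157) -> list[SeqRecord]:
    """Sanger-style reads of library clones with truth labels in the headers.

    Sequestrins are sampled from the design; monomers are first-subunit
    fragments cut inside the linker; dummies are frameshifted or
    stop-containing variants.  Per-base substitution errors are applied at
    the configured rate after class assembly.
    """
    rng = _rng(spec.seed, "reads")
    classes = rng.choice(3, size=n, p=list(spec.class_mixture))
    genes = sample_clones(design, n, rng)
    records = []
    for i, (cls, gene) in enumerate(zip(classes, genes)):
        if cls == 0:
            label, dna = "sequestrin", gene
        elif cls == 1:
            label, dna = "monomer", gene[:monomer_length]
        else:
            label = "dummy"
            if rng.random() < 0.5:
                # premature stop in the first subunit
                stop_at = int(rng.integers(2, 30)) * 3
                dna = gene[:stop_at] + "TAA" + gene[stop_at + 3:]
            else:
                # single-base deletion: frameshift
                cut = int(rng.integers(0, len(gene)))
                dna = gene[:cut] + gene[cut + 1:]
        dna = _substitution_errors(dna, spec.read_error_rate, rng)
        rec = SeqRecord(Seq(dna), id=f"read_{i:06d}", description=f"class={label}")
        rec.letter_annotations["phred_quality"] = [40] * len(dna)
        records.append(rec)
    return records


def _substitution_errors(dna: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return dna
    arr = np.frombuffer(dna.encode(), dtype="S1").copy()
    hits = np.nonzero(rng.random(arr.size) < rate)[0]
    bases = np.array([b"A", b"C", b"G", b"T"])
    for i in hits:
        choices = bases[bases != arr[i]]
        arr[i] = choices[rng.integers(0, choices.size)]
    return arr.tobytes().decode()


def default_concentration_series(top_nm: float = 342.0, dilution: float = 1.5,
                                 steps: int = 7, include_blank: bool = True) -> list[float]:
    """The multi-cycle analyte series: 1:1.5 dilutions from 342 nM down to
    30 nM, plus a zero-concentration blank cycle (molar units)."""
    series = [top_nm * 1e-9 / dilution ** k for k in range(steps)]
    if include_blank:
        series.append(0.0)
    return series


def gen_sensorgram_set(truth: KineticParams, concentrations: list[float] | None = None,
                       sigma: float = 0.0, seed: int = 0, replicates: int = 2,
                       association_end: float = 200.0, dissociation_end: float = 800.0,
                       dt: float = 1.0) -> list[Sensorgram]:
    """Duplicate multi-cycle sensorgrams on the instrument time design.

    200 s injection, 600 s dissociation, Gaussian read noise of `sigma` RU.
    Deterministic under a fixed seed (byte-identical re-runs).
    """
    rng = _rng(seed, "spr")
    if concentrations is None:
        concentrations = default_concentration_series()
    times = np.arange(0.0, dissociation_end + dt / 2, dt)
    out = []
    for conc in concentrations:
        for _ in range(replicates):
            sg = simulate_sensorgram(truth, conc, times, association_end, dissociation_end)
            if sigma > 0:
                sg.response = sg.response + rng.normal(0.0, sigma, size=times.size)
            out.append(sg)
    return out


# Gaussian-band CD basis curves (mdeg at unit amplitude): helix shows the
# double minimum at 208/222 nm, sheet a single minimum near 218 nm, coil a
# deep minimum below 200 nm.
def _gauss(lam, centre, width):
    return np.exp(-0.5 * ((lam - centre) / width) ** 2)


def _cd_basis(wavelengths: np.ndarray) -> np.ndarray:
    lam = np.asarray(wavelengths, dtype=float)
    helix = 1.6 * _gauss(lam, 193, 6) - 1.0 * _gauss(lam, 208, 4.5) - 0.95 * _gauss(lam, 222, 5.5)
    sheet = 1.1 * _gauss(lam, 196, 6) - 1.0 * _gauss(lam, 218, 8)
    coil = -1.4 * _gauss(lam, 198, 8) + 0.1 * _gauss(lam, 222, 20)
    return np.vstack([helix, sheet, coil])


def gen_cd_spectrum(fractions: tuple[float, float, float], sigma: float = 0.0,
                    seed: int = 0, wavelengths: np.ndarray | None = None,
                    amplitude: float = 10.0, label: str = "") -> CDSpectrum:
    """Linear combination of the {helix, sheet, coil} basis plus read noise.

    `fractions` are secondary-structure weights summing to 1; `amplitude`
    scales the basis to millidegrees.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("structure fractions must sum to 1")
    if any(f < 0 for f in fractions):
        raise ValueError("structure fractions must be >= 0")
    rng = _rng(seed, "cd")
    lam = np.arange(195.0, 261.0) if wavelengths is None else np.asarray(wavelengths, float)
    theta = amplitude * np.asarray(fractions) @ _cd_basis(lam)
    if sigma > 0:
        theta = theta + rng.normal(0.0, sigma, size=lam.size)
    return CDSpectrum(lam, theta, label=label)


def secondary_structure_unmix(spectrum: CDSpectrum, amplitude: float = 10.0) -> dict[str, float]:
    """Non-negative least-squares unmixing onto the generator's own basis.

    A documented stand-in for full spectral deconvolution: it recovers the
    {helix, sheet, coil} weights of spectra produced by `gen_cd_spectrum`
    and gives a coarse composition estimate for anything else.
    """
    basis = amplitude * _cd_basis(spectrum.wavelengths)
    weights, _ = nnls(basis.T, spectrum.ellipticity)
    total = weights.sum()
    if total == 0:
        raise ValueError("spectrum cannot be expressed in the basis")
    return dict(zip(("helix", "sheet", "coil"), (weights / total).tolist()))


def gen_melting_curve(truth: MeltingTruth, sigma: float = 0.0, seed: int = 0,
                      temperatures: np.ndarray | None = None) -> MeltingCurve:
    """Two-state melt with linear baselines on a 20-90 degC grid (1 degC steps).

    `sigma` is Gaussian noise as a fraction of the transition amplitude.
    """
    T = np.arange(20.0, 91.0) if temperatures is None else np.asarray(temperatures, float)
    if not (T.min() <= truth.tm <= T.max()):
        raise ValueError("Tm must lie within the temperature span")
    y = _two_state_signal(T, truth.tm, truth.dh, truth.folded_intercept,
                          truth.folded_slope, truth.unfolded_intercept, truth.unfolded_slope)
    if sigma > 0:
        rng = _rng(seed, "melt")
        y = y + rng.normal(0.0, sigma * truth.amplitude, size=T.size)
    return MeltingCurve(T, y)


def gen_tht_series(total_peptide_um: float, sequestrin_um: float,
                   truth: ThTTruth | None = None, sigma: float = 0.0, seed: int = 0,
                   n_cycles: int = 999, cycle_s: float = 325.0,
                   stoichiometry: float = 1.0) -> ThTSeries:
    """Logistic aggregation trace with stoichiometry-depleted plateau.

    The plateau is `plateau_per_um` x stoichiometrically free peptide; a fully
    sequestered sample (ratio >= 1:1) or an inhibitor-only sample is baseline
    noise.  Acquisition mirrors the plate-reader design: `n_cycles` readings
    every `cycle_s` seconds at 37 degC.
    """
    truth = truth or ThTTruth()
    t = np.arange(n_cycles) * cycle_s / 3600.0
    free = stoichiometric_free_peptide(total_peptide_um, sequestrin_um, stoichiometry)
    plateau = truth.plateau_per_um * free
    y = truth.baseline + plateau / (1.0 + np.exp(-truth.growth_per_h * (t - truth.lag_h)))
    if sigma > 0:
        rng = _rng(seed, "tht")
        y = y + rng.normal(0.0, sigma, size=t.size)
    return ThTSeries(t, np.maximum(y, 0.0), total_peptide_um, sequestrin_um)
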