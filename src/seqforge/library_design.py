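"""Spiked-codon combinatorial library design over the dimeric sequestrin scaffold.

The scaffold is a head-to-tail dimer of an N-terminally truncated affibody
subunit (46 residues each) joined by an Ala + (S4G)2 linker, an RAS segment
encoded between linker and second subunit, and a C-terminal Lys, 107 residues
in total.  One fixed cysteine per subunit forms the interchain disulphide.
Twenty-two positions (eleven per subunit) are diversified: eighteen "spiked"
positions keep the wildtype codon at 61% mixed with 39% mutation codons drawn
from a class-specific alphabet, and four positions toggle 50:50 between the
wildtype and one alternative residue.

This module loads and validates such designs, builds per-position codon
mixtures, assembles/splits the degenerate gene, and computes the design-level
combinatorics (theoretical diversity, exact Poisson-binomial mutation load).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

from ._codons import AA20, ECOLI_PREFERRED, STOP_CODONS, codons_of, printed_codon_usage, translate

__all__ = [
    "DesignValidationError",
    "OverlapMismatchError",
    "ScaffoldSpec",
    "PositionSpec",
    "LibraryDesign",
    "DegenerateOligo",
    "MutationLoad",
    "load_design",
    "design_codon_mix",
    "assemble_gene",
    "split_gene",
    "theoretical_diversity",
    "mutation_load_distribution",
    "sample_clones",
]

#: Alphabets attached to the textual diversification classes.  The
#: hydrophobic-core class preserves the hydrophobic subunit interface; the
#: beta-strand class admits every residue but cysteine (including the
#: strand-compatible Pro/Gly); plain spiked positions exclude Pro/Gly/Cys.
CLASS_ALPHABETS = {
    "spiked": "".join(a for a in AA20 if a not in "PGC"),
    "beta-strand": "".join(a for a in AA20 if a != "C"),
    "hydrophobic-core": "AVILMFW",
}

SPIKED_CLASSES = ("spiked", "beta-strand", "hydrophobic-core")

#: Classes counted when tallying scaffold mutations.  Binary 50:50 positions
#: are design toggles, not spiked mutations, and are reported separately.
MUTATION_CLASSES = SPIKED_CLASSES

LINKER_PROTEIN = "ASSSSGSSSSG"
RAS_PROTEIN = "RAS"

_PROB_TOL = 1e-9


class DesignValidationError(ValueError):
    """Raised with the full list of design violations, not just the first."""

    def __init__(self, errors: list[str]):
        self.errors = list(errors)
        super().__init__("invalid library design:\n" + "\n".join(f"  - {e}" for e in errors))


class OverlapMismatchError(ValueError):
    """Raised when two oligos disagree inside their hybridization overlap."""

    def __init__(self, offset: int, base1: str, base2: str):
        self.offset = offset
        super().__init__(
            f"overlap mismatch at offset {offset}: {base1!r} != {base2!r} (N matches N only)"
        )


@dataclass(frozen=True)
class ScaffoldSpec:
    """The fixed dimeric scaffold: gene template plus derived protein segments."""

    gene: str                      # 321-nt template, NNN at randomized codons
    subunit_length: int = 46       # residues per truncated subunit
    cys_position: int = 17         # 1-based fixed Cys index within each subunit
    subunit_protein: str = ""      # wildtype subunit ('X' if wildtypes unknown)
    linker_protein: str = ""       # Ala+(S4G)2 + RAS + terminal K as encoded
    full_protein: str = ""         # 107-residue wildtype concatenation

    @property
    def n_residues(self) -> int:
        return len(self.gene) // 3

    def subunit_gene(self, subunit: int) -> str:
        """Fixed DNA of one subunit (template codons, Ns at designed positions)."""
        start = 0 if subunit == 1 else 3 * (self.subunit_length + len(LINKER_PROTEIN) + len(RAS_PROTEIN))
        return self.gene[start:start + 3 * self.subunit_length]


@dataclass(frozen=True)
class PositionSpec:
    """One diversified position: residue distribution within one subunit."""

    subunit: int                   # 1 or 2
    position: int                  # 1-based residue index within the subunit
    wildtype: str
    spike_class: str               # spiked | beta-strand | hydrophobic-core | binary
    distribution: dict[str, float] = field(compare=False)

    @property
    def allowed_residues(self) -> frozenset[str]:
        return frozenset(aa for aa, p in self.distribution.items() if p > 0)

    @property
    def mutation_probability(self) -> float:
        """Probability of drawing a non-wildtype residue (1 if wildtype absent)."""
        return 1.0 - self.distribution.get(self.wildtype, 0.0)

    def validate(self) -> list[str]:
        tag = f"position {self.subunit}:{self.position}"
        errs = []
        if self.subunit not in (1, 2):
            errs.append(f"{tag}: subunit must be 1 or 2")
        bad = [aa for aa in self.distribution if aa not in AA20]
        if bad:
            errs.append(f"{tag}: residues outside the 20-letter alphabet: {bad}")
        if any(p < 0 for p in self.distribution.values()):
            errs.append(f"{tag}: negative probabilities")
        total = sum(self.distribution.values())
        if not math.isclose(total, 1.0, abs_tol=_PROB_TOL):
            errs.append(f"{tag}: probabilities sum to {total:.6g}, not 1")
        if self.spike_class == "binary":
            if len(self.allowed_residues) != 2:
                errs.append(f"{tag}: binary position must have exactly 2 allowed residues")
        if self.spike_class in SPIKED_CLASSES + ("binary",):
            if self.wildtype not in self.distribution or self.distribution[self.wildtype] <= 0:
                errs.append(f"{tag}: wildtype {self.wildtype!r} not in allowed residues")
        return errs


@dataclass(frozen=True)
class DegenerateOligo:
    """A synthesis-ready degenerate DNA stretch (Ns only in full NNN triplets)."""

    sequence: str
    reading_frame_offset: int = 0
    flank_sites: tuple[str, str] | None = None   # e.g. ("GGATCC", "GTCGAC")

    @property
    def export_sequence(self) -> str:
        if self.flank_sites is None:
            return self.sequence
        return self.flank_sites[0] + self.sequence + self.flank_sites[1]


@dataclass(frozen=True)
class MutationLoad:
    """Exact Poisson-binomial distribution of per-clone mutation counts."""

    pmf: np.ndarray
    mean: float
    variance: float

    def __post_init__(self):
        object.__setattr__(self, "pmf", np.asarray(self.pmf, dtype=float))


@dataclass
class LibraryDesign:
    """A validated 22-position spiked randomization scheme."""

    scaffold: ScaffoldSpec
    positions: list[PositionSpec]
    codon_policy: str = "ecoli-most-frequent"
    codon_mixtures: dict[tuple[int, int], list[tuple[str, float]]] = field(default_factory=dict)

    def position(self, subunit: int, position: int) -> PositionSpec:
        for p in self.positions:
            if p.subunit == subunit and p.position == position:
                return p
        raise KeyError((subunit, position))

    def residue_index(self, subunit: int, position: int) -> int:
        """0-based index into the full 107-residue protein."""
        L = self.scaffold.subunit_length
        offset = 0 if subunit == 1 else L + len(LINKER_PROTEIN) + len(RAS_PROTEIN)
        return offset + position - 1

    @property
    def wildtype_gene(self) -> str:
        """Template gene with every NNN replaced by the wildtype codon."""
        codon_map = self._policy_codon_map()
        codons = codons_of(self.scaffold.gene)
        for spec in self.positions:
            codons[self.residue_index(spec.subunit, spec.position)] = codon_map[spec.wildtype]
        return "".join(codons)

    @property
    def wildtype_protein(self) -> str:
        return self.scaffold.full_protein

    def _policy_codon_map(self) -> dict[str, str]:
        return policy_codon_map(self.codon_policy, self.scaffold.gene)


def policy_codon_map(policy: str, template_gene: str | None = None) -> dict[str, str]:
    """Residue -> codon map for a codon-choice policy."""
    if policy == "ecoli-most-frequent":
        return dict(ECOLI_PREFERRED)
    if policy == "match-printed-oligo":
        table = dict(ECOLI_PREFERRED)
        if template_gene:
            table.update(printed_codon_usage(template_gene))
        return table
    raise ValueError(f"unknown codon policy {policy!r}")


def _class_distribution(spike_class: str, wildtype: str, wt_fraction: float,
                        alternative: str | None) -> dict[str, float]:
    if spike_class == "binary":
        if alternative is None:
            raise ValueError("binary position requires an 'alternative' residue")
        return {wildtype: wt_fraction, alternative: 1.0 - wt_fraction}
    alphabet = CLASS_ALPHABETS[spike_class]
    others = [aa for aa in alphabet if aa != wildtype]
    dist = {aa: (1.0 - wt_fraction) / len(others) for aa in others}
    dist[wildtype] = wt_fraction
    return dist


def _default_config_path() -> Path:
    return Path(str(resources.files("seqforge").joinpath("data/sequestrin_design.yaml")))


def load_design(config_source: str | Path | dict | None = None) -> LibraryDesign:
    """Load and validate a library design from a YAML config (packaged default).

    Every violation found is reported at once inside DesignValidationError.
    """
    if config_source is None:
        config_source = _default_config_path()
    if isinstance(config_source, dict):
        cfg = config_source
    else:
        with open(config_source) as fh:
            cfg = yaml.safe_load(fh)

    errors: list[str] = []
    scaffold_cfg = cfg.get("scaffold", {})
    gene = (scaffold_cfg.get("gene") or "").replace("\n", "").strip().upper()
    if not gene:
        raise DesignValidationError(["scaffold.gene missing"])
    if len(gene) % 3:
        errors.append(f"scaffold gene length {len(gene)} not divisible by 3")
    if any(b not in "ACGTN" for b in gene):
        errors.append("scaffold gene contains non-ACGTN symbols")
    for i, codon in enumerate(codons_of(gene)):
        if "N" in codon and codon != "NNN":
            errors.append(f"codon {i}: partial degeneracy {codon!r} (Ns must form NNN triplets)")

    subunit_length = int(scaffold_cfg.get("subunit_length", 46))
    cys_position = int(scaffold_cfg.get("cys_position", 17))
    policy = cfg.get("codon_policy", "ecoli-most-frequent")

    wt_default = float(cfg.get("spiked_wildtype_fraction", 0.61))
    positions: list[PositionSpec] = []
    seen: set[tuple[int, int]] = set()
    for entry in cfg.get("positions", []):
        key = (int(entry["subunit"]), int(entry["position"]))
        if key in seen:
            errors.append(f"position {key[0]}:{key[1]}: duplicated")
            continue
        seen.add(key)
        spike_class = entry.get("class", "spiked")
        wildtype = entry["wildtype"]
        if "distribution" in entry:
            dist = {aa: float(p) for aa, p in entry["distribution"].items()}
        else:
            try:
                dist = _class_distribution(
                    spike_class, wildtype,
                    float(entry.get("wildtype_fraction",
                                    0.5 if spike_class == "binary" else wt_default)),
                    entry.get("alternative"),
                )
            except (KeyError, ValueError) as exc:
                errors.append(f"position {key[0]}:{key[1]}: {exc}")
                continue
        spec = PositionSpec(key[0], key[1], wildtype, spike_class, dist)
        errors.extend(spec.validate())
        positions.append(spec)

    n_codons = len(gene) // 3
    n_degenerate = sum(1 for c in codons_of(gene) if c == "NNN")
    if n_degenerate != len(positions):
        errors.append(
            f"gene has {n_degenerate} NNN codons but config lists {len(positions)} positions"
        )

    design = LibraryDesign(
        scaffold=ScaffoldSpec(gene, subunit_length, cys_position),
        positions=positions,
        codon_policy=policy,
    )
    # degenerate codons in the template must sit exactly at the configured positions
    template_codons = codons_of(gene)
    for spec in positions:
        idx = design.residue_index(spec.subunit, spec.position)
        if idx >= n_codons or template_codons[idx] != "NNN":
            errors.append(
                f"position {spec.subunit}:{spec.position}: template codon at protein index "
                f"{idx} is not NNN"
            )
    if errors:
        raise DesignValidationError(errors)

    # derive the wildtype proteins and re-check scaffold invariants
    codon_map = policy_codon_map(policy, gene)
    codons = list(template_codons)
    for spec in positions:
        codons[design.residue_index(spec.subunit, spec.position)] = codon_map[spec.wildtype]
    full_protein = translate("".join(codons))
    if "*" in full_protein:
        errors.append("wildtype gene contains a stop codon")
    if full_protein.count("C") != 2:
        errors.append(f"full protein has {full_protein.count('C')} cysteines, expected 2")
    for subunit in (1, 2):
        sub_gene = design.scaffold.subunit_gene(subunit)
        if codons_of(sub_gene).count("TGT") != 1:
            errors.append(f"subunit {subunit} fixed DNA must contain exactly one TGT codon")
    if errors:
        raise DesignValidationError(errors)

    L = subunit_length
    scaffold = ScaffoldSpec(
        gene, subunit_length, cys_position,
        subunit_protein=full_protein[:L],
        linker_protein=full_protein[L:L + len(LINKER_PROTEIN) + len(RAS_PROTEIN)] + full_protein[-1],
        full_protein=full_protein,
    )
    design.scaffold = scaffold
    design.codon_mixtures = {
        (p.subunit, p.position): design_codon_mix(p.distribution, policy, gene)
        for p in positions
    }
    return design


def design_codon_mix(residue_distribution: dict[str, float],
                     codon_choice_policy: str = "ecoli-most-frequent",
                     template_gene: str | None = None) -> list[tuple[str, float]]:
    """One codon per residue, fraction equal to the residue's probability.

    Back-translating the mixture reproduces the input distribution exactly;
    the synthesis platform allows arbitrary codon choices, so the policy only
    picks which synonymous codon represents each residue.
    """
    if not residue_distribution:
        raise ValueError("empty residue distribution")
    total = sum(residue_distribution.values())
    if not math.isclose(total, 1.0, abs_tol=_PROB_TOL):
        raise ValueError(f"residue probabilities sum to {total:.6g}, not 1")
    codon_map = policy_codon_map(codon_choice_policy, template_gene)
    mix = []
    for aa, p in residue_distribution.items():
        if aa not in codon_map:
            raise ValueError(f"no codon for residue {aa!r} under policy {codon_choice_policy!r}")
        if p > 0:
            mix.append((codon_map[aa], float(p)))
    return mix


def assemble_gene(subunit1_oligo: str, subunit2_oligo: str, overlap_length: int) -> str:
    """Hybridize two oligos sharing `overlap_length` identical terminal bases.

    The overlap region is counted once in the product.  Degenerate bases must
    match literally (N pairs only with N).
    """
    if overlap_length < 0 or overlap_length > min(len(subunit1_oligo), len(subunit2_oligo)):
        raise ValueError("overlap length out of range")
    tail = subunit1_oligo[len(subunit1_oligo) - overlap_length:]
    head = subunit2_oligo[:overlap_length]
    for i, (a, b) in enumerate(zip(tail, head)):
        if a != b:
            raise OverlapMismatchError(i, a, b)
    return subunit1_oligo + subunit2_oligo[overlap_length:]


def split_gene(gene: str, junction_position: int, overlap_length: int) -> tuple[str, str]:
    """Inverse of assembly: two oligos sharing `overlap_length` bases at the junction.

    The shared region is centred on the junction; `assemble_gene(o1, o2,
    overlap_length)` reconstructs the input exactly.
    """
    left = overlap_length // 2
    right = overlap_length - left
    if junction_position - left < 0 or junction_position + right > len(gene):
        raise ValueError("junction/overlap out of range")
    if junction_position <= 0 or junction_position >= len(gene):
        raise ValueError("junction must lie strictly inside the gene")
    return gene[:junction_position + right], gene[junction_position - left:]


def theoretical_diversity(design: LibraryDesign) -> int:
    """Exact count of encodable protein variants (big-integer product)."""
    count = 1
    for spec in design.positions:
        count *= len(spec.allowed_residues)
    return count


def mutation_load_distribution(design: LibraryDesign,
                               classes: tuple[str, ...] | None = MUTATION_CLASSES) -> MutationLoad:
    """Exact Poisson-binomial PMF of the number of mutated designed positions.

    Computed by dynamic-programming convolution over per-position mutation
    probabilities; positions lacking the wildtype contribute probability-1
    events.  By default only the spiked (61/39) classes count as mutations;
    pass ``classes=None`` to include the binary 50:50 toggles.
    """
    probs = [p.mutation_probability for p in design.positions
             if classes is None or p.spike_class in classes]
    pmf = np.array([1.0])
    for q in probs:
        pmf = np.convolve(pmf, [1.0 - q, q])
    k = np.arange(pmf.size)
    mean = float(np.dot(k, pmf))
    variance = float(np.dot((k - mean) ** 2, pmf))
    return MutationLoad(pmf=pmf, mean=mean, variance=variance)


def sample_clones(design: LibraryDesign, n: int,
                  seed: int | np.random.Generator) -> list[str]:
    """Draw `n` clone genes: each randomized codon sampled independently from
    its mixture, fixed codons verbatim; reproducible under a fixed seed."""
    if n < 0:
        raise ValueError("n must be nonnegative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    template = codons_of(design.scaffold.gene)
    draws: dict[int, np.ndarray] = {}
    mixtures: dict[int, list[str]] = {}
    for spec in design.positions:
        idx = design.residue_index(spec.subunit, spec.position)
        mix = design.codon_mixtures[(spec.subunit, spec.position)]
        codons = [c for c, _ in mix]
        probs = np.array([f for _, f in mix])
        probs = probs / probs.sum()
        mixtures[idx] = codons
        draws[idx] = rng.choice(len(codons), size=n, p=probs)
    clones = []
    for i in range(n):
        codons = list(template)
        for idx, picks in draws.items():
            codons[idx] = mixtures[idx][picks[i]]
        clones.append("".join(codons))
    return clones
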