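"""Sequencing-based library QC: clone classification, per-position residue
frequencies against the design, and mutation-load shifts between pools.

The wet campaign screens clones by insert length (PCR) and Sanger sequencing;
here the same decisions are made on the sequences directly.  A clone is a
*sequestrin* when its insert is the full-length in-frame stop-free dimeric
gene, a *monomer* when only a single-subunit-sized in-frame fragment is
present, and a *dummy* otherwise (frameshifts, premature stops, unrelated
inserts).  Mutations are counted at the designed spiked positions relative to
the scaffold wildtype; sequencing-error-like substitutions outside designed
positions ("off-design") and the binary 50:50 design toggles are tracked
separately and never inflate the designed-mutation count.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._codons import STOP_CODONS, codons_of, translate
from .library_design import MUTATION_CLASSES, LibraryDesign

__all__ = [
    "CloneRecord",
    "PositionFrequencyTable",
    "PoolComparison",
    "classify_insert",
    "analyze_clone",
    "count_mutations",
    "position_frequencies",
    "compare_pools",
    "class_fractions",
]

#: Single-subunit insert length window (nt): one subunit with/without linker
#: remnants.  The screen in the campaign is length-based without printed
#: cutoffs, so the window is exposed as a parameter with these defaults.
MONOMER_WINDOW = (127, 190)

RESTRICTION_FLANKS = ("GGATCC", "GTCGAC")   # BamHI / SalI


@dataclass
class CloneRecord:
    """One sequenced library member and its interpretation against a design."""

    id: str
    dna: str
    clone_class: str                     # sequestrin | monomer | dummy | invalid
    protein: str | None = None
    mutations: set[tuple[int, int, str]] = field(default_factory=set)
    design_toggles: set[tuple[int, int, str]] = field(default_factory=set)
    off_design: set[tuple[int, str]] = field(default_factory=set)

    @property
    def n_mutations(self) -> int:
        return len(self.mutations)

    @property
    def is_design_only(self) -> bool:
        """True when the clone differs from wildtype only where designed."""
        return not self.off_design


@dataclass
class PositionFrequencyTable:
    """Observed vs designed residue frequencies at every randomized position."""

    table: pd.DataFrame          # columns: subunit, position, residue, observed, designed
    tv_distance: pd.Series       # per (subunit, position) total-variation distance
    clone_count: int

    @property
    def max_tv(self) -> float:
        return float(self.tv_distance.max())


@dataclass
class PoolComparison:
    """Mutation-load and composition shift between a naive and a selected pool."""

    naive_mean_mutations: float
    selected_mean_mutations: float
    mean_shift: float                       # naive - selected
    enrichment: pd.DataFrame                # per (subunit, position, residue) ratio
    naive_design_only_fraction: float
    selected_design_only_fraction: float


def _strip_flanks(dna: str) -> str:
    if dna.startswith(RESTRICTION_FLANKS[0]):
        dna = dna[len(RESTRICTION_FLANKS[0]):]
    if dna.endswith(RESTRICTION_FLANKS[1]):
        dna = dna[:-len(RESTRICTION_FLANKS[1])]
    return dna


def _frame0_stop_free(dna: str) -> bool:
    usable = dna[: len(dna) - len(dna) % 3]
    return not any(c in STOP_CODONS for c in codons_of(usable))


def classify_insert(dna: str, design: LibraryDesign,
                    monomer_window: tuple[int, int] = MONOMER_WINDOW) -> str:
    """Classify one insert as sequestrin / monomer / dummy / invalid.

    Sequestrin: full gene length after flank stripping, in frame, stop-free.
    Monomer: single-subunit-sized fragment whose frame-0 reading is stop-free.
    Dummy: anything else over ACGT.  Invalid: empty or non-nucleotide symbols.
    """
    if not dna:
        return "invalid"
    dna = dna.upper()
    if any(b not in "ACGT" for b in dna):
        return "invalid"
    dna = _strip_flanks(dna)
    full = len(design.scaffold.gene)
    if len(dna) == full and _frame0_stop_free(dna):
        return "sequestrin"
    if monomer_window[0] <= len(dna) <= monomer_window[1] and _frame0_stop_free(dna):
        return "monomer"
    return "dummy"


def analyze_clone(clone_id: str, dna: str, design: LibraryDesign,
                  monomer_window: tuple[int, int] = MONOMER_WINDOW) -> CloneRecord:
    """Classify and, for sequestrins, call designed / toggle / off-design changes."""
    clone_class = classify_insert(dna, design, monomer_window)
    record = CloneRecord(id=clone_id, dna=dna, clone_class=clone_class)
    if clone_class != "sequestrin":
        return record
    protein = translate(_strip_flanks(dna.upper()))
    record.protein = protein
    wildtype = design.scaffold.full_protein
    designed = {design.residue_index(p.subunit, p.position): p for p in design.positions}
    for i, (obs, wt) in enumerate(zip(protein, wildtype)):
        if obs == wt:
            continue
        spec = designed.get(i)
        if spec is None:
            record.off_design.add((i, obs))
        elif spec.spike_class == "binary":
            record.design_toggles.add((spec.subunit, spec.position, obs))
        else:
            record.mutations.add((spec.subunit, spec.position, obs))
    return record


def count_mutations(clone: CloneRecord, design: LibraryDesign) -> int:
    """Number of designed spiked positions differing from wildtype.

    Off-design substitutions and binary-position toggles are available on the
    record but never included in this count.
    """
    if clone.clone_class != "sequestrin":
        raise ValueError(f"mutation counting requires a sequestrin clone, got {clone.clone_class!r}")
    if clone.protein is None:
        raise ValueError("clone is untranslated")
    return clone.n_mutations


def _as_records(clones, design: LibraryDesign) -> list[CloneRecord]:
    out = []
    for i, c in enumerate(clones):
        if isinstance(c, CloneRecord):
            out.append(c)
        else:
            out.append(analyze_clone(f"clone_{i}", c, design))
    return out


def class_fractions(clones, design: LibraryDesign) -> dict[str, float]:
    """Fractions of each clone class in a pool (sums to 1)."""
    records = _as_records(clones, design)
    if not records:
        raise ValueError("empty pool")
    counts = Counter(r.clone_class for r in records)
    return {k: counts.get(k, 0) / len(records)
            for k in ("sequestrin", "monomer", "dummy", "invalid")}


def position_frequencies(clones, design: LibraryDesign) -> PositionFrequencyTable:
    """Observed residue frequencies at every designed position vs the design.

    Only sequestrin-class clones contribute.  The summary total-variation
    distance per position quantifies how well the library maintains the
    designed distribution.
    """
    records = [r for r in _as_records(clones, design) if r.clone_class == "sequestrin"]
    if not records:
        raise ValueError("no sequestrin-class clones to tabulate")
    rows = []
    tv = {}
    for spec in design.positions:
        idx = design.residue_index(spec.subunit, spec.position)
        observed = Counter(r.protein[idx] for r in records)
        n = sum(observed.values())
        residues = sorted(set(observed) | set(spec.distribution))
        obs_freq = {aa: observed.get(aa, 0) / n for aa in residues}
        for aa in residues:
            rows.append({
                "subunit": spec.subunit, "position": spec.position, "residue": aa,
                "observed": obs_freq[aa], "designed": spec.distribution.get(aa, 0.0),
            })
        tv[(spec.subunit, spec.position)] = 0.5 * sum(
            abs(obs_freq[aa] - spec.distribution.get(aa, 0.0)) for aa in residues)
    table = pd.DataFrame(rows)
    tv_series = pd.Series(tv, name="tv_distance")
    tv_series.index.names = ["subunit", "position"]
    return PositionFrequencyTable(table=table, tv_distance=tv_series, clone_count=len(records))


def compare_pools(naive_clones, selected_clones, design: LibraryDesign,
                  pseudocount: float = 0.5) -> PoolComparison:
    """Mutation-load shift and per-position enrichment between two pools.

    Enrichment is (selected frequency / naive frequency) with additive
    smoothing (`pseudocount` per residue) so unobserved residues never divide
    by zero.
    """
    naive = [r for r in _as_records(naive_clones, design) if r.clone_class == "sequestrin"]
    selected = [r for r in _as_records(selected_clones, design) if r.clone_class == "sequestrin"]
    if not naive or not selected:
        raise ValueError("both pools must contain at least one sequestrin clone")

    naive_mean = float(np.mean([r.n_mutations for r in naive]))
    selected_mean = float(np.mean([r.n_mutations for r in selected]))

    rows = []
    for spec in design.positions:
        idx = design.residue_index(spec.subunit, spec.position)
        obs_n = Counter(r.protein[idx] for r in naive)
        obs_s = Counter(r.protein[idx] for r in selected)
        residues = sorted(set(obs_n) | set(obs_s) | set(spec.distribution))
        k = len(residues)
        for aa in residues:
            f_n = (obs_n.get(aa, 0) + pseudocount) / (len(naive) + pseudocount * k)
            f_s = (obs_s.get(aa, 0) + pseudocount) / (len(selected) + pseudocount * k)
            rows.append({
                "subunit": spec.subunit, "position": spec.position, "residue": aa,
                "naive_freq": f_n, "selected_freq": f_s, "enrichment": f_s / f_n,
            })
    return PoolComparison(
        naive_mean_mutations=naive_mean,
        selected_mean_mutations=selected_mean,
        mean_shift=naive_mean - selected_mean,
        enrichment=pd.DataFrame(rows),
        naive_design_only_fraction=float(np.mean([r.is_design_only for r in naive])),
        selected_design_only_fraction=float(np.mean([r.is_design_only for r in selected])),
    )
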