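# seqforge

A desk-scale toolkit for the computational side of a **sequestrin**
phage-display campaign.  Sequestrins are head-to-tail dimeric affibody
scaffolds — two N-terminally truncated 46-residue subunits joined by an
Ala + (S₄G)₂ linker and stabilized by one interchain disulphide — that
encapsulate aggregation-prone peptides such as amyloid-β in a tunnel-like
cavity and thereby inhibit fibril formation.  `seqforge` implements, for
protein engineers building or analysing such libraries:

* **Spiked-codon library design** — the 22-position randomization scheme
  (11 per subunit) in which 18 positions keep the wildtype codon at 61%
  mixed with 39% mutation codons from class-specific alphabets
  (hydrophobic-core, beta-strand, surface) and 4 positions toggle 50:50
  between two residues; degenerate-oligo assembly/splitting; exact
  big-integer theoretical diversity (∏ᵢ |allowedᵢ|, here ≈ 1.26 × 10²²);
  and the exact Poisson-binomial mutation-load distribution (mean
  18 × 0.39 = 7.02 mutations per clone).
* **Sequencing QC** — clone classification (sequestrin / monomer / dummy /
  invalid), per-position residue frequencies vs the design with
  total-variation summaries, and naive-vs-selected pool comparison
  (mutation-load shift, smoothed enrichment ratios).
* **Panning simulation** — multi-round selection with equilibrium capture
  `eff·C/(C+K_D)`, first-order wash survival `exp(−k_d·t_wash)`, complete
  elution and per-class growth bias, in deterministic or seeded binomial
  mode.
* **Binding biophysics** — closed-form 1:1 Langmuir sensorgrams and a
  global multi-start least-squares fit sharing (k_a, k_d, R_max) across a
  dilution series with K_D = k_d/k_a; CD difference spectra
  (complex − Σ free); two-state thermal melting with linear baselines
  (van't Hoff form) yielding T_m; refolding similarity scores;
  stoichiometric aggregation inhibition free-peptide = max(0, total − n·I);
  ELISA display-normalization; average protein masses.
* **Synthetic data** — seeded generators for every input above (Sanger-style
  reads at a 72/24/4 class mixture, duplicate multi-cycle sensorgrams on a
  1:1.5 series from 342 to 30 nM, three-basis CD spectra, melting curves,
  logistic thioflavin-T aggregation traces), each with recoverable ground
  truth.

## Worked example

Validate the packaged design and print its headline combinatorics:

```
$ forge design validate
design OK: 22 randomized positions, 107-residue scaffold

$ forge design diversity
{
  "theoretical_diversity": 1.2607388021510646e+22,
  "theoretical_diversity_exact": "12607388021510646414736",
  "mean_mutations": 7.0200000000000005,
  "variance_mutations": 4.2822000000000005
}
```

`theoretical_diversity` is the number of distinct encodable protein
variants; `mean_mutations` is the expected number of spiked-position
mutations per clone (the Poisson-binomial mean over the eighteen 61/39
positions — "about seven mutations per clone").

Generate a melting curve at a known midpoint and fit it back:

```
$ forge synth melt --tm 59 --seed 1 --out melt59.csv
$ forge fit tm --input melt59.csv
{
  "tm_c": 58.99999999999998,
  "dh_kj_mol": 300.0000000000001,
  "amplitude": 7.7049999999999965
}
```

The fitted `tm_c` is the two-state transition midpoint in °C;
`amplitude` is the separation of the folded/unfolded baselines at T_m in
the signal units (millidegrees at 221 nm).

The same pattern runs end to end from the library: `forge synth reads` →
`forge qc classify|freqs` → `forge pan run` → `forge synth spr` →
`forge fit kinetics`.

## Layout

```
src/seqforge/library_design.py   design loading, oligo assembly, combinatorics
src/seqforge/sequence_qc.py      classification, frequencies, pool comparison
src/seqforge/panning.py          selection-round simulator
src/seqforge/biophysics.py       SPR / CD / melting / ThT / ELISA / mass models
src/seqforge/synthetic.py        seeded generators for all pipeline inputs
src/seqforge/io.py, cli.py       FASTA/FASTQ/CSV I/O and the `forge` CLI
src/seqforge/data/               packaged design config + 321-nt oligo fixture
docs/methods.md                  model assumptions, parameters, limitations
```
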