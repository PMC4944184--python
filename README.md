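# igprofile

Analysis of IgG heavy-chain repertoires from VH-Cγ amplicons — the ~650 bp
RT-PCR products that capture a B cell's rearranged variable region together
with enough constant region to read its IgG subclass. The package targets
the questions asked of tissue-resident (e.g. cutaneous) B-cell repertoires:

* **Annotation** — assign germline V/D/J genes and the IgG1–4 subclass,
  number the sequence with fixed IMGT positions (FR1 1–26 … CDR3 105–117,
  FR4 118–128), extract the junction between the conserved Cys-104 and
  Trp-118, and count silent vs non-silent mutations per region.
* **Somatic hypermutation & selection** — per-sequence BASELINe-style
  selection tests: under no selection the CDR share of a sequence's V-region
  mutations is Binomial(*n*, *f*) with *f* the analysable-nucleotide
  fraction of the CDRs; an exact two-sided binomial test (tail-doubling)
  scores departure, and observed/total < *f* marks negative (purifying)
  selection. Cohort mutation loads compare by Mann–Whitney U.
* **Profiling** — subclass distribution, VH family usage, CDR3 length
  spectratype with the D'Agostino–Pearson omnibus normality test
  (K² = Z₁² + Z₂² ~ χ², 2 df), positional non-silent mutation frequencies
  with SHM hotspots at >35% of sequences, and Jaccard concordance with
  predicted antigen-binding residues flagged at >25%.
* **Clones, switching, lineages** — clone grouping by identical V(D)J
  junction, class-switch detection (identical-V(D)J "strict" events and
  clone-level "clonal" events), and minimum-mutation lineage trees rooted
  at the germline with hypothetical intermediates at shared-mutation branch
  points.
* **Simulation** — a ground-truthed VH-Cγ repertoire generator (junctional
  trimming and N additions, WRC/GYW hotspot-targeted SHM lineages,
  intra-clonal subclass switching, cohort subclass skews) so every stage is
  testable end to end without external data.

A small curated synthetic germline reference (10 IGHV across families 1–5,
3 IGHJ, 5 IGHD, 4 IGHG fragments) ships with the package;
`docs/methods.md` documents the models, conventions and limitations.

## Worked example

```python
from igprofile import (SimConfig, annotate_repertoire, build_cohort_profile,
                       dedupe_unique, default_reference, simulate_repertoire)

reference = default_reference()
rep = simulate_repertoire(SimConfig(n_clones=60, shm_rate=0.02, seed=7),
                          reference)
annotated, rejected = annotate_repertoire(rep.sequences, reference)
unique = dedupe_unique(annotated)
profile = build_cohort_profile("example", unique)
```

Running `python examples/02_annotate_and_profile.py` (the same computation,
with printing) gives:

```
annotated 153 sequences (0 rejected), 153 unique

example record clone0000_00: IGHV5-51 (97.8% germline identity), IGHJ6,
subclass IgG3, CDR3 LMHPCLTN (8 aa)
V-region mutations: 3 silent + 4 non-silent (CDR3 excluded: junctional nt
have no germline counterpart)

subclass distribution (fraction of assigned calls):
  IgG1: 0.19
  IgG2: 0.43
  IgG3: 0.22
  IgG4: 0.16
VH family usage: {'VH1': 0.18, 'VH2': 0.22, 'VH3': 0.14, 'VH4': 0.29, 'VH5': 0.17}
CDR3 length normality: K2=10.56, p=0.005 (rejected)
```

The record line is the per-sequence annotation (germline V call with
percent identity, subclass from the constant fragment, CDR3 peptide); the
distributions are cohort summaries, and the normality test rejects a
Gaussian CDR3 spectratype — here the mixture of clones happens to produce a
multimodal length distribution, the same readout used to flag skewed
tissue repertoires. The other scripts in `examples/` walk through
simulation (`01`), selection testing under CDR-mutation depletion (`03`),
and clone/switch/lineage reconstruction (`04`), each printing a few lines
and saying what they mean.

A thin CLI wraps the same library for shell use:

```bash
igprofile simulate --n-clones 50 --seed 1 --out-fasta rep.fasta --out-truth truth.tsv
igprofile run-all --input rep.fasta --outdir out/ --cohort-id skin
```

`run-all` writes an AIRR-style rearrangement table, selection and clone
tables, a profile JSON, Newick lineage trees and a manifest with input
checksums; reruns are bitwise identical.

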