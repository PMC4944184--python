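# Methods

`igprofile` analyses IgG heavy-chain VH-Cγ amplicon repertoires — the kind
of data produced by cloning and Sanger-sequencing ~650 bp RT-PCR products
that span the rearranged variable region into the constant region, so that a
single read yields both the V(D)J annotation and the IgG subclass. This note
documents the models, conventions and numerical choices behind each stage,
what the simulator does and does not emulate, and the package's known
limitations.

## Germline model and numbering

The variable domain is numbered with fixed IMGT unique-numbering codon
positions 1–128 and partitioned as FR1 1–26, CDR1 27–38, FR2 39–55,
CDR2 56–65, FR3 66–104, CDR3 105–117, FR4 118–128. Insertion codes are not
supported: packaged and simulated germlines are built gap-free, so codon *k*
of a V gene sits at IMGT position *k*. This deliberately removes the hardest
unstated part of a full IMGT gapped alignment while preserving the CDR/FWR
partition that every downstream statistic depends on. CDR3s shorter than the
full 13 codons are accommodated (the V- and J-anchored codons keep their
positions; only junction-interior codons are unnumbered, and nothing
downstream consumes them).

The packaged reference (`data/synthetic_germline.fasta`) is a synthetic
curated set: two V genes per family VH1–VH5 (318 nt = 106 codons, with the
conserved 1st-CYS at codon 23, Trp-41 and 2nd-CYS at codon 104), three J
genes (48 nt covering positions 113–128, Trp-118 at local codon 6), five D
genes (12–16 nt) and four Cγ constant-region 5′ fragments (270 nt, ~90%
pairwise identity, mirroring the high similarity of real IGHG subclass CH1
regions). Within-family V genes are ~10% diverged and J genes ~15%,
emulating realistic within-family similarity. The generator script
(`scripts/make_synthetic_reference.py`, fixed seed) documents exactly how
the fixture was built; analyses are only comparable within one fixed
reference, as gene-level identity always is across database releases.

## Repertoire simulator

The simulator supplies ground truth for every pipeline stage. Its defaults
are the study conditions the validation suite runs under:

| parameter | default | meaning |
|---|---|---|
| `clone_size_law` | geometric, mean 3 | observed sequences per clone |
| `shm_rate` | 0.01 /nt/generation | per-site substitution probability |
| `hotspot_multiplier` | 5.0 | rate multiplier inside WRC/GYW motifs |
| `switch_prob` | 0.1 /daughter | subclass switch probability |
| `subclass_prior` | (0.34, 0.33, 0.21, 0.12) | IgG1–4 clone-root prior |
| `junction_n_len_law` | uniform 0–6 nt | N-addition lengths |
| `trim_law` | uniform 0–4 nt | 3′V/5′D/3′D/5′J exonuclease trims |
| `generations` | 3 | lineage depth |

The subclass prior is a skin-like skew — IgG1-dominant with a distinct
IgG4 component — rather than the serum distribution, because the analyses
target tissue-derived cohorts where such skews are the object of study.

Each clone draws V/D/J uniformly from the reference and joins them with
trims and N additions; junctions colliding with an earlier clone,
out-of-frame products (frame is restored by extending the second N region),
internal stop codons, and CDR3 lengths outside 5–13 codons are rejected and
redrawn. Lineages grow by attaching each new cell to a random existing node
below the depth limit; a daughter inherits its parent's sequence, adds
per-site substitutions (target base uniform over the three alternatives),
and switches to a uniformly chosen different subclass with probability
`switch_prob`. Hotspot targeting multiplies the per-site rate inside WRC
motifs (at the C) and GYW motifs (at the G), evaluated on the parent
sequence; because GYW is the reverse complement of WRC, scanning both on the
forward strand covers both DNA strands.

Three modelling choices matter for interpretation:

* **SHM is confined to IMGT codons 1–103.** The junction (codons 104–118)
  is conserved within a clone and the constant fragment is never mutated.
  Identical-junction clone identity is therefore exact in truth, which is
  what makes clone-recovery validation a sharp test; mutation statistics
  exclude CDR3 anyway (junctional nucleotides have no germline
  counterpart). Real repertoires do mutate CDR3, so on real data the
  identical-junction clone definition is conservative (it may split
  lineages whose junctions diverged).
* **Class switching is a subclass relabel** with no switch-region sequence
  mechanics — the analyses only ever observe subclass labels on identical
  or clonally related V(D)J sequences.
* **Multiple hits and back-mutations can occur**; truth records store the
  net per-position difference to the naive ancestor plus the raw event
  count, so multi-hit cases are identifiable and tests can restrict to the
  single-hit regime where mutation counts equal Hamming distances.

The simulator does **not** emulate indels, gene conversion, sequencing
error, chromatogram quality, allelic variation, or light chains. Passing
validation therefore demonstrates correctness of the analysis machinery
under a clean substitution-only model, not robustness to the full error
structure of wet-lab data.

## Annotation

Gene assignment scores the query against every reference gene (the
reference is small, so exhaustive pairwise scoring is affordable and
deterministic) with a global–local alignment: match +1, mismatch −1, gap
open −4, extend −1, free end gaps on the query only, so the gene must align
end to end and percent identity is measured over the full gene span. This
prevents short spurious perfect local matches from outscoring the true gene.
Ties break by longer aligned span, then lexicographic gene name. Queries
whose best V identity falls below 70% are rejected as non-IgH. The
*reported* V identity is then recomputed over the germline-comparable
region (codons 1–104) — the trimmed V 3′ tail aligns against junctional
nucleotides and would otherwise dilute identity even for unmutated
sequences; J identity is likewise reported over the region 3′ of the
junctional trim.

The junction is extracted between the anchors: codon 104 from the V
numbering map through codon 118 (Trp) from the J map; CDR3 is the junction
minus both anchor codons, reported in amino acids. An in-frame stop anywhere
in the junction flags the sequence non-productive and removes it from CDR3
length statistics. D genes are reported only when an ungapped match of at
least 5 nt to a D gene lies between the V and J spans — shorter matches are
indistinguishable from chance in N-rich junctions.

Mutation counting compares the query to the assigned germline V over codons
1–104. Every mismatched nucleotide is one event, attributed to the region of
its codon and classified **silent** if applying that single substitution
alone to the germline codon preserves the amino acid. A codon with two
mismatches can therefore contribute one silent and one non-silent event;
this per-substitution convention (rather than whole-codon translation) is
documented because totals depend on it. Positions aligned to gaps or
ambiguity characters are counted as uncallable, never as mutations.

Subclass calls align the post-J fragment to each Cγ reference and require
≥90% nucleotide identity, with identity ties resolved by greater coverage
and residual ties left unassigned. The threshold is applied to nucleotide
identity, matching a cloning/Sanger workflow in which the read itself is
nucleotide sequence.

## Selection testing

Following the expected-versus-observed logic of BASELINe, mutation
*placement* is tested per sequence: under no selection, the number of
mutations falling in the CDR class (CDR1+CDR2) out of the sequence's total
V-region mutations is Binomial(total, f), where f is the fraction of
analysable V-region nucleotides in the class — uniform mode uses the raw
nucleotide fraction (66/312 ≈ 0.212 for the packaged genes); hotspot-
weighted mode re-weights each germline position by the WRC/GYW multiplier.
The two-sided p-value doubles the smaller exact binomial tail and caps at 1
(two-sided conventions for exact tests differ; tail-doubling is the one
implemented and tested). Direction is the sign of observed/total − f.
Zero-mutation sequences carry no placement information and are withheld
from cohort fractions. Cohort summaries report direction fractions both
regardless of significance and at p < α.

Two properties of this test deserve emphasis. First, it is exactly
antisymmetric: the CDR and FWR tests of one sequence have identical
p-values and opposite directions. Second, it is **conservative**: being an
exact discrete test, its realised Type-I rate at nominal α = 0.05 is well
below 0.05 at realistic SHM loads (~0.01 at 3–10 mutations per sequence,
still ≤0.033 at 40), so significant calls understate, never overstate,
selection. The full BASELINe posterior machinery (selection strength Σ,
focused test, targeting priors) is intentionally out of scope; the
two-region exact binomial keeps the mathematics fully specified and
independently verifiable.

Cohort mutation-rate comparisons use a two-sided Mann–Whitney U: exact
enumeration for small tie-free samples (either side < 8), normal
approximation with tie correction otherwise.

## Profiling

Subclass and VH-family distributions are proportions over assigned calls
(unassigned counted separately). The CDR3 spectratype is tested for
normality with the D'Agostino–Pearson omnibus statistic, implemented from
the original transforms — D'Agostino's skewness Z₁, Anscombe & Glynn's
kurtosis Z₂, K² = Z₁² + Z₂² against χ²(2df) — rather than delegated, so an
independent reference implementation can serve as a cross-check in the test
suite (agreement to 6 significant figures; n ≥ 20 and positive variance
required). Positional profiles report, per IMGT codon, the fraction of
sequences with ≥1 non-silent substitution; SHM hotspots are positions
strictly above 0.35, and predicted antigen-binding residues (consumed as an
upstream prediction table, one boolean per sequence and position) are
flagged strictly above 0.25. Both thresholds are strict inequalities and
configurable. Concordance between the two position sets is their Jaccard
index, plus a clustering summary counting maximal runs of consecutive
flagged positions.

## Clones, switching and lineage trees

Clones are sequences sharing V call, J call and byte-identical junction
nucleotides; an optional Hamming tolerance (default 0, single-linkage on
equal-length junctions) exists for noisy data. Class-switch events are
reported in two classes, because "identical V(D)J" is ambiguous: *strict*
events group byte-identical V(D)J regions (the constant fragment is
excluded from the comparison — it encodes the subclass itself) carrying ≥2
subclasses; *clonal* events are whole clones carrying ≥2 subclasses. A
strict event always implies a clonal event for its clone; both are emitted,
tagged.

Lineage trees minimise total substitutions under an irreversible
infinite-sites model within the clone: nodes are mutation sets (relative to
the germline V) ordered by containment, the root is the empty set, and the
tree cost is Σ|child − parent|. Violations of infinite sites (one position
mutated to different bases in different members) are detected and reported,
not resolved. The key structural facts are that every useful hypothetical
intermediate is an intersection of observed mutation sets, and that once
the node set is fixed the cost separates — each node simply takes the
largest strict subset present as its parent. The exact mode therefore
enumerates subsets of the intersection closure (clones ≤ 12 members and
≤ 16 optional intermediates; the enumeration is over integer bitmasks) and
keeps the cheapest; it was verified against an independent exhaustive
oracle that enumerates every multifurcating rooted topology and counts
minimal gains per character. Larger clones fall back to greedy
agglomeration (join the pair sharing the most mutations, insert the shared
set), which is flagged `exact=False` in the output. Intermediates with
fewer than two children are spliced out, so 'x' nodes appear only where
two or more descendant branches share mutations.

## Pipeline and reproducibility

`run_pipeline` chains annotate → dedupe (byte-identical amplicons collapse
to unique records with duplication counts) → selection → profile →
clone/switch/lineage, writing AIRR-style rearrangement tables (standard
column names where one exists, `igp_`-prefixed otherwise), per-sequence
selection tables, a JSON profile, clone/switch tables, Newick trees and an
edge list, plus a manifest with input SHA-256 checksums, thresholds, seed
and per-stage record counts. Outputs contain no timestamps; a rerun with
the same config is bitwise identical. All randomness in the package flows
through a single integer seed per simulation config.

## Validation scale

The validation suite and `scripts/acceptance.py` run the full pipeline on
simulated cohorts of 2,000 sequences for annotation round-trips, subclass/
VH-family recovery and neutral selection calibration, 800 sequences for the
CDR-depletion recovery experiment, ~360 sequences for clone/lineage/switch
recovery and 500 for the planted-hotspot experiment — sizes at which
3-standard-error recovery bands are meaningful for the proportions being
checked while a complete run stays in the minutes range on one CPU.

## Known limitations

* No insertion codes: sequences requiring IMGT insertion positions (CDR3
  longer than 13 codons is tolerated but unnumbered in its interior;
  V-region indels are not handled at all) are outside the model.
* Alleles are not resolved; gene-level calls only.
* The identical-junction clone definition and the infinite-sites tree model
  are exact for the simulator but approximations for real data (junction
  SHM, reversions, homoplasy).
* The selection test is per-sequence; mutations shared through clonal
  descent are counted once per sequence, not de-duplicated across a
  lineage, so clonally expanded samples overweight their clones' placement
  pattern (both per-sequence and per-clone groupings are available
  downstream).
* Binding-residue predictions are consumed, not produced; their quality is
  outside the package's control.
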