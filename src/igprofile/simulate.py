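"""Synthetic VH-Cgamma amplicon repertoire simulator with complete ground truth.

Emulates the statistical structure of a cutaneous IgG heavy-chain repertoire:
clones founded by distinct V(D)J rearrangements (junctional trimming and
N-additions), branching somatic-hypermutation lineages with AID hotspot
(WRC/GYW) targeting, intra-clonal switching among the IgG1-4 subclasses, and
cohort-level subclass skews. Amplicons span the rearranged VH region plus a
constant-region 5' fragment (~650 bp total, matching a VH-Cgamma RT-PCR
product).

Ground truth — clone membership, lineage parentage, gene assignments,
junction, subclass and the exact mutation list of every sequence — is emitted
alongside the FASTA so every analysis stage can be validated without any
external data.

Modelling notes
---------------
* SHM is applied to the V region upstream of the junction (IMGT codons
  1-103). The junction (codons 104-118) is conserved within a clone, which
  keeps identical-junction clone identity exact, and the constant fragment is
  untouched, matching a subclass call made on an unmutated C region.
* Hotspot targeting multiplies the per-site substitution probability inside
  classical AID motifs WRC/GYW (W=A/T, R=A/G, Y=C/T), evaluated on the
  current (parental) sequence; scanning both motifs on the forward strand
  covers both DNA strands because GYW is the reverse complement of WRC.
* Class switching is a subclass relabel along the lineage; no switch-region
  sequence mechanics are simulated, since the analysis only observes subclass
  labels on identical or clonally related V(D)J sequences.
* Back-mutations and repeated hits at one site can occur; truth records store
  the *net* difference to the naive ancestor (unique by position) plus the
  raw event count, so multi-hit cases are identifiable.
"""
from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .germline import GermlineGene, GermlineReference, region_of

__all__ = [
    "SimConfig",
    "TruthRecord",
    "NaiveRearrangement",
    "SimulatedRepertoire",
    "recombine_vdj",
    "mutate_lineage",
    "attach_constant_fragment",
    "simulate_repertoire",
    "simulate_binding_table",
    "hotspot_mask",
    "TRUTH_COLUMNS",
]

BASES = "ACGT"
STOPS = {"TAA", "TAG", "TGA"}
SUBCLASSES = ("IgG1", "IgG2", "IgG3", "IgG4")

#: nt index (0-based) where IMGT codon 104 starts in a gap-free rearrangement.
JUNCTION_START_NT = 3 * (104 - 1)
#: number of nt after the junction (FR4 codons 119-128).
FR4_TAIL_NT = 3 * 10

TRUTH_COLUMNS = ["sequence_id", "clone_id", "parent_id", "v_call", "d_call",
                 "j_call", "c_call", "junction", "subclass", "generation",
                 "mutations", "n_mutation_events"]


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the repertoire generator.

    Defaults describe the study conditions the analyses are validated under:
    geometric clone sizes with mean 3, per-site per-generation SHM rate 0.01,
    five-fold hotspot targeting, 10% per-daughter switch probability and a
    skewed IgG subclass prior (IgG1-dominant with a distinct IgG4 component).
    """

    n_clones: int = 100
    clone_size_law: tuple = ("geometric", 3.0)   # or ("fixed", k)
    shm_rate: float = 0.01
    hotspot_multiplier: float = 5.0
    switch_prob: float = 0.1
    subclass_prior: tuple = (0.34, 0.33, 0.21, 0.12)
    junction_n_len_law: tuple = ("uniform", 0, 6)
    trim_law: tuple = ("uniform", 0, 4)
    generations: int = 3
    seed: int = 0
    cdr_rejection: float = 0.0
    planted_mutation: Optional[tuple] = None     # (imgt_codon, fraction)

    def __post_init__(self):
        if self.n_clones < 1:
            raise ValueError("n_clones must be positive")
        for name in ("shm_rate", "switch_prob", "cdr_rejection"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if self.hotspot_multiplier < 0:
            raise ValueError("hotspot_multiplier must be nonnegative")
        prior = np.asarray(self.subclass_prior, dtype=float)
        if prior.shape != (4,) or (prior < 0).any() or abs(prior.sum() - 1.0) > 1e-9:
            raise ValueError("subclass_prior must be 4 nonnegative values summing to 1")
        if self.generations < 1:
            raise ValueError("generations must be >= 1")


@dataclass
class TruthRecord:
    """Ground truth for one simulated sequence.

    ``mutations`` is the net difference of the VH region to the clone's naive
    ancestor: unique by position, each entry ``(nt_pos0, naive_base,
    observed_base)`` with ``nt_pos0`` 0-based in the VH (IMGT codon =
    ``nt_pos0 // 3 + 1``).
    """

    seq_id: str
    clone_id: str
    parent_id: str
    v_gene: str
    d_gene: str
    j_gene: str
    junction_nt: str
    subclass: str
    generation: int
    mutations: list = field(default_factory=list)
    n_mutation_events: int = 0

    @property
    def multi_hit(self) -> bool:
        return self.n_mutation_events > len(self.mutations)

    def mutations_str(self) -> str:
        return ";".join(f"{p}:{a}>{b}" for p, a, b in self.mutations)


@dataclass(frozen=True)
class NaiveRearrangement:
    """A naive (unmutated) V(D)J joint with its junction bookkeeping."""

    sequence: str
    junction_interval: Optional[tuple] = None   # (start, end) nt, half-open

    @property
    def junction_nt(self) -> Optional[str]:
        if self.junction_interval is None:
            return None
        s, e = self.junction_interval
        return self.sequence[s:e]


def _seq_of(gene) -> str:
    return gene.nt_sequence if isinstance(gene, GermlineGene) else str(gene)


def recombine_vdj(v, d, j, trims: Sequence[int] = (0, 0, 0, 0),
                  n1: str = "", n2: str = "") -> NaiveRearrangement:
    """Join V, D and J segments with exonuclease trims and N additions.

    ``trims`` are the nonnegative trim lengths (3'V, 5'D, 3'D, 5'J); the naive
    sequence is trimmed-V + n1 + trimmed-D + n2 + trimmed-J. The junction
    interval (IMGT codons 104-118) is recorded when the product is in frame
    and long enough to contain it.
    """
    v_nt, d_nt, j_nt = _seq_of(v), _seq_of(d), _seq_of(j)
    tv, td5, td3, tj = trims
    if min(tv, td5, td3, tj) < 0:
        raise ValueError("trims must be nonnegative")
    if tv >= len(v_nt):
        raise ValueError(f"3'V trim {tv} exhausts V segment of {len(v_nt)} nt")
    if td5 + td3 > len(d_nt):
        raise ValueError(
            f"D trims {td5}+{td3} exceed D segment of {len(d_nt)} nt")
    if tj >= len(j_nt):
        raise ValueError(f"5'J trim {tj} exhausts J segment of {len(j_nt)} nt")
    seq = (v_nt[:len(v_nt) - tv] + n1 + d_nt[td5:len(d_nt) - td3]
           + n2 + j_nt[tj:])
    interval = None
    end = len(seq) - FR4_TAIL_NT
    if len(seq) % 3 == 0 and end > JUNCTION_START_NT:
        interval = (JUNCTION_START_NT, end)
    return NaiveRearrangement(sequence=seq, junction_interval=interval)


def hotspot_mask(seq: str, mutable_end: Optional[int] = None) -> np.ndarray:
    """Boolean mask of AID hotspot positions (WRC and GYW, forward strand).

    WRC marks the C (mutable cytidine), GYW the G (the paired cytidine on the
    reverse strand); together they cover both strands.
    """
    n = len(seq) if mutable_end is None else min(mutable_end, len(seq))
    arr = np.frombuffer(seq.encode(), dtype="S1")
    mask = np.zeros(len(seq), dtype=bool)
    W = (arr == b"A") | (arr == b"T")
    R = (arr == b"A") | (arr == b"G")
    Y = (arr == b"C") | (arr == b"T")
    isC = arr == b"C"
    isG = arr == b"G"
    # WRC: positions i >= 2 with W[i-2] R[i-1] C[i]
    mask[2:] |= W[:-2] & R[1:-1] & isC[2:]
    # GYW: positions i <= n-3 with G[i] Y[i+1] W[i+2]
    mask[:-2] |= isG[:-2] & Y[1:-1] & W[2:]
    return mask[:n] if mutable_end is not None else mask


def _draw_length(law: tuple, rng: np.random.Generator) -> int:
    kind = law[0]
    if kind == "uniform":
        lo, hi = int(law[1]), int(law[2])
        return int(rng.integers(lo, hi + 1))
    if kind == "fixed":
        return int(law[1])
    if kind == "geometric":
        mean = float(law[1])
        return int(rng.geometric(1.0 / mean))
    raise ValueError(f"unknown distribution law {law!r}")


def _mutate_once(seq: str, config: SimConfig, rng: np.random.Generator,
                 mutable_end: int):
    """One lineage generation: per-site substitutions with hotspot weighting."""
    if config.shm_rate == 0.0:
        return seq, []
    rates = np.full(mutable_end, config.shm_rate)
    hot = hotspot_mask(seq, mutable_end)
    rates[hot] *= config.hotspot_multiplier
    np.clip(rates, 0.0, 1.0, out=rates)
    hits = np.nonzero(rng.random(mutable_end) < rates)[0]
    events = []
    chars = list(seq)
    for pos in hits:
        pos = int(pos)
        if config.cdr_rejection > 0.0:
            codon_pos = pos // 3 + 1
            if region_of(codon_pos) in ("CDR1", "CDR2"):
                if rng.random() < config.cdr_rejection:
                    continue
        old = chars[pos]
        alternatives = [b for b in BASES if b != old]
        new = alternatives[int(rng.integers(0, 3))]
        chars[pos] = new
        events.append((pos, old, new))
    return "".join(chars), events


def mutate_lineage(naive: str, config: SimConfig, rng: np.random.Generator,
                   n_descendants: int = 1, subclass: str = "IgG1",
                   mutable_end: Optional[int] = None) -> list[dict]:
    """Grow a branching SHM lineage from a naive sequence.

    Descendants are attached one at a time to a random existing node whose
    depth is below ``config.generations``; each daughter inherits its parent's
    sequence and adds per-site substitutions (hotspot-weighted) plus an
    optional subclass switch. Returns the observed descendants (the naive root
    itself is not observed) as dicts with keys ``sequence``, ``events``
    (cumulative substitution events vs naive), ``generation``, ``subclass``
    and ``parent`` (index into the returned list, -1 for the root).
    """
    if len(naive) < 3:
        raise ValueError("naive sequence must be at least one codon")
    if mutable_end is None:
        mutable_end = min(len(naive), JUNCTION_START_NT)
    nodes = [{"sequence": naive, "events": [], "generation": 0,
              "subclass": subclass, "parent": -2}]
    for _ in range(n_descendants):
        eligible = [i for i, nd in enumerate(nodes)
                    if nd["generation"] < config.generations]
        pidx = eligible[int(rng.integers(0, len(eligible)))]
        parent = nodes[pidx]
        seq, new_events = _mutate_once(parent["sequence"], config, rng,
                                       mutable_end)
        sub = parent["subclass"]
        if config.switch_prob > 0.0 and rng.random() < config.switch_prob:
            others = [s for s in SUBCLASSES if s != sub]
            sub = others[int(rng.integers(0, 3))]
        nodes.append({"sequence": seq,
                      "events": parent["events"] + new_events,
                      "generation": parent["generation"] + 1,
                      "subclass": sub,
                      "parent": pidx - 1})
    return nodes[1:]


def attach_constant_fragment(vh: str, subclass: str,
                             reference: GermlineReference) -> str:
    """Append the constant-region 5' fragment of an IgG subclass to a VH sequence."""
    try:
        c_gene = reference.c_gene_for_subclass(subclass)
    except KeyError as exc:
        raise ValueError(str(exc)) from None
    return vh + c_gene.nt_sequence


def _net_mutations(naive: str, seq: str, limit: int) -> list:
    return [(i, naive[i], seq[i]) for i in range(min(limit, len(naive)))
            if naive[i] != seq[i]]


def _has_stop(seq: str) -> bool:
    return any(seq[i:i + 3] in STOPS for i in range(0, len(seq) - 2, 3))


@dataclass
class SimulatedRepertoire:
    """Amplicon sequences plus ground-truth table from one simulation run."""

    sequences: list            # list of (sequence_id, amplicon nt) pairs
    truth: pd.DataFrame        # one row per sequence, TRUTH_COLUMNS
    config: SimConfig

    def write_fasta(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.fasta_str())

    def fasta_str(self) -> str:
        buf = io.StringIO()
        for seq_id, seq in self.sequences:
            buf.write(f">{seq_id}\n")
            for i in range(0, len(seq), 60):
                buf.write(seq[i:i + 60] + "\n")
        return buf.getvalue()

    def write_truth(self, path) -> None:
        self.truth.to_csv(path, sep="\t", index=False)


def simulate_repertoire(config: SimConfig,
                        reference: GermlineReference) -> SimulatedRepertoire:
    """Simulate a full VH-Cgamma amplicon repertoire with ground truth.

    Clones draw V/D/J genes uniformly from the reference, junctions are made
    unique across clones by rejection sampling (re-drawing on collision,
    out-of-frame products, internal stops, or CDR3 lengths outside 5-13
    codons, which the gap-free 128-position numbering accommodates), and each
    clone grows a mutation lineage whose observed leaves become amplicons.
    Deterministic under ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    v_names = sorted(reference.v_genes)
    d_names = sorted(reference.d_genes)
    j_names = sorted(reference.j_genes)
    if not (v_names and d_names and j_names):
        raise ValueError("reference must contain V, D and J genes")
    prior = np.asarray(config.subclass_prior, dtype=float)

    sequences: list[tuple[str, str]] = []
    rows = []
    used_junctions: set[str] = set()
    for c in range(config.n_clones):
        clone_id = f"clone{c:04d}"
        for _attempt in range(1000):
            v = reference.v_genes[v_names[int(rng.integers(len(v_names)))]]
            d = reference.d_genes[d_names[int(rng.integers(len(d_names)))]]
            j = reference.j_genes[j_names[int(rng.integers(len(j_names)))]]
            trims = tuple(_draw_length(config.trim_law, rng) for _ in range(4))
            n1 = "".join(BASES[i] for i in
                         rng.integers(0, 4, size=_draw_length(
                             config.junction_n_len_law, rng)))
            n2 = "".join(BASES[i] for i in
                         rng.integers(0, 4, size=_draw_length(
                             config.junction_n_len_law, rng)))
            try:
                naive = recombine_vdj(v, d, j, trims, n1, n2)
            except ValueError:
                continue
            seq = naive.sequence
            if len(seq) % 3 != 0:
                pad = "".join(BASES[i] for i in
                              rng.integers(0, 4, size=3 - len(seq) % 3))
                naive = recombine_vdj(v, d, j, trims, n1, n2 + pad)
                seq = naive.sequence
            cdr3_codons = len(seq) // 3 - 115
            if not 5 <= cdr3_codons <= 13:
                continue
            if _has_stop(seq):
                continue
            if naive.junction_nt in used_junctions:
                continue
            break
        else:
            raise RuntimeError("failed to draw a unique viable junction")
        used_junctions.add(naive.junction_nt)
        root_subclass = SUBCLASSES[int(rng.choice(4, p=prior))]
        n_obs = _draw_length(config.clone_size_law, rng)
        nodes = mutate_lineage(naive.sequence, config, rng,
                               n_descendants=n_obs, subclass=root_subclass)
        for i, node in enumerate(nodes):
            seq_id = f"{clone_id}_{i:02d}"
            parent_id = ("germline" if node["parent"] < 0
                         else f"{clone_id}_{node['parent']:02d}")
            rows.append({"seq_id": seq_id, "clone_id": clone_id,
                         "parent_id": parent_id, "node": node,
                         "v": v.name, "d": d.name, "j": j.name,
                         "junction": naive.junction_nt,
                         "naive": naive.sequence})

    # optional planted recurrent non-silent mutation (for hotspot-map tests)
    planted = set()
    if config.planted_mutation is not None:
        codon, fraction = config.planted_mutation
        n_plant = int(round(fraction * len(rows)))
        planted = set(rng.choice(len(rows), size=n_plant, replace=False).tolist())

    for idx, row in enumerate(rows):
        node, naive = row["node"], row["naive"]
        seq = node["sequence"]
        if idx in planted:
            codon, _ = config.planted_mutation
            seq = _apply_nonsilent(seq, naive, codon)
            node = dict(node, sequence=seq,
                        events=node["events"] + [("planted", codon)])
        muts = _net_mutations(naive, seq, JUNCTION_START_NT)
        n_events = len([e for e in node["events"] if e[0] != "planted"])
        n_events = max(n_events, len(muts))
        c_call = {"IgG1": "IGHG1", "IgG2": "IGHG2",
                  "IgG3": "IGHG3", "IgG4": "IGHG4"}[node["subclass"]]
        rows[idx] = {
            "sequence_id": row["seq_id"], "clone_id": row["clone_id"],
            "parent_id": row["parent_id"], "v_call": row["v"],
            "d_call": row["d"], "j_call": row["j"], "c_call": c_call,
            "junction": row["junction"], "subclass": node["subclass"],
            "generation": node["generation"],
            "mutations": ";".join(f"{p}:{a}>{b}" for p, a, b in muts),
            "n_mutation_events": n_events,
            "_amplicon": attach_constant_fragment(seq, node["subclass"],
                                                  reference),
        }

    truth = pd.DataFrame([{k: r[k] for k in TRUTH_COLUMNS} for r in rows],
                         columns=TRUTH_COLUMNS)
    sequences = [(r["sequence_id"], r["_amplicon"]) for r in rows]
    return SimulatedRepertoire(sequences=sequences, truth=truth, config=config)


def _apply_nonsilent(seq: str, naive: str, codon: int) -> str:
    """Force a non-silent substitution at an IMGT codon (vs the naive codon)."""
    start = 3 * (codon - 1)
    from Bio.Seq import Seq
    ref_codon = naive[start:start + 3]
    ref_aa = str(Seq(ref_codon).translate())
    for offset in range(3):
        for base in BASES:
            if base == ref_codon[offset]:
                continue
            cand = ref_codon[:offset] + base + ref_codon[offset + 1:]
            if cand in STOPS:
                continue
            if str(Seq(cand).translate()) != ref_aa:
                return seq[:start] + cand + seq[start + 3:]
    raise RuntimeError(f"no non-silent substitution available at codon {codon}")


def simulate_binding_table(seq_ids: Sequence[str], target_positions: Sequence[int],
                           rng: np.random.Generator, target_rate: float = 0.6,
                           background_rate: float = 0.02,
                           positions: Sequence[int] = range(1, 105)) -> pd.DataFrame:
    """Fabricate a per-sequence per-position binding-prediction table.

    Positions in ``target_positions`` are flagged in each sequence with
    probability ``target_rate``; all other positions with
    ``background_rate``. Mirrors the shape of an upstream structural
    binding-residue prediction so concordance scoring is testable with a
    controllable overlap.
    """
    target = set(target_positions)
    rows = []
    for sid in seq_ids:
        for pos in positions:
            rate = target_rate if pos in target else background_rate
            rows.append({"sequence_id": sid, "imgt_position": int(pos),
                         "predicted_binding": bool(rng.random() < rate)})
    return pd.DataFrame(rows)
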