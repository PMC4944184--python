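"""Germline reference model: genes, IMGT unique numbering and the CDR/FWR partition.

Every downstream computation — mutation counting, selection testing, hotspot
mapping, lineage rooting — is defined relative to the germline model in this
module. The variable domain is numbered with fixed IMGT unique-numbering codon
positions 1-128 and partitioned into framework (FWR) and
complementarity-determining (CDR) regions:

    FR1 1-26, CDR1 27-38, FR2 39-55, CDR2 56-65, FR3 66-104,
    CDR3 105-117, FR4 118-128

Packaged germlines are gap-free under this numbering (no insertion codes), so
codon *k* of a V gene sits at IMGT position *k*. The shipped reference
(``data/synthetic_germline.fasta``) is a synthetic curated set — 2 genes per
VH family 1-5, 3 J genes, 5 D genes and the four IgG1-4 constant-region 5'
fragments — built to satisfy these conventions exactly.

Reference FASTA headers use the pipe-delimited grammar ``NAME|CLASS[|SUBCLASS]``
where CLASS is one of V/D/J/C and SUBCLASS (C genes only) is IgG1..IgG4.
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Optional

from Bio import SeqIO

__all__ = [
    "REGION_BOUNDARIES",
    "IMGT_POSITIONS",
    "CDR_REGIONS",
    "FWR_REGIONS",
    "GermlineGene",
    "GermlineReference",
    "ReferenceError",
    "region_of",
    "load_germline_reference",
    "default_reference",
]

#: Inclusive IMGT unique-numbering codon intervals for each region label.
REGION_BOUNDARIES: dict[str, tuple[int, int]] = {
    "FR1": (1, 26),
    "CDR1": (27, 38),
    "FR2": (39, 55),
    "CDR2": (56, 65),
    "FR3": (66, 104),
    "CDR3": (105, 117),
    "FR4": (118, 128),
}

IMGT_POSITIONS = 128
CDR_REGIONS = ("CDR1", "CDR2", "CDR3")
FWR_REGIONS = ("FR1", "FR2", "FR3", "FR4")

#: Last IMGT codon of the V segment proper analysed for germline divergence
#: (2nd-CYS anchor); CDR3 and FR4 codons have junctional/J origins.
V_ANALYSIS_END = 104

_VALID_NT = re.compile(r"^[ACGT]+$")
_VH_FAMILY = re.compile(r"^IGHV(\d+)")
_SUBCLASSES = ("IgG1", "IgG2", "IgG3", "IgG4")


class ReferenceError(ValueError):
    """Raised when the germline reference is unusable (empty or incomplete)."""


def region_of(position: int) -> str:
    """Return the region label (FR1..FR4, CDR1..CDR3) containing an IMGT codon position.

    Parameters
    ----------
    position
        1-based IMGT unique-numbering codon position, 1-128.
    """
    if not 1 <= position <= IMGT_POSITIONS:
        raise ValueError(
            f"IMGT position must be in 1..{IMGT_POSITIONS}, got {position}")
    for label, (lo, hi) in REGION_BOUNDARIES.items():
        if lo <= position <= hi:
            return label
    raise AssertionError("unreachable: boundary table covers 1..128")


@dataclass(frozen=True)
class GermlineGene:
    """A reference V, D, J or constant-region (C) gene segment.

    ``family`` is parsed from the name for V genes (integer after "IGHV");
    ``subclass_label`` identifies the IgG subclass for C genes.
    """

    name: str
    segment_class: str
    nt_sequence: str
    family: Optional[int] = None
    subclass_label: Optional[str] = None

    def __post_init__(self):
        if self.segment_class not in ("V", "D", "J", "C"):
            raise ValueError(
                f"{self.name}: segment_class must be V/D/J/C, got {self.segment_class!r}")
        if not self.nt_sequence or not _VALID_NT.match(self.nt_sequence):
            raise ValueError(
                f"{self.name}: nt_sequence must be non-empty over A/C/G/T")
        if self.segment_class == "V":
            if len(self.nt_sequence) % 3 != 0:
                raise ValueError(
                    f"{self.name}: V gene length {len(self.nt_sequence)} is not a "
                    "whole number of codons")
            m = _VH_FAMILY.match(self.name)
            if m is None:
                raise ValueError(f"{self.name}: cannot parse VH family from name")
            expected = int(m.group(1))
            if self.family is None:
                object.__setattr__(self, "family", expected)
            elif self.family != expected:
                raise ValueError(
                    f"{self.name}: family {self.family} contradicts name")
        if self.segment_class == "C":
            if self.subclass_label not in _SUBCLASSES:
                raise ValueError(
                    f"{self.name}: C gene requires subclass_label in {_SUBCLASSES}")

    @property
    def n_codons(self) -> int:
        return len(self.nt_sequence) // 3

    def codon(self, position: int) -> str:
        """Codon at 1-based position (IMGT position for gap-free V genes)."""
        if not 1 <= position <= self.n_codons:
            raise ValueError(f"{self.name}: no codon at position {position}")
        return self.nt_sequence[3 * (position - 1):3 * position]


@dataclass
class GermlineReference:
    """Container for a loaded germline gene set, indexed by segment class."""

    v_genes: dict[str, GermlineGene] = field(default_factory=dict)
    d_genes: dict[str, GermlineGene] = field(default_factory=dict)
    j_genes: dict[str, GermlineGene] = field(default_factory=dict)
    c_genes: dict[str, GermlineGene] = field(default_factory=dict)
    errors: list[str] = field(default_factory=list)

    def add(self, gene: GermlineGene) -> None:
        bucket = {"V": self.v_genes, "D": self.d_genes,
                  "J": self.j_genes, "C": self.c_genes}[gene.segment_class]
        bucket[gene.name] = gene

    def __len__(self) -> int:
        return (len(self.v_genes) + len(self.d_genes)
                + len(self.j_genes) + len(self.c_genes))

    def __iter__(self) -> Iterable[GermlineGene]:
        yield from self.v_genes.values()
        yield from self.d_genes.values()
        yield from self.j_genes.values()
        yield from self.c_genes.values()

    def get(self, name: str) -> GermlineGene:
        for bucket in (self.v_genes, self.d_genes, self.j_genes, self.c_genes):
            if name in bucket:
                return bucket[name]
        raise KeyError(name)

    def c_gene_for_subclass(self, subclass: str) -> GermlineGene:
        for gene in self.c_genes.values():
            if gene.subclass_label == subclass:
                return gene
        raise KeyError(f"no constant-region fragment for subclass {subclass!r}")

    @property
    def subclasses(self) -> list[str]:
        return sorted({g.subclass_label for g in self.c_genes.values()})

    def validate_complete(self) -> None:
        """The pipeline needs at least one V, one J and all four C-gamma fragments."""
        missing = []
        if not self.v_genes:
            missing.append("V genes")
        if not self.j_genes:
            missing.append("J genes")
        have = {g.subclass_label for g in self.c_genes.values()}
        for sub in _SUBCLASSES:
            if sub not in have:
                missing.append(f"C fragment for {sub}")
        if missing:
            raise ReferenceError(
                "incomplete germline reference, missing: " + ", ".join(missing))


def _parse_header(header: str) -> tuple[str, str, Optional[str]]:
    parts = header.split("|")
    if len(parts) == 2:
        name, cls = parts
        sub = None
    elif len(parts) == 3:
        name, cls, sub = parts
    else:
        raise ValueError(
            f"malformed reference header {header!r}: expected NAME|CLASS[|SUBCLASS]")
    if cls not in ("V", "D", "J", "C"):
        raise ValueError(
            f"malformed reference header {header!r}: class {cls!r} not in V/D/J/C")
    if cls == "C" and sub is None:
        raise ValueError(
            f"malformed reference header {header!r}: C gene requires a subclass field")
    return name, cls, sub


def load_germline_reference(path, require_complete: bool = True) -> GermlineReference:
    """Load a germline reference FASTA with ``NAME|CLASS[|SUBCLASS]`` headers.

    Unparseable records are skipped and reported in ``reference.errors``
    (one message per offending header); an empty file is fatal. When
    ``require_complete`` (default), the loaded set must contain at least one
    V, one J and all four IgG constant fragments.
    """
    reference = GermlineReference()
    n_records = 0
    for record in SeqIO.parse(str(path), "fasta"):
        n_records += 1
        header = record.id if "|" in record.id else record.description
        try:
            name, cls, sub = _parse_header(header)
            gene = GermlineGene(name=name, segment_class=cls,
                                nt_sequence=str(record.seq).upper(),
                                subclass_label=sub)
        except ValueError as exc:
            reference.errors.append(str(exc))
            continue
        reference.add(gene)
    if n_records == 0:
        raise ReferenceError(f"empty or unreadable reference FASTA: {path}")
    if require_complete:
        reference.validate_complete()
    return reference


def default_reference() -> GermlineReference:
    """Load the packaged synthetic curated germline reference."""
    ref_path = resources.files("igprofile.data") / "synthetic_germline.fasta"
    with resources.as_file(ref_path) as p:
        return load_germline_reference(p)
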