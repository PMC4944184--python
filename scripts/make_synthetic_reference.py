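"""One-off generator for the packaged synthetic germline reference.

Run from the repo root:  python scripts/make_synthetic_reference.py
Writes src/igprofile/data/synthetic_germline.fasta (frozen fixture; the
package never regenerates it at run time).

Layout mirrors a minimal human IGH locus slice:
  - 10 IGHV genes (2 per family VH1-5), 106 codons (318 nt), gap-free under
    IMGT unique numbering positions 1-106, with conserved 1st-CYS (codon 23,
    TGC), Trp-41 (TGG) and 2nd-CYS (codon 104, TGT); no in-frame stops.
  - 3 IGHJ genes, 16 codons (48 nt) covering IMGT positions 113-128 with the
    conserved Trp-118 (local codon 6, TGG).
  - 5 IGHD genes, 12-16 nt.
  - 4 IGHG constant-region 5' fragments, 270 nt (90 codons), ~5% diverged
    from a common ancestor so pairwise subclass identity is ~90%.
Within-family V genes are ~10% diverged; J genes ~15% diverged from a
common ancestor, emulating real within-family similarity.
"""
from __future__ import annotations

import numpy as np

STOPS = {"TAA", "TAG", "TGA"}
SENSE = [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"
         if a + b + c not in STOPS]
BASES = "ACGT"


def random_codons(rng: np.random.Generator, n: int) -> list[str]:
    return [SENSE[i] for i in rng.integers(0, len(SENSE), size=n)]


def mutate_fraction(rng, codons, frac, frozen_codons=()):
    """Mutate ~frac of nucleotides, never creating a stop or touching frozen codons."""
    codons = list(codons)
    n_nt = 3 * len(codons)
    n_mut = int(round(frac * n_nt))
    done = 0
    while done < n_mut:
        i = int(rng.integers(0, len(codons)))
        if i in frozen_codons:
            continue
        j = int(rng.integers(0, 3))
        old = codons[i]
        new_base = BASES[int(rng.integers(0, 4))]
        if new_base == old[j]:
            continue
        cand = old[:j] + new_base + old[j + 1:]
        if cand in STOPS:
            continue
        codons[i] = cand
        done += 1
    return codons


def main():
    rng = np.random.default_rng(20240917)
    records = []

    # V genes: anchors at codons 23, 41, 104 (1-based)
    v_names = {
        1: ["IGHV1-2", "IGHV1-46"],
        2: ["IGHV2-5", "IGHV2-70"],
        3: ["IGHV3-23", "IGHV3-7"],
        4: ["IGHV4-34", "IGHV4-59"],
        5: ["IGHV5-51", "IGHV5-10"],
    }
    anchors = {22: "TGC", 40: "TGG", 103: "TGT"}  # 0-based codon index
    for fam, names in v_names.items():
        ancestor = random_codons(rng, 106)
        for idx, base in anchors.items():
            ancestor[idx] = base
        for k, name in enumerate(names):
            codons = ancestor if k == 0 else mutate_fraction(
                rng, ancestor, 0.10, frozen_codons=set(anchors))
            records.append((f"{name}|V", "".join(codons)))

    # J genes: Trp-118 at local codon 6 (0-based index 5)
    j_anc = random_codons(rng, 16)
    j_anc[5] = "TGG"
    for k, name in enumerate(["IGHJ4", "IGHJ5", "IGHJ6"]):
        codons = j_anc if k == 0 else mutate_fraction(rng, j_anc, 0.15,
                                                      frozen_codons={5})
        records.append((f"{name}|J", "".join(codons)))

    # D genes
    for name, ln in [("IGHD1-26", 14), ("IGHD2-2", 16), ("IGHD3-10", 15),
                     ("IGHD4-17", 12), ("IGHD5-12", 13)]:
        seq = "".join(BASES[i] for i in rng.integers(0, 4, size=ln))
        records.append((f"{name}|D", seq))

    # C gamma fragments
    c_anc = random_codons(rng, 90)
    for name, sub in [("IGHG1", "IgG1"), ("IGHG2", "IgG2"),
                      ("IGHG3", "IgG3"), ("IGHG4", "IgG4")]:
        codons = mutate_fraction(rng, c_anc, 0.05)
        records.append((f"{name}|C|{sub}", "".join(codons)))

    with open("src/igprofile/data/synthetic_germline.fasta", "w") as fh:
        for header, seq in records:
            fh.write(f">{header}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i:i + 60] + "\n")
    print(f"wrote {len(records)} records")


if __name__ == "__main__":
    main()
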