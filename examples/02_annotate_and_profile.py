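"""Annotate amplicons and profile the cohort.

Runs germline assignment (V/D/J + subclass), junction/CDR3 extraction and
silent vs non-silent mutation counting, then summarises the cohort: subclass
distribution, VH family usage and the CDR3 length spectratype with its
normality test (a bimodal spectratype rejects the Gaussian hypothesis).
"""
from igprofile import (SimConfig, annotate_repertoire, build_cohort_profile,
                       dedupe_unique, default_reference, simulate_repertoire)

reference = default_reference()
rep = simulate_repertoire(SimConfig(n_clones=60, shm_rate=0.02, seed=7),
                          reference)
annotated, rejected = annotate_repertoire(rep.sequences, reference)
unique = dedupe_unique(annotated)
print(f"annotated {len(annotated)} sequences ({len(rejected)} rejected), "
      f"{len(unique)} unique")

rec = unique[0]
print(f"\nexample record {rec.seq_id}: {rec.v_call} "
      f"({rec.v_identity:.1%} germline identity), {rec.j_call}, "
      f"subclass {rec.subclass}, CDR3 {rec.cdr3_aa} ({rec.cdr3_length} aa)")
sil = sum(c["silent"] for c in rec.region_mutations.values())
non = sum(c["nonsilent"] for c in rec.region_mutations.values())
print(f"V-region mutations: {sil} silent + {non} non-silent "
      "(CDR3 excluded: junctional nt have no germline counterpart)")

profile = build_cohort_profile("example", unique)
print("\nsubclass distribution (fraction of assigned calls):")
for sub, p in sorted(profile.subclass["proportions"].items()):
    print(f"  {sub}: {p:.2f}")
print("VH family usage:", {k: round(v, 2)
                           for k, v in profile.vh_families["proportions"].items()})
if profile.cdr3_normality:
    k2, p = profile.cdr3_normality
    verdict = "rejected" if p < 0.05 else "not rejected"
    print(f"CDR3 length normality: K2={k2:.2f}, p={p:.3f} ({verdict})")
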