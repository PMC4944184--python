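"""Quantify selection pressure from mutation placement.

Each sequence's mutations are split between CDR (antigen-contacting) and FWR
(framework) and compared with the fraction expected if every analysable
V-region nucleotide were equally mutable; an exact binomial test scores the
departure. A CDR mutation fraction below expectation marks negative
(purifying) selection. Here the simulator rejects 80% of CDR mutations, so
the cohort should read out as strongly negatively selected in CDR.
"""
from igprofile import (SimConfig, annotate_repertoire, cohort_selection_summary,
                       default_reference, sequence_selection,
                       simulate_repertoire)

reference = default_reference()
cfg = SimConfig(n_clones=120, clone_size_law=("fixed", 1), shm_rate=0.04,
                hotspot_multiplier=1.0, cdr_rejection=0.8, switch_prob=0.0,
                seed=3)
rep = simulate_repertoire(cfg, reference)
annotated, _ = annotate_repertoire(rep.sequences, reference)

cdr_results = []
for rec in annotated:
    res = sequence_selection(rec, reference.v_genes[rec.v_call])
    cdr_results.append(res["CDR"])

summary = cohort_selection_summary(cdr_results, alpha=0.05)
print(f"informative sequences (>=1 V-region mutation): {summary['n']} "
      f"({summary['n_withheld']} withheld)")
print(f"fraction under negative selection in CDR: "
      f"{summary['negative_fraction']:.2f}")
print(f"  of which significant at p<0.05:        "
      f"{summary['negative_significant_fraction']:.2f}")
print("(simulator rejected 80% of CDR mutations, so most sequences place "
      "fewer CDR mutations than the ~21% null expectation)")
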