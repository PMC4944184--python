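"""File I/O: FASTA input, AIRR-style rearrangement tables, selection tables.

Tabular outputs follow AIRR-community rearrangement column naming where a
standard column exists (sequence_id, v_call, d_call, j_call, c_call,
junction, junction_aa, cdr3, cdr3_aa, productive, duplicate_count,
v_identity, j_identity); bespoke columns are namespaced with an ``igp_``
prefix (per-region mutation counts, serialized mutation events, VH family).
All tables are UTF-8, tab-delimited, header row, no quoting.
"""
from __future__ import annotations

from typing import Sequence

import pandas as pd
from Bio import SeqIO

from .annotate import AnnotatedSequence, MutationEvent
from .germline import region_of

__all__ = [
    "read_fasta",
    "write_tsv",
    "read_tsv",
    "to_airr_table",
    "records_from_airr",
    "selection_table",
]

_REGIONS = ("FR1", "CDR1", "FR2", "CDR2", "FR3")

AIRR_COLUMNS = [
    "sequence_id", "sequence", "productive", "v_call", "d_call", "j_call",
    "c_call", "v_identity", "j_identity", "junction", "junction_aa",
    "cdr3", "cdr3_aa", "duplicate_count",
]


def read_fasta(path) -> list[tuple[str, str]]:
    """Read a FASTA file into ``(sequence_id, sequence)`` pairs.

    Accepts wrapped or unwrapped records; duplicate sequence ids are fatal.
    """
    pairs = []
    seen = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in seen:
            seen[record.id] += 1
        else:
            seen[record.id] = 1
        pairs.append((record.id, str(record.seq).upper()))
    dupes = sorted(k for k, v in seen.items() if v > 1)
    if dupes:
        raise ValueError(f"duplicate sequence ids in {path}: {', '.join(dupes)}")
    return pairs


def write_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"sequence_id": str}, keep_default_na=False,
                       na_values=[""])


def _serialize_events(events: Sequence[MutationEvent]) -> str:
    return ";".join(
        f"{ev.nt_pos}:{ev.germline_base}>{ev.observed_base}:"
        f"{'S' if ev.silent else 'N'}" for ev in events)


def _parse_events(text) -> list[MutationEvent]:
    events = []
    if not isinstance(text, str) or not text:
        return events
    for token in text.split(";"):
        pos_part, change, flag = token.split(":")
        nt_pos = int(pos_part)
        germ, obs = change.split(">")
        codon = nt_pos // 3 + 1
        events.append(MutationEvent(nt_pos=nt_pos, imgt_codon=codon,
                                    region=region_of(codon),
                                    germline_base=germ, observed_base=obs,
                                    silent=(flag == "S")))
    return events


def to_airr_table(records: Sequence[AnnotatedSequence]) -> pd.DataFrame:
    """Serialize annotated records to an AIRR-style rearrangement table."""
    rows = []
    for r in records:
        row = {
            "sequence_id": r.seq_id,
            "sequence": r.sequence,
            "productive": "T" if r.productive else "F",
            "v_call": r.v_call,
            "d_call": r.d_call or "",
            "j_call": r.j_call or "",
            "c_call": {"IgG1": "IGHG1", "IgG2": "IGHG2", "IgG3": "IGHG3",
                       "IgG4": "IGHG4"}.get(r.subclass, ""),
            "v_identity": round(r.v_identity, 6),
            "j_identity": round(r.j_identity, 6),
            "junction": r.junction_nt or "",
            "junction_aa": r.junction_aa or "",
            "cdr3": r.cdr3_nt or "",
            "cdr3_aa": r.cdr3_aa or "",
            "duplicate_count": r.duplicate_count,
            "igp_subclass": r.subclass or "unassigned",
            "igp_c_identity": round(r.c_identity, 6),
            "igp_vh_family": r.vh_family,
            "igp_cdr3_length": "" if r.cdr3_length is None else r.cdr3_length,
            "igp_uncallable": r.uncallable,
            "igp_vh_end": "" if r.vh_end is None else r.vh_end,
            "igp_mutation_events": _serialize_events(r.mutation_events),
        }
        for region in _REGIONS:
            counts = r.region_mutations.get(region, {"silent": 0, "nonsilent": 0})
            row[f"igp_silent_{region.lower()}"] = counts["silent"]
            row[f"igp_nonsilent_{region.lower()}"] = counts["nonsilent"]
        rows.append(row)
    return pd.DataFrame(rows)


def records_from_airr(df: pd.DataFrame) -> list[AnnotatedSequence]:
    """Rebuild annotated records from a rearrangement table written by this package."""
    records = []
    for _, row in df.iterrows():
        events = _parse_events(row.get("igp_mutation_events", ""))
        region_mutations = {}
        for region in _REGIONS:
            region_mutations[region] = {
                "silent": int(row.get(f"igp_silent_{region.lower()}", 0)),
                "nonsilent": int(row.get(f"igp_nonsilent_{region.lower()}", 0)),
            }
        subclass = row.get("igp_subclass", "unassigned")
        cdr3_len = row.get("igp_cdr3_length", "")
        records.append(AnnotatedSequence(
            seq_id=str(row["sequence_id"]),
            sequence=row.get("sequence", ""),
            v_call=row["v_call"],
            v_identity=float(row.get("v_identity", 0.0)),
            j_call=row.get("j_call") or None,
            j_identity=float(row.get("j_identity", 0.0)),
            d_call=row.get("d_call") or None,
            vh_family=int(row.get("igp_vh_family", 0)),
            junction_nt=row.get("junction") or None,
            junction_aa=row.get("junction_aa") or None,
            cdr3_nt=row.get("cdr3") or None,
            cdr3_aa=row.get("cdr3_aa") or None,
            cdr3_length=int(cdr3_len) if str(cdr3_len) not in ("", "nan") else None,
            productive=str(row.get("productive", "T")) == "T",
            subclass=None if subclass == "unassigned" else subclass,
            c_identity=float(row.get("igp_c_identity", 0.0)),
            subclass_reason=None,
            region_mutations=region_mutations,
            mutation_events=events,
            uncallable=int(row.get("igp_uncallable", 0)),
            duplicate_count=int(row.get("duplicate_count", 1)),
            vh_end=(int(row["igp_vh_end"])
                    if str(row.get("igp_vh_end", "")) not in ("", "nan")
                    else None),
        ))
    return records


def selection_table(results_by_seq: dict) -> pd.DataFrame:
    """Serialize per-sequence selection results (CDR and FWR) to a table.

    ``results_by_seq`` maps seq_id -> {"CDR": SelectionResult|None, "FWR": ...}.
    Withheld results (no mutations) are emitted with empty statistics and
    reason "no mutations".
    """
    rows = []
    for seq_id, by_class in results_by_seq.items():
        for region_class in ("CDR", "FWR"):
            res = by_class.get(region_class)
            if res is None:
                rows.append({"sequence_id": seq_id,
                             "region_class": region_class,
                             "observed": "", "total": "",
                             "expected_fraction": "", "direction": "withheld",
                             "p_value": "", "reason": "no mutations"})
            else:
                rows.append({"sequence_id": seq_id,
                             "region_class": region_class,
                             "observed": res.observed, "total": res.total,
                             "expected_fraction": round(res.expected_fraction, 6),
                             "direction": res.direction,
                             "p_value": f"{res.p_value:.6g}", "reason": ""})
    return pd.DataFrame(rows)
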