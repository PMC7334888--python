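"""AIRR Rearrangement TSV and FASTA output.

The native on-disk format is a fixed-order AIRR Rearrangement TSV (UTF-8, LF
line endings). Standard columns use AIRR names; package-specific annotation
(trims, mutation counts, the full event trace) lives in ``vdjsim_``-prefixed
extension columns so the file stays consumable by generic AIRR tooling. The
event trace is serialized as compact JSON in ``vdjsim_event_json`` which makes
a written repertoire fully replayable after reading it back.
"""

from __future__ import annotations

import json

import pandas as pd

from .engine import RecombinationEvent, Repertoire, SequenceRecord

#: mandatory on read; fixed emission order on write (standard, then extensions)
STANDARD_COLUMNS = (
    "sequence_id", "sequence", "sequence_aa", "productive",
    "v_call", "d_call", "j_call", "junction", "junction_aa",
    "np1", "np2", "duplicate_count", "cell_id",
)
EXTENSION_COLUMNS = (
    "vdjsim_chain", "vdjsim_species",
    "vdjsim_v_trim_3p", "vdjsim_d_trim_5p", "vdjsim_d_trim_3p",
    "vdjsim_j_trim_5p", "vdjsim_shm_count", "vdjsim_modified",
    "vdjsim_event_json",
)
ALL_COLUMNS = STANDARD_COLUMNS + EXTENSION_COLUMNS

_MANDATORY_ON_READ = tuple(c for c in STANDARD_COLUMNS if c != "cell_id")


class AirrIOError(ValueError):
    """Malformed or incomplete AIRR TSV."""


def _event_to_json(ev: RecombinationEvent) -> str:
    payload = {
        "v_id": ev.v_id, "d_id": ev.d_id, "j_id": ev.j_id,
        "v_trim_3p": ev.v_trim_3p, "d_trim_5p": ev.d_trim_5p,
        "d_trim_3p": ev.d_trim_3p, "j_trim_5p": ev.j_trim_5p,
        "n1_seq": ev.n1_seq, "n2_seq": ev.n2_seq,
        "fragment_boundaries": [list(b) for b in ev.fragment_boundaries],
        "v_anchor_pos": ev.v_anchor_pos, "j_anchor_pos": ev.j_anchor_pos,
        "shm_edits": [list(e) for e in ev.shm_edits],
        "modification_edits": [list(e) for e in ev.modification_edits],
        "attempt_index": ev.attempt_index,
    }
    return json.dumps(payload, sort_keys=True, separators=(",", ":"))


def _event_from_json(blob: str) -> RecombinationEvent:
    d = json.loads(blob)
    return RecombinationEvent(
        v_id=d["v_id"], d_id=d["d_id"], j_id=d["j_id"],
        v_trim_3p=d["v_trim_3p"], d_trim_5p=d["d_trim_5p"],
        d_trim_3p=d["d_trim_3p"], j_trim_5p=d["j_trim_5p"],
        n1_seq=d["n1_seq"], n2_seq=d["n2_seq"],
        fragment_boundaries=tuple(tuple(b) for b in d["fragment_boundaries"]),
        v_anchor_pos=d["v_anchor_pos"], j_anchor_pos=d["j_anchor_pos"],
        shm_edits=[tuple(e) for e in d["shm_edits"]],
        modification_edits=[tuple(e) for e in d["modification_edits"]],
        attempt_index=d["attempt_index"])


def write_airr_tsv(repertoire: Repertoire, path) -> None:
    """Write the repertoire as an AIRR Rearrangement TSV (order-preserving,
    byte-deterministic for identical repertoires)."""
    species = str(repertoire.metadata.get("species", ""))
    with open(path, "w", newline="\n", encoding="utf-8") as fh:
        fh.write("\t".join(ALL_COLUMNS) + "\n")
        for rec in repertoire:
            ev = rec.event
            row = [
                rec.sequence_id, rec.sequence_nt, rec.sequence_aa, "T",
                rec.v_call, rec.d_call or "", rec.j_call,
                rec.junction_nt, rec.junction_aa,
                ev.n1_seq if ev else "",
                (ev.n2_seq or "") if ev else "",
                str(rec.duplicate_count), rec.cell_id or "",
                rec.chain, species,
                str(ev.v_trim_3p) if ev else "",
                str(ev.d_trim_5p) if ev and ev.d_trim_5p is not None else "",
                str(ev.d_trim_3p) if ev and ev.d_trim_3p is not None else "",
                str(ev.j_trim_5p) if ev else "",
                str(len(ev.shm_edits)) if ev else "",
                "T" if ev and ev.modification_edits else "F",
                _event_to_json(ev) if ev else "",
            ]
            fh.write("\t".join(row) + "\n")


def read_airr_tsv(path) -> Repertoire:
    """Read an AIRR TSV written by this package (or any file with the
    mandatory standard columns); event traces are reconstructed when the
    ``vdjsim_event_json`` extension column is present."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in _MANDATORY_ON_READ:
        if col not in df.columns:
            raise AirrIOError(f"missing mandatory column: {col}")
    has_event = "vdjsim_event_json" in df.columns
    records: list[SequenceRecord] = []
    for row in df.itertuples(index=False):
        event = None
        if has_event and row.vdjsim_event_json:
            event = _event_from_json(row.vdjsim_event_json)
        records.append(SequenceRecord(
            sequence_id=row.sequence_id,
            sequence_nt=row.sequence,
            sequence_aa=row.sequence_aa,
            junction_nt=row.junction,
            junction_aa=row.junction_aa,
            v_call=row.v_call,
            d_call=row.d_call or None,
            j_call=row.j_call,
            chain=getattr(row, "vdjsim_chain", "") or "",
            duplicate_count=int(row.duplicate_count),
            event=event,
            cell_id=(getattr(row, "cell_id", "") or None),
        ))
    metadata = {}
    if "vdjsim_species" in df.columns and len(df):
        metadata["species"] = df["vdjsim_species"].iloc[0]
    if "vdjsim_chain" in df.columns and len(df):
        chains = set(df["vdjsim_chain"])
        metadata["chain"] = chains.pop() if len(chains) == 1 else "+".join(
            sorted(chains))
    return Repertoire(records=records, metadata=metadata)


def write_fasta(repertoire: Repertoire, path, level: str = "nt") -> None:
    """FASTA export; ``level`` selects nt, aa, or junction_aa sequences.
    Headers carry the sequence id and a duplicate_count tag."""
    attr = {"nt": "sequence_nt", "aa": "sequence_aa",
            "junction_aa": "junction_aa"}.get(level)
    if attr is None:
        raise AirrIOError(f"unknown FASTA level {level!r}")
    with open(path, "w", newline="\n", encoding="utf-8") as fh:
        for rec in repertoire:
            fh.write(f">{rec.sequence_id}|duplicate_count="
                     f"{rec.duplicate_count}\n{getattr(rec, attr)}\n")


def write_table(rows: list[dict], path) -> None:
    """Small helper for modification/removal logs: TSV with LF endings."""
    if not rows:
        with open(path, "w", newline="\n", encoding="utf-8") as fh:
            fh.write("\n")
        return
    cols = list(rows[0])
    with open(path, "w", newline="\n", encoding="utf-8") as fh:
        fh.write("\t".join(cols) + "\n")
        for row in rows:
            fh.write("\t".join(str(row[c]) for c in cols) + "\n")
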