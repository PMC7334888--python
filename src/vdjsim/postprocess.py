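"""Post-simulation sequence modifications.

Three families of benchmark-oriented edits, all of which keep the event trace
replayable by appending per-base ``modification_edits`` to each record's
event:

* motif implantation — length-preserving replacement of an amino-acid window
  inside the CDR3 (strictly between the two anchors) by a chosen k-mer, at a
  controlled per-record frequency;
* synonymous codon replacement — nucleotide-level perturbation that leaves
  the amino-acid sequence untouched;
* similarity-architecture modification — pruning of high-degree nodes of the
  equal-length Hamming similarity graph over junctions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._seq import AA20, AA_TO_CODONS, CODON_TO_AA, translate
from .engine import Repertoire, SequenceRecord

POSITION_RULES = ("fixed", "random_interior")


class PostprocessError(ValueError):
    """Invalid modification request."""


@dataclass
class MotifSpec:
    """What to implant, how often, and where.

    ``motifs`` maps amino-acid k-mers to sampling weights. With the ``fixed``
    rule the motif starts ``fixed_offset`` residues after the junction's
    anchor cysteine (offset >= 1 keeps the anchor intact); ``random_interior``
    draws a uniform admissible start strictly inside the junction.
    """

    motifs: dict[str, float]
    frequency: float
    position_rule: str = "fixed"
    fixed_offset: int | None = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.motifs:
            raise PostprocessError("at least one motif required")
        for m in self.motifs:
            if not m or set(m) - set(AA20):
                raise PostprocessError(f"motif {m!r} not over the 20-aa alphabet")
        if any(w < 0 for w in self.motifs.values()) or \
                sum(self.motifs.values()) <= 0:
            raise PostprocessError("motif weights must be >= 0, positive sum")
        if not 0.0 <= self.frequency <= 1.0:
            raise PostprocessError("frequency must lie in [0, 1]")
        if self.position_rule not in POSITION_RULES:
            raise PostprocessError(f"unknown position rule {self.position_rule!r}")
        if self.position_rule == "fixed":
            if self.fixed_offset is None or self.fixed_offset < 1:
                raise PostprocessError("fixed_offset must be >= 1")


def _replace_codons(rec: SequenceRecord, nt_start: int, new_aa: str,
                    rng: np.random.Generator) -> None:
    """Rewrite ``len(new_aa)`` codons starting at ``nt_start`` (codon-aligned),
    choosing uniformly among each residue's synonymous codons, and record the
    per-base diffs on the event."""
    chars = list(rec.sequence_nt)
    edits = rec.event.modification_edits if rec.event is not None else []
    for i, aa in enumerate(new_aa):
        codons = AA_TO_CODONS[aa]
        codon = codons[rng.integers(len(codons))]
        for k, base in enumerate(codon):
            pos = nt_start + 3 * i + k
            if chars[pos] != base:
                edits.append((pos, chars[pos], base))
                chars[pos] = base
    rec.sequence_nt = "".join(chars)
    rec.sequence_aa = translate(rec.sequence_nt)
    if rec.event is not None:
        ev = rec.event
        rec.junction_nt = rec.sequence_nt[ev.v_anchor_pos:ev.j_anchor_pos + 3]
        rec.junction_aa = translate(rec.junction_nt)


def implant_motifs(repertoire: Repertoire, spec: MotifSpec
                   ) -> tuple[Repertoire, list[dict]]:
    """Implant motifs into a Bernoulli(frequency) subset of records, in place.

    Replacement (not insertion) keeps junction lengths and reading frame
    intact. Records whose junction interior cannot host the chosen motif are
    skipped and logged; it is an error if no junction in the repertoire could
    host even the shortest motif.
    """
    if len(repertoire) == 0:
        raise PostprocessError("empty repertoire")
    interiors = [len(rec.junction_aa) - 2 for rec in repertoire]
    if max(interiors) < min(len(m) for m in spec.motifs):
        raise PostprocessError("every motif is longer than every junction interior")
    rng = np.random.default_rng(spec.seed)
    names = list(spec.motifs)
    weights = np.asarray([spec.motifs[m] for m in names], dtype=float)
    weights /= weights.sum()
    log: list[dict] = []
    for rec in repertoire.records:
        entry = {"sequence_id": rec.sequence_id, "implanted": False,
                 "motif": "", "position": -1, "reason": ""}
        log.append(entry)
        if rng.random() >= spec.frequency:
            entry["reason"] = "not selected"
            continue
        motif = names[rng.choice(len(names), p=weights)]
        L = len(rec.junction_aa)
        if spec.position_rule == "fixed":
            pos = spec.fixed_offset
            if pos + len(motif) > L - 1:
                entry["reason"] = "junction too short"
                continue
        else:
            hi = L - 1 - len(motif)  # inclusive upper bound on start
            if hi < 1:
                entry["reason"] = "junction too short"
                continue
            pos = int(rng.integers(1, hi + 1))
        if rec.event is None:
            raise PostprocessError(
                f"{rec.sequence_id}: motif implantation requires an event "
                "trace to locate the junction")
        nt_start = rec.event.v_anchor_pos + 3 * pos
        _replace_codons(rec, nt_start, motif, rng)
        entry.update(implanted=True, motif=motif, position=pos)
    return repertoire, log


def synonymous_codon_replacement(repertoire: Repertoire,
                                 replacement_prob: float,
                                 rng: np.random.Generator) -> Repertoire:
    """Replace each codon, independently with ``replacement_prob``, by a
    uniform draw from its synonymous alternatives (no-op for Met/Trp).

    The amino-acid sequence and junction boundaries are strictly unchanged.
    """
    if not 0.0 <= replacement_prob <= 1.0:
        raise PostprocessError("replacement_prob must lie in [0, 1]")
    if replacement_prob == 0.0:
        return repertoire
    for rec in repertoire.records:
        chars = list(rec.sequence_nt)
        edits = rec.event.modification_edits if rec.event is not None else []
        n_codons = len(chars) // 3
        hits = np.flatnonzero(rng.random(n_codons) < replacement_prob)
        for ci in hits:
            start = 3 * int(ci)
            codon = "".join(chars[start:start + 3])
            alternatives = [c for c in AA_TO_CODONS[CODON_TO_AA[codon]]
                            if c != codon]
            if not alternatives:
                continue
            new = alternatives[rng.integers(len(alternatives))]
            for k in range(3):
                if chars[start + k] != new[k]:
                    edits.append((start + k, chars[start + k], new[k]))
                    chars[start + k] = new[k]
        rec.sequence_nt = "".join(chars)
        if rec.event is not None:
            ev = rec.event
            rec.junction_nt = rec.sequence_nt[ev.v_anchor_pos:
                                              ev.j_anchor_pos + 3]
    return repertoire


# ---------------------------------------------------------------------------
# similarity architecture
# ---------------------------------------------------------------------------

def _degrees(seqs: list[str], max_hamming: int) -> np.ndarray:
    """Degree of each sequence in the equal-length Hamming-<=m graph."""
    degrees = np.zeros(len(seqs), dtype=int)
    by_len: dict[int, list[int]] = {}
    for i, s in enumerate(seqs):
        by_len.setdefault(len(s), []).append(i)
    for length, idx in by_len.items():
        if len(idx) < 2 or length == 0:
            continue
        mat = np.array([np.frombuffer(seqs[i].encode("ascii"), dtype=np.uint8)
                        for i in idx])
        for lo in range(0, len(idx), 256):  # chunk rows to bound memory
            chunk = mat[lo:lo + 256]
            dist = (chunk[:, None, :] != mat[None, :, :]).sum(axis=2)
            close = (dist <= max_hamming).sum(axis=1) - 1  # exclude self
            degrees[np.asarray(idx)[lo:lo + len(chunk)]] = close
    return degrees


def similarity_degree_profile(repertoire: Repertoire, max_hamming: int = 1,
                              level: str = "junction_aa") -> np.ndarray:
    """Per-record degree: number of other records whose equal-length junction
    lies within Hamming distance ``max_hamming`` (no edges across lengths;
    identical junctions are at distance 0 and therefore adjacent)."""
    if len(repertoire) == 0:
        raise PostprocessError("empty repertoire")
    if max_hamming < 1:
        raise PostprocessError("max_hamming must be >= 1")
    if level not in ("junction_aa", "junction_nt"):
        raise PostprocessError(f"unknown level {level!r}")
    seqs = [getattr(rec, level) for rec in repertoire]
    return _degrees(seqs, max_hamming)


def modify_similarity_architecture(repertoire: Repertoire, mode: str,
                                   threshold: int, max_hamming: int = 1,
                                   level: str = "junction_aa"
                                   ) -> tuple[Repertoire, list[tuple[str, int]]]:
    """Remove high-degree records from the similarity graph.

    ``prune_hubs`` iteratively removes the highest-degree record (ties broken
    by lowest index) and recomputes degrees until the maximum degree is at
    most ``threshold``; ``cap_degree`` removes, in one pass, every record
    whose initial degree exceeds it. Returns the modified repertoire and a
    removal log of ``(sequence_id, degree_at_removal)``.
    """
    if mode not in ("prune_hubs", "cap_degree"):
        raise PostprocessError(f"unknown mode {mode!r}")
    if threshold < 0:
        raise PostprocessError("threshold must be >= 0")
    records = list(repertoire.records)
    seqs = [getattr(rec, level) for rec in records]
    removal_log: list[tuple[str, int]] = []
    if mode == "cap_degree":
        deg = _degrees(seqs, max_hamming)
        keep = [i for i in range(len(records)) if deg[i] <= threshold]
        removal_log = [(records[i].sequence_id, int(deg[i]))
                       for i in range(len(records)) if deg[i] > threshold]
        records = [records[i] for i in keep]
    else:
        while records:
            deg = _degrees(seqs, max_hamming)
            worst = int(np.argmax(deg))  # argmax takes the lowest index on ties
            if deg[worst] <= threshold:
                break
            removal_log.append((records[worst].sequence_id, int(deg[worst])))
            del records[worst]
            del seqs[worst]
    if not records:
        raise PostprocessError(
            "threshold would empty the repertoire (last surviving subset "
            f"size {len(records)})")
    out = Repertoire(records=records, metadata=dict(repertoire.metadata),
                     germline_set=repertoire.germline_set)
    out.metadata["architecture_removed"] = len(removal_log)
    return out, removal_log
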