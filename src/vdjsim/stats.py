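"""Repertoire summary statistics and native-likeness comparison metrics.

The metric bundle used to validate that simulated repertoires reproduce
their input distributions (or match another repertoire): Spearman rank
correlation of germline gene usage, Jensen–Shannon divergence (base 2) of
CDR3 length distributions, mean squared difference of positional amino-acid
frequencies, Spearman correlation of gapped-k-mer occurrence profiles, and
an internal ground-truth annotation-consistency check that replays each
record's event trace.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import jensenshannon
from scipy.stats import spearmanr

from ._seq import AA20
from .engine import Repertoire, SequenceRecord
from .germline import FrequencyTable, GermlineSet


class StatsError(ValueError):
    """Degenerate input for a comparison metric."""


@dataclass
class ComparisonReport:
    """Metric bundle from :func:`compare_repertoires`."""

    gene_usage_rho: dict[str, float]
    cdr3_length_divergence: float  # Jensen-Shannon divergence, bits
    positional_aa_mmse: float
    gapped_kmer_rho: float
    k: int
    m_max: int
    n_a: int
    n_b: int
    skipped_positions: list[int] = field(default_factory=list)

    def to_text(self) -> str:
        lines = []
        for cls, rho in sorted(self.gene_usage_rho.items()):
            lines.append(f"gene_usage_rho_{cls}={rho:.6f}")
        lines.append(f"cdr3_length_divergence_bits="
                     f"{self.cdr3_length_divergence:.6f}")
        lines.append(f"positional_aa_mmse={self.positional_aa_mmse:.6g}")
        lines.append(f"gapped_kmer_rho={self.gapped_kmer_rho:.6f}")
        lines.append(f"k={self.k}")
        lines.append(f"m_max={self.m_max}")
        lines.append(f"n_a={self.n_a}")
        lines.append(f"n_b={self.n_b}")
        return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# gene usage
# ---------------------------------------------------------------------------

def realized_gene_frequencies(repertoire: Repertoire,
                              segment_class: str) -> dict[str, float]:
    """Empirical call frequencies of one segment class (unweighted records)."""
    attr = {"V": "v_call", "D": "d_call", "J": "j_call"}[segment_class]
    counts = Counter(getattr(rec, attr) for rec in repertoire
                     if getattr(rec, attr))
    total = sum(counts.values())
    if total == 0:
        return {}
    return {gid: c / total for gid, c in counts.items()}


def gene_usage_spearman(repertoire: Repertoire, table: FrequencyTable) -> float:
    """Spearman rho between input probabilities and realized call frequencies,
    over the union of gene ids (absent genes count 0; average-rank ties)."""
    realized = realized_gene_frequencies(repertoire, table.segment_class)
    nonzero = sum(1 for p in table.probabilities if p > 0)
    if nonzero < 3:
        raise StatsError("rank correlation needs >= 3 genes with nonzero mass")
    ids = sorted(set(table.gene_ids) | set(realized))
    a = np.array([table.entries.get(g, 0.0) for g in ids])
    b = np.array([realized.get(g, 0.0) for g in ids])
    return float(spearmanr(a, b).statistic)


def _frequency_spearman(freq_a: dict[str, float],
                        freq_b: dict[str, float]) -> float:
    ids = sorted(set(freq_a) | set(freq_b))
    if len(ids) < 3:
        raise StatsError("rank correlation needs >= 3 categories")
    a = np.array([freq_a.get(g, 0.0) for g in ids])
    b = np.array([freq_b.get(g, 0.0) for g in ids])
    return float(spearmanr(a, b).statistic)


# ---------------------------------------------------------------------------
# positional amino-acid frequencies
# ---------------------------------------------------------------------------

def _positional_freqs(repertoire: Repertoire, n_positions: int) -> np.ndarray:
    """(n_positions, 20) frequency matrix over junction_aa; rows with zero
    coverage are NaN."""
    aa_index = {aa: i for i, aa in enumerate(AA20)}
    out = np.full((n_positions, len(AA20)), np.nan)
    for pos in range(n_positions):
        counts = np.zeros(len(AA20))
        for rec in repertoire:
            if len(rec.junction_aa) > pos:
                counts[aa_index[rec.junction_aa[pos]]] += 1
        if counts.sum() > 0:
            out[pos] = counts / counts.sum()
    return out


def positional_aa_mmse(rep_a: Repertoire, rep_b: Repertoire,
                       n_positions: int = 10) -> float:
    """Mean (over junction positions 1..n and 20 amino acids) squared
    difference of positional amino-acid frequencies.

    Positions uncovered in either repertoire are skipped with a warning;
    an error is raised if every position is skipped.
    """
    if len(rep_a) == 0 or len(rep_b) == 0:
        raise StatsError("both repertoires must be non-empty")
    if n_positions < 1:
        raise StatsError("n_positions must be >= 1")
    fa = _positional_freqs(rep_a, n_positions)
    fb = _positional_freqs(rep_b, n_positions)
    valid = ~(np.isnan(fa[:, 0]) | np.isnan(fb[:, 0]))
    skipped = [int(i) for i in np.flatnonzero(~valid)]
    if skipped:
        warnings.warn(f"positions with zero coverage skipped: {skipped}",
                      stacklevel=2)
    if not valid.any():
        raise StatsError("no junction position covered in both repertoires")
    return float(((fa[valid] - fb[valid]) ** 2).mean())


# ---------------------------------------------------------------------------
# gapped k-mers
# ---------------------------------------------------------------------------

def gapped_kmer_profile(repertoire: Repertoire, k: int = 3,
                        m_max: int = 3) -> Counter:
    """Occurrence counts of contiguous and single-gap k-mer patterns.

    A pattern is a length-k amino-acid subsequence of a junction with at most
    one internal gap block of length g (0 <= g <= m_max). Gapped keys encode
    the gap as ``left.g.right`` (e.g. ``CA.2.RF``); g=0 gives plain k-mers.
    Counts are summed over all records and start positions.
    """
    if k < 2:
        raise StatsError("k must be >= 2")
    if m_max < 0:
        raise StatsError("m_max must be >= 0")
    profile: Counter = Counter()
    for rec in repertoire:
        s = rec.junction_aa
        L = len(s)
        for start in range(L - k + 1):
            profile[s[start:start + k]] += 1
        for g in range(1, m_max + 1):
            span = k + g
            for start in range(L - span + 1):
                for split in range(1, k):
                    left = s[start:start + split]
                    right = s[start + split + g:start + span]
                    profile[f"{left}.{g}.{right}"] += 1
    if not profile:
        warnings.warn("k exceeds every junction length; empty profile",
                      stacklevel=2)
    return profile


def gapped_kmer_spearman(profile_a: Counter, profile_b: Counter) -> float:
    keys = sorted(set(profile_a) | set(profile_b))
    if len(keys) < 3:
        raise StatsError("rank correlation needs >= 3 patterns")
    a = np.array([profile_a.get(p, 0) for p in keys], dtype=float)
    b = np.array([profile_b.get(p, 0) for p in keys], dtype=float)
    return float(spearmanr(a, b).statistic)


# ---------------------------------------------------------------------------
# length distributions and the full report
# ---------------------------------------------------------------------------

def cdr3_length_jsd(rep_a: Repertoire, rep_b: Repertoire) -> float:
    """Jensen-Shannon divergence (bits) of junction_aa length distributions."""
    la = Counter(len(rec.junction_aa) for rec in rep_a)
    lb = Counter(len(rec.junction_aa) for rec in rep_b)
    support = sorted(set(la) | set(lb))
    pa = np.array([la.get(x, 0) for x in support], dtype=float)
    pb = np.array([lb.get(x, 0) for x in support], dtype=float)
    if len(support) == 1:
        return 0.0
    return float(jensenshannon(pa, pb, base=2) ** 2)


def compare_repertoires(rep_a: Repertoire, rep_b: Repertoire, k: int = 3,
                        m_max: int = 3,
                        n_positions: int = 10) -> ComparisonReport:
    """Assemble the full native-likeness comparison of two repertoires."""
    if len(rep_a) == 0 or len(rep_b) == 0:
        raise StatsError("both repertoires must be non-empty")
    gene_rho: dict[str, float] = {}
    for cls in ("V", "D", "J"):
        fa = realized_gene_frequencies(rep_a, cls)
        fb = realized_gene_frequencies(rep_b, cls)
        if fa and fb:
            gene_rho[cls] = _frequency_spearman(fa, fb)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        mmse = positional_aa_mmse(rep_a, rep_b, n_positions)
    rho_kmer = gapped_kmer_spearman(gapped_kmer_profile(rep_a, k, m_max),
                                    gapped_kmer_profile(rep_b, k, m_max))
    return ComparisonReport(
        gene_usage_rho=gene_rho,
        cdr3_length_divergence=cdr3_length_jsd(rep_a, rep_b),
        positional_aa_mmse=mmse,
        gapped_kmer_rho=rho_kmer,
        k=k, m_max=m_max, n_a=len(rep_a), n_b=len(rep_b))


# ---------------------------------------------------------------------------
# annotation ground truth
# ---------------------------------------------------------------------------

def replay_record(record: SequenceRecord,
                  germline_set: GermlineSet) -> str:
    """Rebuild the sequence from its event trace: germline fragments, trims,
    insertions, then SHM and modification edits, in order."""
    ev = record.event
    if ev is None:
        raise StatsError(f"{record.sequence_id}: no event trace")
    v = germline_set.gene(ev.v_id)
    j = germline_set.gene(ev.j_id)
    v_part = v.sequence_nt[:len(v) - ev.v_trim_3p]
    j_part = j.sequence_nt[ev.j_trim_5p:]
    if ev.d_id is not None:
        d = germline_set.gene(ev.d_id)
        d_part = d.sequence_nt[ev.d_trim_5p:len(d) - ev.d_trim_3p]
        chars = list(v_part + ev.n1_seq + d_part + (ev.n2_seq or "") + j_part)
    else:
        chars = list(v_part + ev.n1_seq + j_part)
    for pos, old, new in list(ev.shm_edits) + list(ev.modification_edits):
        if chars[pos] != old:
            raise StatsError(
                f"{record.sequence_id}: edit at {pos} expected {old!r}, "
                f"found {chars[pos]!r}")
        chars[pos] = new
    return "".join(chars)


def annotation_consistency(repertoire: Repertoire,
                           germline_set: GermlineSet | None = None
                           ) -> tuple[float, list[tuple[str, str]]]:
    """Fraction of records whose replayed event trace reproduces
    ``sequence_nt`` exactly, plus the offender list ``(id, reason)``."""
    if len(repertoire) == 0:
        return 1.0, []
    offenders: list[tuple[str, str]] = []
    for rec in repertoire:
        gs = germline_set or repertoire.germline_for(rec)
        if gs is None:
            offenders.append((rec.sequence_id, "no germline set available"))
            continue
        try:
            rebuilt = replay_record(rec, gs)
        except Exception as exc:
            offenders.append((rec.sequence_id, str(exc)))
            continue
        if rebuilt != rec.sequence_nt:
            offenders.append((rec.sequence_id, "replayed sequence differs"))
    fraction = 1.0 - len(offenders) / len(repertoire)
    return fraction, offenders
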