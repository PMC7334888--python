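"""Clonal abundance assignment and somatic hypermutation.

Abundance models set ``duplicate_count`` per record (one row per clone, the
AIRR Rearrangement convention); the power-law model draws from a discrete
Zipf-like distribution P(c) ∝ c^(-alpha) truncated at ``c_max``.

Somatic hypermutation is a per-site i.i.d. point-mutation model with AID
hotspot weighting: sites inside a WRC or GYW motif (W∈{A,T}, R∈{A,G},
Y∈{C,T}) mutate at ``rate_per_site * hotspot_multiplier`` (probability capped
at 1). SHM applies to B-cell receptor chains only. Mutants that would acquire
an in-frame stop codon or destroy a junction anchor are re-rolled so the
repertoire keeps its requested size and its productivity invariants.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

from ._seq import NT, translate
from .engine import Repertoire, SequenceRecord
from .germline import BCR_CHAINS

logger = logging.getLogger("vdjsim")

_W = set("AT")
_R = set("AG")
_Y = set("CT")


class ShapingError(ValueError):
    """Invalid abundance model or SHM request."""


@dataclass
class AbundanceModel:
    """Clone-size model: uniform (all 1), power-law, or empirical resampling."""

    kind: str
    alpha: float | None = None
    c_max: int = 10_000
    empirical_counts: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("uniform", "powerlaw", "empirical"):
            raise ShapingError(f"unknown abundance model kind {self.kind!r}")
        if self.kind == "powerlaw":
            if self.alpha is None or self.alpha <= 1:
                raise ShapingError("powerlaw requires alpha > 1")
            if self.c_max < 1:
                raise ShapingError("c_max must be >= 1")
        if self.kind == "empirical":
            if not self.empirical_counts:
                raise ShapingError("empirical model requires counts")
            if any(int(c) < 1 for c in self.empirical_counts):
                raise ShapingError("empirical counts must be positive integers")


def sample_abundances(model: AbundanceModel, n: int,
                      rng: np.random.Generator) -> np.ndarray:
    """Draw ``n`` clone sizes from the model."""
    if model.kind == "uniform":
        return np.ones(n, dtype=int)
    if model.kind == "empirical":
        pool = np.asarray(model.empirical_counts, dtype=int)
        return pool[rng.integers(len(pool), size=n)]
    c = np.arange(1, model.c_max + 1, dtype=float)
    p = c ** (-model.alpha)
    p /= p.sum()
    return rng.choice(model.c_max, size=n, p=p) + 1


def assign_abundances(repertoire: Repertoire, model: AbundanceModel,
                      rng: np.random.Generator) -> Repertoire:
    """Set ``duplicate_count`` per record; all other fields untouched."""
    if len(repertoire) == 0:
        raise ShapingError("cannot assign abundances to an empty repertoire")
    counts = sample_abundances(model, len(repertoire), rng)
    for rec, c in zip(repertoire.records, counts):
        rec.duplicate_count = int(c)
    return repertoire


def fit_powerlaw_alpha(counts, c_max: int = 10_000) -> float:
    """Maximum-likelihood exponent of the truncated discrete power law.

    Independent recovery check for :func:`sample_abundances`: maximizes
    sum(-alpha log c) - n log Z(alpha) with Z the truncated zeta sum.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.size == 0 or np.any(counts < 1):
        raise ShapingError("counts must be positive")
    log_counts_mean = np.log(counts).mean()
    c = np.arange(1, c_max + 1, dtype=float)
    log_c = np.log(c)

    def neg_loglik(alpha: float) -> float:
        z = np.exp(-alpha * log_c).sum()
        return alpha * log_counts_mean + np.log(z)

    res = minimize_scalar(neg_loglik, bounds=(1.0001, 10.0), method="bounded")
    return float(res.x)


# ---------------------------------------------------------------------------
# somatic hypermutation
# ---------------------------------------------------------------------------

def hotspot_mask(seq: str) -> np.ndarray:
    """Boolean mask: True where a site lies within any WRC or GYW 3-mer."""
    mask = np.zeros(len(seq), dtype=bool)
    for i in range(len(seq) - 2):
        a, b, c = seq[i], seq[i + 1], seq[i + 2]
        if (a in _W and b in _R and c == "C") or \
           (a == "G" and b in _Y and c in _W):
            mask[i:i + 3] = True
    return mask


def _mutate_once(seq: str, p: np.ndarray, rng: np.random.Generator
                 ) -> tuple[str, list[tuple[int, str, str]]]:
    hits = np.flatnonzero(rng.random(len(seq)) < p)
    chars = list(seq)
    edits: list[tuple[int, str, str]] = []
    for pos in hits:
        pos = int(pos)
        alternatives = [b for b in NT if b != chars[pos]]
        new = alternatives[rng.integers(3)]
        edits.append((pos, chars[pos], new))
        chars[pos] = new
    return "".join(chars), edits


def apply_shm(repertoire: Repertoire, rate_per_site: float,
              hotspot_multiplier: float = 1.0,
              rng: np.random.Generator | None = None,
              max_attempts: int = 100) -> Repertoire:
    """Apply somatic hypermutation in place to a BCR repertoire.

    Each mutant is re-rolled (fresh per-site draws) up to ``max_attempts``
    times if it acquires a stop codon or breaks a junction anchor; if every
    attempt fails the record is left unmutated and a warning counter in the
    repertoire metadata is incremented.
    """
    if rng is None:
        raise ShapingError("apply_shm requires a seeded generator")
    if not 0.0 <= rate_per_site <= 0.2:
        raise ShapingError("rate_per_site must lie in [0, 0.2]")
    if hotspot_multiplier < 1.0:
        raise ShapingError("hotspot_multiplier must be >= 1")
    chains = {rec.chain for rec in repertoire}
    if not chains <= BCR_CHAINS:
        raise ShapingError("SHM is B-cell only; repertoire contains "
                           f"{sorted(chains - BCR_CHAINS)}")
    if rate_per_site == 0.0:
        return repertoire
    fallbacks = 0
    for rec in repertoire.records:
        seq = rec.sequence_nt
        p = np.full(len(seq), rate_per_site)
        if hotspot_multiplier > 1.0:
            p[hotspot_mask(seq)] = min(rate_per_site * hotspot_multiplier, 1.0)
        ev = rec.event
        for _ in range(max_attempts):
            mutated, edits = _mutate_once(seq, p, rng)
            aa = translate(mutated)
            if "*" in aa:
                continue
            j_nt = mutated[ev.v_anchor_pos:ev.j_anchor_pos + 3]
            j_aa = translate(j_nt)
            if j_aa[0] != "C" or j_aa[-1] not in "FW":
                continue
            rec.sequence_nt = mutated
            rec.sequence_aa = aa
            rec.junction_nt = j_nt
            rec.junction_aa = j_aa
            ev.shm_edits = edits
            break
        else:
            fallbacks += 1
    if fallbacks:
        logger.warning("SHM: %d records left unmutated after %d attempts",
                       fallbacks, max_attempts)
    repertoire.metadata["shm_unmutated_fallbacks"] = (
        repertoire.metadata.get("shm_unmutated_fallbacks", 0) + fallbacks)
    return repertoire
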