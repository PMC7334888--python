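"""Codon-level sequence utilities shared across the package.

Everything here is frame-0 arithmetic on uppercase DNA strings over {A,C,G,T};
translation uses the standard genetic code with ``*`` for stop codons.
"""

from __future__ import annotations

import numpy as np
from Bio.Data.CodonTable import unambiguous_dna_by_id

NT = "ACGT"
AA20 = "ACDEFGHIKLMNPQRSTVWY"

_standard = unambiguous_dna_by_id[1]

#: codon -> single-letter amino acid, stops mapped to "*"
CODON_TO_AA: dict[str, str] = dict(_standard.forward_table)
for _stop in _standard.stop_codons:
    CODON_TO_AA[_stop] = "*"

STOP_CODONS = frozenset(_standard.stop_codons)
NON_STOP_CODONS = tuple(sorted(set(CODON_TO_AA) - STOP_CODONS))

#: amino acid -> sorted tuple of its codons
AA_TO_CODONS: dict[str, tuple[str, ...]] = {}
for _codon, _aa in sorted(CODON_TO_AA.items()):
    AA_TO_CODONS.setdefault(_aa, ())
    AA_TO_CODONS[_aa] = AA_TO_CODONS[_aa] + (_codon,)


def translate(seq: str) -> str:
    """Translate ``seq`` from frame 0; length must be a multiple of 3."""
    if len(seq) % 3 != 0:
        raise ValueError(f"sequence length {len(seq)} is not a multiple of 3")
    table = CODON_TO_AA
    try:
        return "".join(table[seq[i : i + 3]] for i in range(0, len(seq), 3))
    except KeyError as exc:  # pragma: no cover - guarded upstream
        raise ValueError(f"unknown codon {exc.args[0]!r}") from exc


def is_dna(seq: str) -> bool:
    return bool(seq) and not (set(seq) - set(NT))


def random_nt(rng: np.random.Generator, n: int) -> str:
    """Uniform random DNA string of length ``n``."""
    return "".join(rng.choice(list(NT), size=n)) if n else ""


def random_nt_no_stop(rng: np.random.Generator, n: int) -> str:
    """Random DNA of length ``n`` with no stop triplet (TAA/TAG/TGA) in ANY frame.

    Built base by base, resampling any base that would complete a stop triplet.
    Composition is therefore slightly non-uniform; used for synthetic germline
    bodies where frame-independent stop depletion is the point.
    """
    out: list[str] = []
    nts = list(NT)
    while len(out) < n:
        b = nts[rng.integers(4)]
        if len(out) >= 2 and out[-2] + out[-1] + b in STOP_CODONS:
            continue
        out.append(b)
    return "".join(out)


def random_codons_no_stop(rng: np.random.Generator, n_codons: int,
                          exclude: frozenset[str] = frozenset()) -> list[str]:
    """``n_codons`` random non-stop codons, optionally excluding some codons."""
    pool = [c for c in NON_STOP_CODONS if c not in exclude]
    return [pool[i] for i in rng.integers(len(pool), size=n_codons)]


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal lengths")
    return sum(x != y for x, y in zip(a, b))
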