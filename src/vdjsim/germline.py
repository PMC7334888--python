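"""Germline V/D/J reference handling.

Loads, validates, writes and synthesizes germline gene sets together with the
gene-frequency tables and trim/insertion length distributions that
parameterize in-silico V(D)J recombination.

Junction anchors follow the immunogenetics convention: the conserved cysteine
codon near the 3' end of every V gene, and the Phe/Trp codon of the J gene's
[FW]-G-x-G motif. Anchor offsets are 0-based nucleotide offsets from the 5'
end of the germline sequence.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._seq import (
    CODON_TO_AA,
    NT,
    is_dna,
    random_codons_no_stop,
    random_nt,
    random_nt_no_stop,
    translate,
)

SEGMENT_CLASSES = ("V", "D", "J")
CHAINS = ("IGH", "IGK", "IGL", "TRB", "TRA")
#: chains whose loci carry D segments
D_CHAINS = frozenset({"IGH", "TRB"})
BCR_CHAINS = frozenset({"IGH", "IGK", "IGL"})

_J_MOTIF_RE = re.compile(r"[FW]G.G")


class GermlineError(ValueError):
    """Invalid germline gene, set or reference file."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GermlineGene:
    """One germline segment (V, D or J).

    ``anchor_offset`` is the 0-based offset of the first base of the conserved
    cysteine codon (V) or of the J anchor Phe/Trp codon (J); ``None`` for D.
    """

    gene_id: str
    segment_class: str
    sequence_nt: str
    anchor_offset: int | None = None

    def __post_init__(self) -> None:
        if self.segment_class not in SEGMENT_CLASSES:
            raise GermlineError(f"unknown segment class {self.segment_class!r}")
        if not is_dna(self.sequence_nt):
            raise GermlineError(
                f"{self.gene_id}: sequence must be non-empty over {{A,C,G,T}}")
        if self.segment_class == "D":
            if self.anchor_offset is not None:
                raise GermlineError(f"{self.gene_id}: D genes carry no anchor")
            return
        off = self.anchor_offset
        if off is None:
            raise GermlineError(f"{self.gene_id}: {self.segment_class} gene "
                                "requires an anchor_offset")
        if off < 0 or off + 3 > len(self.sequence_nt):
            raise GermlineError(f"{self.gene_id}: anchor_offset {off} out of range")
        aa = CODON_TO_AA[self.sequence_nt[off:off + 3]]
        if self.segment_class == "V" and aa != "C":
            raise GermlineError(
                f"{self.gene_id}: V anchor codon translates to {aa!r}, not C")
        if self.segment_class == "J" and aa not in ("F", "W"):
            raise GermlineError(
                f"{self.gene_id}: J anchor codon translates to {aa!r}, not F/W")

    @property
    def anchor_codon(self) -> str | None:
        if self.anchor_offset is None:
            return None
        return self.sequence_nt[self.anchor_offset:self.anchor_offset + 3]

    def __len__(self) -> int:
        return len(self.sequence_nt)


@dataclass
class GermlineSet:
    """A complete germline reference for one species/chain."""

    species: str
    chain: str
    v_genes: list[GermlineGene]
    d_genes: list[GermlineGene] = field(default_factory=list)
    j_genes: list[GermlineGene] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.chain not in CHAINS:
            raise GermlineError(f"unknown chain {self.chain!r}")
        if not self.v_genes or not self.j_genes:
            raise GermlineError("v_genes and j_genes must be non-empty")
        if self.has_d and not self.d_genes:
            raise GermlineError(f"chain {self.chain} requires D genes")
        if not self.has_d and self.d_genes:
            raise GermlineError(f"chain {self.chain} has no D locus")
        ids = [g.gene_id for g in self.v_genes + self.d_genes + self.j_genes]
        if len(ids) != len(set(ids)):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise GermlineError(f"duplicate gene ids: {dupes}")
        self._by_id = {g.gene_id: g
                       for g in self.v_genes + self.d_genes + self.j_genes}

    @property
    def has_d(self) -> bool:
        return self.chain in D_CHAINS

    def gene(self, gene_id: str) -> GermlineGene:
        try:
            return self._by_id[gene_id]
        except KeyError:
            raise GermlineError(f"unknown gene id {gene_id!r}") from None

    def genes(self, segment_class: str) -> list[GermlineGene]:
        return {"V": self.v_genes, "D": self.d_genes,
                "J": self.j_genes}[segment_class]


class FrequencyTable:
    """Gene-usage probabilities for one segment class.

    The constructor normalizes, so raw counts are accepted as well as
    probabilities. Entry order is preserved (insertion order).
    """

    def __init__(self, entries: dict[str, float], segment_class: str):
        if segment_class not in SEGMENT_CLASSES:
            raise GermlineError(f"unknown segment class {segment_class!r}")
        if not entries:
            raise GermlineError("frequency table must be non-empty")
        weights = np.asarray(list(entries.values()), dtype=float)
        if np.any(weights < 0) or not np.all(np.isfinite(weights)):
            raise GermlineError("frequencies must be finite and >= 0")
        total = weights.sum()
        if total <= 0:
            raise GermlineError("frequencies sum to zero")
        self.segment_class = segment_class
        self.gene_ids: tuple[str, ...] = tuple(entries)
        self.probabilities: np.ndarray = weights / total
        self.entries: dict[str, float] = dict(zip(self.gene_ids,
                                                  self.probabilities.tolist()))

    def __len__(self) -> int:
        return len(self.gene_ids)

    def __eq__(self, other: object) -> bool:
        return (isinstance(other, FrequencyTable)
                and self.segment_class == other.segment_class
                and self.gene_ids == other.gene_ids
                and np.array_equal(self.probabilities, other.probabilities))

    def validate_against(self, germline_set: GermlineSet) -> None:
        """Every entry must resolve to a gene of matching segment class."""
        for gid in self.gene_ids:
            gene = germline_set.gene(gid)
            if gene.segment_class != self.segment_class:
                raise GermlineError(
                    f"{gid} is a {gene.segment_class} gene, table expects "
                    f"{self.segment_class}")


class LengthDistribution:
    """Discrete distribution over non-negative nt lengths (trims/insertions)."""

    PURPOSES = ("v_trim", "d_trim_5", "d_trim_3", "j_trim", "n1_len", "n2_len")

    def __init__(self, support, probabilities, purpose: str):
        if purpose not in self.PURPOSES:
            raise GermlineError(f"unknown purpose {purpose!r}")
        support = tuple(int(s) for s in support)
        probs = np.asarray(probabilities, dtype=float)
        if len(support) != len(probs) or len(support) == 0:
            raise GermlineError("support and probabilities must match, non-empty")
        if any(s < 0 for s in support):
            raise GermlineError("lengths must be non-negative")
        if any(b <= a for a, b in zip(support, support[1:])):
            raise GermlineError("support must be strictly increasing")
        if np.any(probs < 0) or probs.sum() <= 0:
            raise GermlineError("probabilities must be >= 0 with positive sum")
        self.purpose = purpose
        self.support = support
        self.probabilities = probs / probs.sum()

    @classmethod
    def geometric(cls, mean: float, purpose: str,
                  max_len: int = 15) -> "LengthDistribution":
        """Geometric-on-{0..max_len} with the given (untruncated) mean."""
        if mean < 0:
            raise GermlineError("mean must be >= 0")
        if mean == 0:
            return cls((0,), (1.0,), purpose)
        q = mean / (1.0 + mean)
        support = range(max_len + 1)
        probs = [(1 - q) * q ** k for k in support]
        return cls(tuple(support), probs, purpose)

    def sample(self, rng: np.random.Generator) -> int:
        return self.support[rng.choice(len(self.support), p=self.probabilities)]

    def restrict(self, max_value: int | None = None,
                 residue_mod3: int | None = None) -> "LengthDistribution | None":
        """Renormalized restriction; ``None`` if the admissible set is empty."""
        keep = [i for i, s in enumerate(self.support)
                if (max_value is None or s <= max_value)
                and (residue_mod3 is None or s % 3 == residue_mod3)]
        keep = [i for i in keep if self.probabilities[i] > 0]
        if not keep:
            return None
        return LengthDistribution(tuple(self.support[i] for i in keep),
                                  self.probabilities[keep], self.purpose)

    @property
    def max_support(self) -> int:
        return self.support[-1]


# ---------------------------------------------------------------------------
# FASTA I/O
# ---------------------------------------------------------------------------

def _detect_v_anchor(seq: str) -> int | None:
    """Last in-frame (frame 0) TGT/TGC codon start, or None."""
    found = None
    for i in range(0, len(seq) - 2, 3):
        if seq[i:i + 3] in ("TGT", "TGC"):
            found = i
    return found


def _detect_j_anchor(seq: str) -> int | None:
    """Nt offset of the first [FW]GxG amino-acid match in any frame, or None."""
    best = None
    for frame in range(3):
        aa = "".join(CODON_TO_AA[seq[i:i + 3]]
                     for i in range(frame, len(seq) - 2, 3))
        m = _J_MOTIF_RE.search(aa)
        if m:
            off = frame + 3 * m.start()
            if best is None or off < best:
                best = off
    return best


def load_germline_fasta(path, segment_class: str, anchor_rule: str = "auto",
                        anchor_offsets: dict[str, int] | None = None,
                        ) -> tuple[list[GermlineGene], list[tuple[str, str]]]:
    """Load germline genes of one segment class from FASTA.

    Returns ``(accepted, rejected)`` where ``rejected`` holds
    ``(record_id, reason)`` pairs for records whose anchor could not be
    established — never silently dropped.
    """
    if segment_class not in SEGMENT_CLASSES:
        raise GermlineError(f"unknown segment class {segment_class!r}")
    if anchor_rule not in ("auto", "explicit"):
        raise GermlineError(f"unknown anchor_rule {anchor_rule!r}")
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise GermlineError(f"empty FASTA: {path}")
    ids = [r.id for r in records]
    if len(ids) != len(set(ids)):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise GermlineError(f"duplicate identifiers in {path}: {dupes}")
    accepted: list[GermlineGene] = []
    rejected: list[tuple[str, str]] = []
    for rec in records:
        seq = str(rec.seq).upper()
        if not is_dna(seq):
            bad = sorted(set(seq) - set(NT)) or ["<empty>"]
            raise GermlineError(
                f"{rec.id}: non-ACGT characters {bad} in {path}")
        if segment_class == "D":
            accepted.append(GermlineGene(rec.id, "D", seq))
            continue
        if anchor_rule == "explicit":
            if anchor_offsets is None or rec.id not in anchor_offsets:
                rejected.append((rec.id, "no explicit anchor offset supplied"))
                continue
            off = anchor_offsets[rec.id]
        elif segment_class == "V":
            off = _detect_v_anchor(seq)
            if off is None:
                rejected.append((rec.id, "no cysteine anchor"))
                continue
        else:
            off = _detect_j_anchor(seq)
            if off is None:
                rejected.append((rec.id, "no J anchor motif"))
                continue
        try:
            accepted.append(GermlineGene(rec.id, segment_class, seq, off))
        except GermlineError as exc:
            rejected.append((rec.id, str(exc)))
    return accepted, rejected


def write_germline_fasta(genes: list[GermlineGene], path) -> None:
    records = [SeqRecord(Seq(g.sequence_nt), id=g.gene_id, description="")
               for g in genes]
    with open(path, "w", newline="\n") as fh:
        SeqIO.write(records, fh, "fasta")


def write_germline_set_fasta(germline_set: GermlineSet, directory) -> dict[str, str]:
    """Write v.fasta / d.fasta / j.fasta under ``directory``; returns paths."""
    import os
    paths = {}
    for cls, genes in (("V", germline_set.v_genes),
                       ("D", germline_set.d_genes),
                       ("J", germline_set.j_genes)):
        if not genes:
            continue
        p = os.path.join(str(directory), f"{cls.lower()}.fasta")
        write_germline_fasta(genes, p)
        paths[cls] = p
    return paths


# ---------------------------------------------------------------------------
# tabular distribution files: two columns, one-line header
# ---------------------------------------------------------------------------

def write_frequency_table(table: FrequencyTable, path) -> None:
    with open(path, "w", newline="\n") as fh:
        fh.write("gene_id\tprobability\n")
        for gid, p in table.entries.items():
            fh.write(f"{gid}\t{p:.12g}\n")


def read_frequency_table(path, segment_class: str) -> FrequencyTable:
    entries: dict[str, float] = {}
    with open(path) as fh:
        header = fh.readline()
        if not header.strip():
            raise GermlineError(f"empty frequency file: {path}")
        for line in fh:
            if not line.strip():
                continue
            gid, prob = line.rstrip("\n").split("\t")
            entries[gid] = float(prob)
    return FrequencyTable(entries, segment_class)


def write_length_distribution(dist: LengthDistribution, path) -> None:
    with open(path, "w", newline="\n") as fh:
        fh.write("length\tprobability\n")
        for s, p in zip(dist.support, dist.probabilities):
            fh.write(f"{s}\t{p:.12g}\n")


def read_length_distribution(path, purpose: str) -> LengthDistribution:
    support, probs = [], []
    with open(path) as fh:
        fh.readline()
        for line in fh:
            if not line.strip():
                continue
            s, p = line.rstrip("\n").split("\t")
            support.append(int(s))
            probs.append(float(p))
    return LengthDistribution(support, probs, purpose)


# ---------------------------------------------------------------------------
# synthetic reference generation
# ---------------------------------------------------------------------------

def _synthesize_v(rng: np.random.Generator, length: int, tail_len: int) -> tuple[str, int]:
    """Synthetic V: frame-0 ORF ending ...TGT + ``tail_len`` nt tail.

    The anchor cysteine sits ``tail_len + 3`` nt before the 3' end so that
    small 3' trims leave it intact; no in-frame TGT/TGC occurs after it, so
    auto-detection (last in-frame Cys codon) round-trips exactly.
    """
    n_codons = length // 3
    anchor_codon_idx = n_codons - 1 - tail_len // 3
    codons = random_codons_no_stop(rng, anchor_codon_idx)
    codons.append("TGT")
    codons += random_codons_no_stop(rng, tail_len // 3,
                                    exclude=frozenset({"TGT", "TGC"}))
    return "".join(codons), anchor_codon_idx * 3


_J_ANCHOR_LEN = 12  # TTT GGA NNN GGA


def _synthesize_j(rng: np.random.Generator, length: int) -> tuple[str, int]:
    """Synthetic J: stop-free random prefix + TTT GGA NNN GGA (F-G-x-G) tail.

    The anchor is the TTT; the 12-nt tail keeps (length - anchor) % 3 == 0 so
    a codon-aligned anchor implies a frame-closing J fragment. Resamples until
    the intended anchor is also the FIRST [FW]GxG match in any frame, so
    auto-detection round-trips.
    """
    prefix_len = length - _J_ANCHOR_LEN
    for _ in range(1000):
        x = random_codons_no_stop(rng, 1)[0]
        seq = random_nt_no_stop(rng, prefix_len) + "TTTGGA" + x + "GGA"
        if _detect_j_anchor(seq) == prefix_len:
            return seq, prefix_len
    raise GermlineError("could not synthesize a J gene with a unique anchor")


def generate_synthetic_germline_set(n_v: int, n_d: int, n_j: int,
                                    v_len: tuple[int, int] = (45, 75),
                                    d_len: tuple[int, int] = (9, 24),
                                    j_len: tuple[int, int] = (30, 54),
                                    seed: int = 0,
                                    chain: str | None = None,
                                    species: str = "synthetic",
                                    v_tail_len: int = 3) -> GermlineSet:
    """Generate a fully synthetic germline reference.

    The set carries the structural features junction extraction relies on
    (conserved V cysteine, J [FW]GxG anchor, frame-closing J tail) but is
    otherwise random; identical seeds give byte-identical sets. Gene bodies of
    D genes and J pre-anchor regions avoid stop triplets in every frame so
    productivity filtering does not bias gene usage (see docs/methods.md).
    """
    if n_v < 1 or n_j < 1:
        raise GermlineError("n_v and n_j must be >= 1")
    if n_d < 0:
        raise GermlineError("n_d must be >= 0")
    if chain is None:
        chain = "IGH" if n_d > 0 else "IGK"
    if (n_d > 0) != (chain in D_CHAINS):
        raise GermlineError(f"chain {chain} is inconsistent with n_d={n_d}")
    if v_tail_len % 3 != 0:
        raise GermlineError("v_tail_len must be a multiple of 3")
    if v_len[0] < v_tail_len + 6:
        raise GermlineError(f"v_len range too short for the anchor "
                            f"(need >= {v_tail_len + 6})")
    if j_len[0] < _J_ANCHOR_LEN:
        raise GermlineError(f"j_len range too short for the J anchor "
                            f"(need >= {_J_ANCHOR_LEN})")
    if d_len[0] < 1 and n_d > 0:
        raise GermlineError("d_len range too short")
    rng = np.random.default_rng(seed)

    def pick_len(lo: int, hi: int, multiple3: bool) -> int:
        n = int(rng.integers(lo, hi + 1))
        return n - n % 3 if multiple3 else n

    v_genes, d_genes, j_genes = [], [], []
    for i in range(n_v):
        length = max(pick_len(*v_len, True), v_tail_len + 6)
        seq, off = _synthesize_v(rng, length, v_tail_len)
        v_genes.append(GermlineGene(f"V{i + 1:02d}-syn", "V", seq, off))
    for i in range(n_d):
        seq = random_nt_no_stop(rng, pick_len(*d_len, False))
        d_genes.append(GermlineGene(f"D{i + 1:02d}-syn", "D", seq))
    for i in range(n_j):
        seq, off = _synthesize_j(rng, pick_len(*j_len, False))
        j_genes.append(GermlineGene(f"J{i + 1:02d}-syn", "J", seq, off))
    return GermlineSet(species=species, chain=chain, v_genes=v_genes,
                       d_genes=d_genes, j_genes=j_genes)


# ---------------------------------------------------------------------------
# frequency-table constructors and perturbation
# ---------------------------------------------------------------------------

def uniform_frequency_table(genes: list[GermlineGene]) -> FrequencyTable:
    if not genes:
        raise GermlineError("cannot build a frequency table from no genes")
    classes = {g.segment_class for g in genes}
    if len(classes) != 1:
        raise GermlineError("genes must share one segment class")
    return FrequencyTable({g.gene_id: 1.0 for g in genes}, classes.pop())


def geometric_frequency_table(genes: list[GermlineGene],
                              decay: float = 0.8) -> FrequencyTable:
    """Non-uniform table with probability proportional to decay**rank."""
    if not genes:
        raise GermlineError("cannot build a frequency table from no genes")
    if not 0 < decay <= 1:
        raise GermlineError("decay must be in (0, 1]")
    classes = {g.segment_class for g in genes}
    if len(classes) != 1:
        raise GermlineError("genes must share one segment class")
    return FrequencyTable({g.gene_id: decay ** i for i, g in enumerate(genes)},
                          classes.pop())


def perturb_frequency_table(table: FrequencyTable, noise_sd: float,
                            seed: int) -> FrequencyTable:
    """Multiplicative log-normal noise per entry, renormalized.

    ``noise_sd`` is the standard deviation of the log-normal on the log scale;
    0 returns an identical table. This is the single knob that moves a
    native-like parameterization toward an aberrant one.
    """
    if noise_sd < 0:
        raise GermlineError("noise_sd must be >= 0")
    if noise_sd == 0:
        return FrequencyTable(dict(table.entries), table.segment_class)
    rng = np.random.default_rng(seed)
    factors = np.exp(rng.normal(0.0, noise_sd, size=len(table)))
    weights = table.probabilities * factors
    return FrequencyTable(dict(zip(table.gene_ids, weights)),
                          table.segment_class)
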