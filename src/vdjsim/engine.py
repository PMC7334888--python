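"""In-silico V(D)J recombination.

One recombination draws germline genes from their frequency tables, trims the
V 3' end, both D ends and the J 5' end, inserts non-templated n1/n2 regions,
and assembles V'-n1-D'-n2-J' (V'-n-J' for loci without D). The reading frame
is frame 0 of the untrimmed V gene. Frame closure is deterministic: the length
of the last insertion is restricted to the residue class (mod 3) that makes
the assembled length divisible by 3, which — because every J gene ends an
integral number of codons after its anchor — also codon-aligns the J anchor.
Stop codons are the only stochastic rejection cause; unproductive drafts are
discarded and redrawn until the requested repertoire size is reached.

Every accepted sequence carries its complete generative trace
(:class:`RecombinationEvent`), the ground truth that downstream consistency
checks replay.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from collections import Counter
from dataclasses import dataclass, field

import numpy as np

from ._seq import NT, translate
from .germline import (
    FrequencyTable,
    GermlineError,
    GermlineGene,
    GermlineSet,
    LengthDistribution,
    uniform_frequency_table,
)

logger = logging.getLogger("vdjsim")

#: valid single-cell chain pairings (heavy/beta first by convention)
VALID_PAIRINGS = (("TRB", "TRA"), ("IGH", "IGK"), ("IGH", "IGL"))


class SimulationError(RuntimeError):
    """Recombination could not satisfy the configuration."""


class FrameUnsatisfiableError(SimulationError):
    """No admissible insertion length closes the reading frame."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class RecombinationEvent:
    """Complete generative trace of one sequence.

    ``fragment_boundaries`` are 0-based half-open intervals tiling the
    assembled (pre-mutation) sequence: (V', n1, D', n2, J') for D loci,
    (V', n, J') otherwise. ``shm_edits`` and ``modification_edits`` are
    ordered lists of (position, from_base, to_base) applied after assembly.
    """

    v_id: str
    j_id: str
    d_id: str | None = None
    v_trim_3p: int = 0
    d_trim_5p: int | None = None
    d_trim_3p: int | None = None
    j_trim_5p: int = 0
    n1_seq: str = ""
    n2_seq: str | None = None
    fragment_boundaries: tuple[tuple[int, int], ...] = ()
    v_anchor_pos: int = 0
    j_anchor_pos: int = 0
    shm_edits: list[tuple[int, str, str]] = field(default_factory=list)
    modification_edits: list[tuple[int, str, str]] = field(default_factory=list)
    attempt_index: int = 0


@dataclass
class SequenceRecord:
    """One simulated receptor sequence with full annotation."""

    sequence_id: str
    sequence_nt: str
    sequence_aa: str
    junction_nt: str
    junction_aa: str
    v_call: str
    j_call: str
    chain: str
    d_call: str | None = None
    duplicate_count: int = 1
    event: RecombinationEvent | None = None
    cell_id: str | None = None


@dataclass
class Repertoire:
    """Ordered collection of simulated sequences plus run metadata."""

    records: list[SequenceRecord]
    metadata: dict = field(default_factory=dict)
    #: GermlineSet, or {chain: GermlineSet} for paired repertoires
    germline_set: object | None = None

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __getitem__(self, i):
        return self.records[i]

    def germline_for(self, record: SequenceRecord) -> GermlineSet | None:
        gs = self.germline_set
        if isinstance(gs, dict):
            return gs.get(record.chain)
        return gs


@dataclass
class SimulationConfig:
    """Everything one simulation run needs; validated before any draw."""

    germline_set: GermlineSet
    v_freq: FrequencyTable
    j_freq: FrequencyTable
    n_sequences: int
    seed: int
    d_freq: FrequencyTable | None = None
    v_trim_dist: LengthDistribution | None = None
    d_trim5_dist: LengthDistribution | None = None
    d_trim3_dist: LengthDistribution | None = None
    j_trim_dist: LengthDistribution | None = None
    n1_dist: LengthDistribution | None = None
    n2_dist: LengthDistribution | None = None
    shm_rate: float = 0.0
    shm_hotspot_multiplier: float = 1.0
    abundance_model: object | None = None  # shaping.AbundanceModel
    species: str | None = None
    max_attempts_per_sequence: int = 1000

    def __post_init__(self) -> None:
        gs = self.germline_set
        if self.v_trim_dist is None:
            self.v_trim_dist = LengthDistribution.geometric(2.0, "v_trim")
        if self.j_trim_dist is None:
            self.j_trim_dist = LengthDistribution.geometric(2.0, "j_trim")
        if self.n1_dist is None:
            self.n1_dist = LengthDistribution.geometric(4.0, "n1_len")
        if gs.has_d:
            if self.d_trim5_dist is None:
                self.d_trim5_dist = LengthDistribution.geometric(2.0, "d_trim_5")
            if self.d_trim3_dist is None:
                self.d_trim3_dist = LengthDistribution.geometric(2.0, "d_trim_3")
            if self.n2_dist is None:
                self.n2_dist = LengthDistribution.geometric(4.0, "n2_len")
        if self.species is None:
            self.species = gs.species

    @property
    def chain(self) -> str:
        return self.germline_set.chain

    def validate(self) -> None:
        if self.n_sequences < 1:
            raise GermlineError("n_sequences must be >= 1")
        if self.seed is None:
            raise GermlineError("seed must be set")
        if not 0.0 <= self.shm_rate <= 0.2:
            raise GermlineError("shm_rate must lie in [0, 0.2]")
        if self.shm_hotspot_multiplier < 1.0:
            raise GermlineError("shm_hotspot_multiplier must be >= 1")
        gs = self.germline_set
        self.v_freq.validate_against(gs)
        self.j_freq.validate_against(gs)
        if gs.has_d:
            if self.d_freq is None:
                raise GermlineError("D locus requires a D frequency table")
            self.d_freq.validate_against(gs)
        elif self.d_freq is not None:
            raise GermlineError(f"chain {gs.chain} has no D locus")
        for gid in self.v_freq.gene_ids:
            g = gs.gene(gid)
            if self.v_trim_dist.restrict(max_value=_v_trim_limit(g)) is None:
                raise GermlineError(
                    f"v_trim distribution leaves no admissible trim for {gid}")
        for gid in self.j_freq.gene_ids:
            g = gs.gene(gid)
            if (len(g) - g.anchor_offset) % 3 != 0:
                raise GermlineError(
                    f"{gid}: (length - anchor_offset) must be a multiple of 3 "
                    "so the junction can be codon-aligned")
            if self.j_trim_dist.restrict(max_value=g.anchor_offset) is None:
                raise GermlineError(
                    f"j_trim distribution leaves no admissible trim for {gid}")
        if gs.has_d:
            for gid in self.d_freq.gene_ids:
                g = gs.gene(gid)
                if self.d_trim5_dist.restrict(max_value=len(g) - 1) is None:
                    raise GermlineError(
                        f"d_trim_5 distribution exceeds length of {gid}")

    def fingerprint(self) -> str:
        """Stable hash of all generative parameters (not output paths)."""
        gs = self.germline_set
        payload = {
            "species": self.species,
            "chain": gs.chain,
            "n_sequences": self.n_sequences,
            "seed": self.seed,
            "genes": [(g.gene_id, g.segment_class, g.sequence_nt,
                       g.anchor_offset)
                      for g in gs.v_genes + gs.d_genes + gs.j_genes],
            "freqs": {
                cls: (list(t.gene_ids), [round(p, 12) for p in t.probabilities])
                for cls, t in (("V", self.v_freq), ("D", self.d_freq),
                               ("J", self.j_freq)) if t is not None},
            "dists": {
                d.purpose: (list(d.support),
                            [round(p, 12) for p in d.probabilities])
                for d in (self.v_trim_dist, self.d_trim5_dist,
                          self.d_trim3_dist, self.j_trim_dist,
                          self.n1_dist, self.n2_dist) if d is not None},
            "shm": (self.shm_rate, self.shm_hotspot_multiplier),
            "abundance": repr(self.abundance_model),
            "max_attempts": self.max_attempts_per_sequence,
        }
        blob = json.dumps(payload, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


def make_default_config(germline_set: GermlineSet, n_sequences: int, seed: int,
                        **overrides) -> SimulationConfig:
    """Convenience constructor: uniform gene usage, default length models."""
    kwargs = dict(
        germline_set=germline_set,
        v_freq=uniform_frequency_table(germline_set.v_genes),
        j_freq=uniform_frequency_table(germline_set.j_genes),
        d_freq=(uniform_frequency_table(germline_set.d_genes)
                if germline_set.has_d else None),
        n_sequences=n_sequences,
        seed=seed,
    )
    kwargs.update(overrides)
    cfg = SimulationConfig(**kwargs)
    cfg.validate()
    return cfg


# ---------------------------------------------------------------------------
# elementary sampling operations
# ---------------------------------------------------------------------------

def sample_gene(table: FrequencyTable, rng: np.random.Generator) -> str:
    """Draw one gene id from the categorical distribution of ``table``."""
    idx = rng.choice(len(table.gene_ids), p=table.probabilities)
    return table.gene_ids[idx]


def _v_trim_limit(gene: GermlineGene) -> int:
    # 3' trims must leave the conserved cysteine codon intact
    return len(gene) - gene.anchor_offset - 3


def trim_segment(gene: GermlineGene, end: str, length_dist: LengthDistribution,
                 rng: np.random.Generator,
                 max_trim: int | None = None) -> tuple[str, int]:
    """Trim a sampled number of nt from one end of a germline gene.

    V genes are only ever trimmed at 3' and the trim is restricted so the
    anchor cysteine survives (equivalent to resampling offending draws).
    """
    if end not in ("5p", "3p"):
        raise ValueError(f"end must be '5p' or '3p', got {end!r}")
    if max_trim is None:
        if gene.segment_class == "V":
            if end != "3p":
                raise ValueError("V genes are trimmed at the 3' end only")
            max_trim = _v_trim_limit(gene)
        else:
            max_trim = len(gene) - 1
    restricted = length_dist.restrict(max_value=max_trim)
    if restricted is None:
        raise GermlineError(
            f"no admissible trim length for {gene.gene_id} "
            f"(max {max_trim}, support min {length_dist.support[0]})")
    t = restricted.sample(rng)
    seq = gene.sequence_nt[t:] if end == "5p" else gene.sequence_nt[:len(gene) - t]
    return seq, t


def choose_j_trim(j_gene: GermlineGene, length_dist: LengthDistribution,
                  rng: np.random.Generator) -> int:
    """5' J trim restricted so the J anchor survives; renormalized."""
    if j_gene.anchor_offset is None:
        raise GermlineError(f"{j_gene.gene_id} has no anchor")
    restricted = length_dist.restrict(max_value=j_gene.anchor_offset)
    if restricted is None:
        raise GermlineError(
            f"no admissible J trim for {j_gene.gene_id} "
            f"(anchor_offset {j_gene.anchor_offset})")
    return restricted.sample(rng)


def sample_insertions(n1_dist: LengthDistribution,
                      n2_dist: LengthDistribution,
                      template_len: int,
                      rng: np.random.Generator) -> tuple[str, str]:
    """Draw the n1 and frame-closing n2 insertions.

    ``template_len`` is the combined V'+D'+J' length. n1 is drawn freely;
    the n2 length is restricted to the residue class (mod 3) that makes the
    total assembled length divisible by 3.
    """
    n1_len = n1_dist.sample(rng)
    residue = (-(template_len + n1_len)) % 3
    restricted = n2_dist.restrict(residue_mod3=residue)
    if restricted is None:
        raise FrameUnsatisfiableError(
            f"no n2 length with residue {residue} (mod 3) in support")
    n2_len = restricted.sample(rng)
    bases = list(NT)
    n1 = "".join(bases[i] for i in rng.integers(4, size=n1_len))
    n2 = "".join(bases[i] for i in rng.integers(4, size=n2_len))
    return n1, n2


def sample_single_insertion(n_dist: LengthDistribution, template_len: int,
                            rng: np.random.Generator) -> str:
    """Frame-closing single insertion for loci without a D segment."""
    residue = (-template_len) % 3
    restricted = n_dist.restrict(residue_mod3=residue)
    if restricted is None:
        raise FrameUnsatisfiableError(
            f"no insertion length with residue {residue} (mod 3) in support")
    n_len = restricted.sample(rng)
    bases = list(NT)
    return "".join(bases[i] for i in rng.integers(4, size=n_len))


def extract_junction(sequence_nt: str, v_anchor_pos: int,
                     j_anchor_pos: int) -> tuple[str, str]:
    """CDR3 spanning the V cysteine codon through the J anchor codon, inclusive."""
    if v_anchor_pos % 3 or j_anchor_pos % 3:
        raise SimulationError(
            f"anchor positions not codon-aligned: {v_anchor_pos}, {j_anchor_pos}")
    if not 0 <= v_anchor_pos < j_anchor_pos + 3 <= len(sequence_nt):
        raise SimulationError("anchor positions out of range")
    junction_nt = sequence_nt[v_anchor_pos:j_anchor_pos + 3]
    return junction_nt, translate(junction_nt)


# ---------------------------------------------------------------------------
# one recombination
# ---------------------------------------------------------------------------

def _draft(config: SimulationConfig, rng: np.random.Generator):
    """One draft assembly; returns (fields..., None) or (None, cause)."""
    gs = config.germline_set
    v = gs.gene(sample_gene(config.v_freq, rng))
    j = gs.gene(sample_gene(config.j_freq, rng))
    v_seq, v_trim = trim_segment(v, "3p", config.v_trim_dist, rng)
    j_trim = choose_j_trim(j, config.j_trim_dist, rng)
    j_seq = j.sequence_nt[j_trim:]

    if gs.has_d:
        d = gs.gene(sample_gene(config.d_freq, rng))
        d5_dist = config.d_trim5_dist.restrict(max_value=len(d) - 1)
        if d5_dist is None:
            return None, "d_trim_unsatisfiable"
        d_trim5 = d5_dist.sample(rng)
        d3_dist = config.d_trim3_dist.restrict(
            max_value=min(len(d) - d_trim5, len(d) - 1))
        if d3_dist is None:
            return None, "d_trim_unsatisfiable"
        d_trim3 = d3_dist.sample(rng)
        d_seq = d.sequence_nt[d_trim5:len(d) - d_trim3]
        try:
            n1, n2 = sample_insertions(config.n1_dist, config.n2_dist,
                                       len(v_seq) + len(d_seq) + len(j_seq),
                                       rng)
        except FrameUnsatisfiableError:
            return None, "frame_unsatisfiable"
        fragments = (v_seq, n1, d_seq, n2, j_seq)
        event = RecombinationEvent(
            v_id=v.gene_id, j_id=j.gene_id, d_id=d.gene_id,
            v_trim_3p=v_trim, d_trim_5p=d_trim5, d_trim_3p=d_trim3,
            j_trim_5p=j_trim, n1_seq=n1, n2_seq=n2)
    else:
        try:
            n1 = sample_single_insertion(config.n1_dist,
                                         len(v_seq) + len(j_seq), rng)
        except FrameUnsatisfiableError:
            return None, "frame_unsatisfiable"
        fragments = (v_seq, n1, j_seq)
        event = RecombinationEvent(v_id=v.gene_id, j_id=j.gene_id,
                                   v_trim_3p=v_trim, j_trim_5p=j_trim,
                                   n1_seq=n1)

    seq = "".join(fragments)
    aa = translate(seq)
    if "*" in aa:
        return None, "stop_codon"

    bounds, pos = [], 0
    for frag in fragments:
        bounds.append((pos, pos + len(frag)))
        pos += len(frag)
    event.fragment_boundaries = tuple(bounds)
    event.v_anchor_pos = v.anchor_offset
    event.j_anchor_pos = len(seq) - len(j_seq) + (j.anchor_offset - j_trim)
    junction_nt, junction_aa = extract_junction(seq, event.v_anchor_pos,
                                                event.j_anchor_pos)
    if junction_aa[0] != "C" or junction_aa[-1] not in "FW":
        raise SimulationError(  # unreachable by construction; guarded anyway
            f"junction anchors corrupted: {junction_aa}")
    return (seq, aa, junction_nt, junction_aa, event), None


def recombine_once(config: SimulationConfig, rng: np.random.Generator,
                   tally: Counter | None = None,
                   sequence_id: str = "seq1") -> SequenceRecord:
    """Draft-and-discard loop for one accepted productive sequence."""
    rejected = 0
    for attempt in range(config.max_attempts_per_sequence):
        fields, cause = _draft(config, rng)
        if fields is None:
            rejected += 1
            if tally is not None:
                tally[cause] += 1
            continue
        seq, aa, junction_nt, junction_aa, event = fields
        event.attempt_index = rejected
        return SequenceRecord(
            sequence_id=sequence_id, sequence_nt=seq, sequence_aa=aa,
            junction_nt=junction_nt, junction_aa=junction_aa,
            v_call=event.v_id, d_call=event.d_id, j_call=event.j_id,
            chain=config.chain, event=event)
    causes = dict(tally) if tally is not None else {}
    raise SimulationError(
        f"max_attempts_per_sequence={config.max_attempts_per_sequence} "
        f"exceeded; rejection causes: {causes}")


# ---------------------------------------------------------------------------
# repertoire-level simulation
# ---------------------------------------------------------------------------

def simulate_repertoire(config: SimulationConfig) -> Repertoire:
    """Simulate until ``n_sequences`` productive sequences are accepted.

    Deterministic given the seed: all randomness flows from a single
    generator seeded from ``config.seed``. Clonal abundance and (for BCR
    chains) somatic hypermutation are applied afterwards with the same
    generator when configured.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    tally: Counter = Counter()
    width = max(6, len(str(config.n_sequences)))
    records = [
        recombine_once(config, rng, tally, sequence_id=f"sim{i:0{width}d}")
        for i in range(config.n_sequences)
    ]
    rep = Repertoire(
        records=records,
        metadata={
            "species": config.species,
            "chain": config.chain,
            "seed": config.seed,
            "config_hash": config.fingerprint(),
            "n_rejected": sum(tally.values()),
            "rejection_causes": dict(tally),
            "shm_unmutated_fallbacks": 0,
        },
        germline_set=config.germline_set,
    )
    logger.info("simulated %d sequences (%d drafts rejected: %s)",
                len(records), sum(tally.values()), dict(tally))
    if config.abundance_model is not None:
        from .shaping import assign_abundances
        assign_abundances(rep, config.abundance_model, rng)
    if config.shm_rate > 0:
        from .shaping import apply_shm
        apply_shm(rep, config.shm_rate, config.shm_hotspot_multiplier, rng)
    return rep


def simulate_paired(config_a: SimulationConfig, config_b: SimulationConfig,
                    n_cells: int, seed: int) -> Repertoire:
    """Simulate paired chains: ``n_cells`` cells, one record per chain each.

    Chains are simulated independently (no pairing bias model); records of a
    cell share a ``cell_id``. Valid pairings: TRB+TRA, IGH+IGK, IGH+IGL.
    """
    pair = (config_a.chain, config_b.chain)
    if pair not in VALID_PAIRINGS and pair[::-1] not in VALID_PAIRINGS:
        raise SimulationError(f"invalid chain pairing {pair[0]}+{pair[1]}")
    if n_cells < 1:
        raise SimulationError("n_cells must be >= 1")
    child_seeds = [int(s) & 0x7FFFFFFF
                   for s in np.random.SeedSequence(seed).generate_state(2)]
    reps = []
    for cfg, child in zip((config_a, config_b), child_seeds):
        cfg = dataclasses.replace(cfg, n_sequences=n_cells, seed=child)
        reps.append(simulate_repertoire(cfg))
    records: list[SequenceRecord] = []
    for i in range(n_cells):
        cell = f"cell{i:06d}"
        for rep in reps:
            rec = rep.records[i]
            rec.cell_id = cell
            rec.sequence_id = f"{cell}_{rec.chain}"
            records.append(rec)
    return Repertoire(
        records=records,
        metadata={
            "species": config_a.species,
            "chain": f"{config_a.chain}+{config_b.chain}",
            "seed": seed,
            "config_hash": hashlib.sha256(
                (config_a.fingerprint() + config_b.fingerprint()).encode()
            ).hexdigest(),
            "n_rejected": sum(r.metadata["n_rejected"] for r in reps),
            "rejection_causes": {},
            "n_cells": n_cells,
        },
        germline_set={config_a.chain: config_a.germline_set,
                      config_b.chain: config_b.germline_set},
    )
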