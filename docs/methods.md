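# Methods

## Recombination model

Each simulated sequence is one V(D)J recombination: germline V, (D,) J genes
are drawn from per-segment categorical frequency tables; the V 3' end, both
D ends and the J 5' end are trimmed by lengths drawn from discrete length
distributions; non-templated n1 (5' of D) and n2 (3' of D) insertions with
uniform base composition join the fragments (one insertion for loci without
D). The reading frame is frame 0 of the untrimmed V gene, and germline V
sequences are required to be stop-free open reading frames in that frame.

Frame closure is deterministic rather than probabilistic: the final
insertion length is sampled from its distribution restricted to the residue
class (mod 3) that makes the assembled length divisible by 3. Because every
J gene is required to end an integral number of codons after its anchor
(validated at configuration time), this single constraint also places the J
anchor on a codon boundary, so every draft is in frame with an intact CDR3
from the V cysteine through the J Phe/Trp. The only stochastic rejection
cause is an in-frame stop codon, in which case the whole draft is discarded
and redrawn; the per-cause tallies are reported in the run metadata and the
manifest. This is deliberately stronger than maximizing the probability of
an in-frame product: it is simpler to verify and leaves the discard loop
with a single, interpretable failure mode. Locally detectable dead ends are
handled by restriction instead of rejection — V trims are restricted so the
anchor cysteine survives, J trims so the J anchor survives — which is
distributionally identical to resampling offending draws but never wastes a
draft.

Coordinates are 0-based half-open everywhere internally. A fully trimmed-away
D (empty D') is legal and the d_call is still recorded: annotation reflects
simulation truth, not recoverability by an external annotator.

## Tunable parameters

| parameter | units | default | note |
|---|---|---|---|
| gene frequencies | probability | uniform | any non-negative weights; normalized on construction |
| trim lengths (V 3', D 5', D 3', J 5') | nt | geometric, mean 2, truncated at 15 | placeholder for unpublished empirical tables; fully user-overridable from two-column TSV files |
| insertion lengths (n1, n2) | nt | geometric, mean 4, truncated at 15 | same caveat |
| SHM rate | probability / site | 0 (off) | bounded at 0.2; BCR chains only |
| SHM hotspot multiplier | — | 1 | applied within WRC/GYW motifs, capped so p ≤ 1 |
| abundance α | — | — | discrete power law P(c) ∝ c^(−α), c ≤ c_max (default 10,000) |
| max attempts / sequence | drafts | 1000 | pathological configs fail fast with cause tallies |

The geometric defaults are explicit placeholders: no published empirical
deletion/insertion tables ship with the package, and any two-column
(value, probability) file replaces them.

## Synthetic germline reference

The generator emulates exactly the structural features the pipeline relies
on. Synthetic V genes are random stop-free ORFs whose anchor cysteine (TGT)
sits 3 nt + tail (default 3 nt, i.e. 6 nt total) before the 3' end, so trims
at the default distributions rarely need restriction; the tail contains no
in-frame TGT/TGC, making the "last in-frame cysteine" auto-detection rule an
exact round trip. Synthetic J genes end in TTT-GGA-NNN-GGA (F-G-x-G with a
non-stop x), anchored at the TTT; the 12-nt tail makes the post-anchor
region a whole number of codons, and generation resamples until that anchor
is the first [FW]GxG match in any frame so FASTA round trips are exact.

Two deliberate departures from plain uniform-random bodies: D genes and J
pre-anchor regions are generated without stop triplets (TAA/TAG/TGA) in any
frame. With fully random bodies, individual genes would carry different
numbers of potential stops, giving gene-specific draft-rejection rates that
systematically distort realized gene usage away from the input tables — an
artifact of the synthetic reference, not of the recombination machinery the
package exists to provide. Real germline segments are likewise strongly
depleted of stops in their productive reading frames.

What the synthetic reference does NOT emulate: allele nomenclature, realistic
V gene length (~300 nt framework regions; synthetic V defaults to 45–75 nt,
which shortens sequences without affecting junction statistics), family
structure or sequence similarity between genes, and empirical trim/insertion
profiles. Tests passing on synthetic references therefore demonstrate the
correctness of the recombination, annotation and metric machinery — not that
any particular simulated repertoire is indistinguishable from an
experimental one, which additionally requires user-supplied empirical
references and parameter tables.

## Somatic hypermutation

SHM is a per-site i.i.d. point-mutation model: each site mutates with
probability `rate` (times the hotspot multiplier inside WRC/GYW motifs,
where W∈{A,T}, R∈{A,G}, Y∈{C,T}; every position of a matching 3-mer counts
as hot), with a uniform choice among the three alternative bases. This is a
deliberate simplification of lineage-based (phylogenetic) SHM simulators: a
flat, documented model keeps the package self-contained, and the interface
leaves room for a lineage strategy later. Mutants that acquire a stop codon
or destroy a junction anchor (junction no longer C...F/W) are re-rolled up
to 100 times, then left unmutated with a counter in the metadata — the
repertoire never shrinks and never loses its productivity invariants.

## Post-simulation modifications

Motif implantation replaces (never inserts) an amino-acid window strictly
inside the junction — excluding both anchor residues — realized at the
nucleotide level as one uniformly chosen synonymous codon per residue.
Replacement keeps junction length distributions and reading frame intact so
motif-detection benchmarks are not confounded by length shifts. Synonymous
codon replacement redraws each codon with a given probability uniformly
from its synonymous alternatives (Met/Trp are fixed points). Both append
per-base edits to the record's event, as does SHM, so replaying
(germline fragments → trims → insertions → SHM edits → modification edits)
reproduces each sequence byte-for-byte; `annotation_consistency` asserts
exactly this and is the package's internal ground-truth check.

The similarity architecture operations act on the standard repertoire
network: nodes are records, edges connect equal-length junctions at Hamming
distance ≤ m (default 1, on junction_aa; identical junctions are adjacent at
distance 0; no edges across lengths). `prune_hubs` greedily removes the
highest-degree node (ties: lowest record index, for determinism) and
recomputes until the maximum degree is at or below the threshold;
`cap_degree` is a single pass removing all initially over-threshold nodes.
Both algorithms are this package's constructions for the stated purpose
(stress-testing graph-based tools); degrees are verified against an
all-pairs brute-force oracle in the tests.

## Comparison metrics

Gene-usage agreement is Spearman rank correlation over the union of gene
ids (absent genes count 0; average ranks on ties). CDR3 length distributions
are compared by Jensen–Shannon divergence in bits (bounded [0, 1],
symmetric). Positional amino-acid frequencies are compared as the mean over
junction positions 1..n (default 10, counted from the anchor cysteine;
records shorter than a position are excluded at that position, positions
with zero coverage are skipped with a warning) of the mean over the 20
amino acids of squared frequency differences. Gapped-k-mer profiles count
all length-k subsequences with at most one internal gap block of length
g ≤ m (default k = 3, m = 3; keys like `CA.2.RF`; g = 0 gives plain k-mers),
compared by Spearman correlation over the union of patterns.

## Numerical and design choices

* All randomness flows from one `numpy` generator seeded top-down; no
  global RNG state. Identical config + seed gives byte-identical AIRR TSV.
* Frequency tables and length distributions normalize on construction
  (counts are as common an input as probabilities); restriction
  renormalizes over the admissible subset.
* Paired simulation derives one child seed per chain from the master seed
  and simulates chains independently; cell ids link the two records of a
  cell. Pairing bias is out of scope.
* Abundance is one row per clone with a `duplicate_count`, the AIRR
  Rearrangement convention; rows are never expanded.
* The power-law abundance fit used as recovery oracle is the truncated
  discrete maximum-likelihood estimator (bounded scalar optimization of
  the exact log-likelihood).
* The AIRR writer emits a fixed, documented column order with
  `vdjsim_`-prefixed extension columns; the full event trace rides along as
  compact JSON, so a written repertoire remains fully replayable when read
  back.

## Problem sizes

The validation suite simulates 10,000 sequences per seed for the
input/output gene-usage fidelity check (three seeds, 20 V / 10 D / 5 J
genes, geometrically decaying input tables with ratio 0.8), 10 × 1,000
sequences across randomized configurations for the frame/productivity
invariants, and 2,000-sequence repertoires for the annotation-replay and
motif-recovery checks — sizes at which the binomial sampling bands and rank
statistics under test are tight while a full run stays interactive.

## Known limitations

* No P-nucleotides / palindromic additions; no sequencing-error or quality
  model; no selection; no clonal lineage trees or class-switching.
* Insertion base composition defaults to uniform rather than an empirical
  insertion-sequence pool.
* The internal annotation-consistency check validates the simulator against
  its own generative truth; it does not measure agreement with any external
  annotation service.
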