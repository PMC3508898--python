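# Methods

## Background and model

Heterotrimeric G-protein γ subunits (Gγ) bind Gβ through a coiled coil and
anchor the Gβγ dimer to the plasma membrane via lipidation of their
C-terminus. In plants, Gγ C-termini fall into three structural types:

* **Type A** — short subunits ending in a terminal CaaX box. The CaaX
  cysteine sits at signed index −4 (last residue = −1) and is the
  prenylation site; when a second cysteine sits at −6 (the CxC spacing of
  the CGCSIL terminus) it is an S-acylation candidate, giving dual
  lipidation.
* **Type B** — no CaaX box and no cysteine near the C-terminus at all.
  Membrane affinity is instead attributed to a C-terminal stretch enriched
  in basic (K/R), aromatic (W/F) and hydrophobic (I/L) residues, which the
  package quantifies as per-class fractions over the terminal window.
* **Type C** — a long cysteine-rich C-terminal extension (~70–350 aa at
  roughly 19–38% cysteine), often carrying short tandem repeats; about
  half of these tails also end in a CaaX-like motif.

All types share a conserved ~60-aa central domain containing the
[D/E]-P-L-[L/I] block (template positions 51–54) and the Gβ-contact
residues L/V12, E25, S36, D/E51, P52, L53, L/I54. The anchor block is the
coordinate origin for dissection: everything downstream of it is "the
tail".

## Classification procedure

`cterminal.classify` applies, in order: (1) no anchor → unclassified;
(2) tail length ≥ `l_c` **and** tail cysteine fraction ≥ `c_min` → C;
(3) terminal CaaX (cysteine exactly at −4, nothing after −1) → A;
(4) no cysteine in the last `window` residues → B; (5) otherwise
unclassified. The cysteine-rich test pre-empts the CaaX test because many
type C tails also terminate in a CaaX-like motif; the CaaX status of a
type C record is kept as evidence (`type_c_has_caax`), not as a separate
label.

Parameter defaults, with rationale:

| parameter | default | unit | rationale |
|-----------|---------|------|-----------|
| `l_c`     | 50      | aa   | below the ~70 aa minimum observed for cysteine-rich extensions, leaving margin for truncated tails |
| `c_min`   | 0.15    | —    | below the observed 19% lower bound of tail cysteine content |
| `window`  | 25      | aa   | "proximity of the C-terminus" is not quantified anywhere; 25 aa covers every observed type A/B terminal element with slack |

Tail length is measured from the anchor end (not from a hypothetical CaaX
position); the choice is recorded in the evidence of every call.

Prenyltransferase assignment uses only the CaaX X residue: X ∈ {L, I} →
PGGT-I, X ∈ {M, Q, A, C, S} → PFT, anything else → ambiguous. The two
preference sets are disjoint, so a call is never dual. The a1/a2 positions
are deliberately unconstrained — plant CaaX boxes frequently carry
tryptophan at a1 (CWIL), which would be rejected by an "aliphatic-only"
filter.

## Consensus

`consensus.cterm_consensus` right-anchors sequences (no MSA needed for
termini) and applies the strict majority rule: a residue wins a position
only with frequency **strictly** above 0.5 among contributors; exact 50%
ties and contributor-free positions are written `x`. Sequences shorter
than the offset abstain, as do gap characters, `x` placeholders and the
unknown residue `X` — an unknown residue cannot meaningfully vote, which
mirrors the "X never matches" rule used in identity computations.
`hierarchical_consensus` computes one consensus per group and joins the
group strings with a second majority pass, so each group weighs equally
regardless of size. `frequency_matrix` exposes the per-position residue
frequencies and information content (log2 20 − Shannon entropy, bits)
that underlie a sequence logo; rendering is out of scope.

## Gene structure

Exon boundaries are projected from CDS nucleotide space onto the protein:
for cumulative CDS length *c* after an exon, residue = ⌈c/3⌉ and phase =
c mod 3. The codon-split convention (boundary assigned to the codon
containing the split, with the phase reported) makes the projection
exactly invertible, which `exon_lengths_from_projection` exploits and the
tests verify. Projection depends only on exon lengths, never on absolute
genomic coordinates. `compare_boundaries` maps each projected residue
through a row's gap structure to an alignment column; equal columns across
genes mark a shared intron position. Gene models are taken on the coding
strand, 1-based inclusive, with the stop codon included by default
(protein length = CDS/3 − 1).

## Tandem repeats

`repeats.find_tandem_repeats` scans every start × unit length (default
units 5–10 aa), growing an array while the next unit's identity to the
running column-majority consensus stays ≥ `min_identity` (default 0.7 —
"sound identity" is not quantified anywhere, so the floor is configurable).
Identity is exact matches over the unit length; `X` never matches. Column
ties in the consensus resolve to the first copy's residue. Overlapping
candidates are resolved greedily by span length, then leftmost start, then
shortest unit. The detector is verified against an exhaustive
brute-force oracle in the tests.

## Phylogenetics

Only the conserved central domain is informative enough to align, so
`phylo.extract_central_domain` slices the column window
[anchor_start − 45, anchor_end + 2] (clipped) from the alignment; the
window boundaries are configurable because no canonical window exists.
Distances are p-distances with pairwise deletion of gapped column pairs
(`X` counts as compared but never matches), optionally Poisson-corrected
(d = −ln(1 − p), p capped at 0.95 with a saturation flag).

Trees are built by neighbor-joining (Saitou–Nei) rather than parsimony or
ML: the three reconstruction families are reported to produce very similar
topologies on this problem, and NJ is exactly testable in-house — the
suite verifies that NJ reproduces **every** unrooted topology on up to six
taxa from its additive path-distance matrix (3 + 15 + 105 trees). Q-ties
break on the lexicographically smallest representative-id pair; negative
branch lengths are floored at zero with the deficit moved to the sister
branch, preserving the pair's summed length.

Cluster support is measured by column bootstrap: resample columns with
replacement (one seeded generator, replicate r consuming draw r), rebuild
the NJ tree, and ask for each labelled group whether its taxa form one
side of a bipartition (monophyly on an unrooted tree). Support is the
fraction of replicates in which they do. Groups of size < 2 or > n−2 have
no non-trivial bipartition and are reported absent rather than 0.
`majority_consensus` implements the strict majority rule (> threshold,
no greedy completion of compatible minority splits); at the default
threshold 0.5 retained splits are automatically compatible, while lower
thresholds process splits in frequency order and skip incompatible ones.

## Synthetic data

`synthetic_data` generates cohorts with planted ground truth, because no
curated Gγ collection is available for download. A record is
N-terminus + central domain + type-specific tail:

* N-terminus: 10–75 aa, uniform residues (termini are described as highly
  variable with no compositional signal worth emulating);
* central domain: a fixed cysteine-free 60-aa template carrying the anchor
  and all Gβ contacts, with per-type signature substitutions (probability
  0.3 per non-conserved column) plus per-record noise (default divergence
  0.05); conserved positions are immune. Substitutions draw from the
  19 non-cysteine residues so noise can never violate the planted type B
  truth of a cysteine-free terminus;
* tails: type A = short linker + one of CRCWIL/CGCSIL/CLIL/CSIL; type B =
  cysteine-free linker + eudicot SR..KRWI or monocot KGSDFS (dialect tied
  to the assigned species group); type C = 70–350 aa with a uniform
  cysteine fraction drawn from 0.19–0.38, optional planted tandem array,
  and a CaaX-like terminus on about half of the tails.

The generator rejects (bounded resampling) any sequence whose first
anchor match is not the template one, keeping planted truth exact. The
MSA is native — gaps only pad the variable N-terminus (left) and tail
(right) — so template columns are shared and de-gapping a row recovers
its sequence; no internal indels are simulated. Gene models place exon
boundaries at shared template-relative positions (phases drawn once per
cohort), with the type C fifth boundary at the tail start and intron
lengths of 80–500 nt.

What passing tests on this generator do **not** show: robustness to real
indel-rich alignments, to non-uniform residue composition, to anchor
degeneracy beyond [D/E]PL[L/I], or to fragmentary sequences; the
between-type signal in the central domain is planted, so bootstrap
supports on synthetic cohorts measure the machinery, not any biological
claim.

## Problem sizes and numerical choices

The test suite uses cohorts of 15–300 sequences and bootstraps of 25–100
replicates on 24-taxon alignments; these sizes give stable statistics for
the planted effect sizes while keeping the whole suite fast. All
randomness flows through explicitly seeded `numpy` generators; repeated
runs with one seed are bit-identical. Distances guard saturation (p cap
0.95); consensus ties at exactly 0.5 are `x` by the strict-majority rule;
empty regions, ragged alignments, non-triplet CDS and overlapping exons
are rejected with messages naming the offender.

## Known limitations

* Classification is rule-based on the stated thresholds; it does not
  estimate them from data and offers no probabilistic confidence.
* Homology search (deciding whether a protein is a Gγ at all) is out of
  scope; inputs are assumed to be Gγ candidates.
* NJ replaces parsimony/ML; published support values obtained with other
  algorithms on curated data are not expected to be reproduced literally.
* In vivo prenylation efficiency is not predicted — the transferase call
  is a motif-level preference only.
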