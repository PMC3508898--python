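# ggamma

Structural typing, lipidation-site prediction and central-domain
phylogenetics for plant heterotrimeric G-protein γ subunits.

## The problem

Gγ subunits bind Gβ through a coiled coil and anchor the Gβγ dimer to the
plasma membrane through post-translational lipidation of their C-terminus.
In plants the C-termini are unusually diverse and fall into three
structural types:

* **A** — short subunits with a terminal CaaX prenylation box. The CaaX
  cysteine sits at signed index −4 (the last residue is −1); in termini
  like `CGCSIL` a second cysteine at −6 is an S-acylation candidate
  (dual lipidation). The CaaX X residue predicts the prenyltransferase:
  X ∈ {L, I} → PGGT-I, X ∈ {M, Q, A, C, S} → PFT.
* **B** — no CaaX and no cysteine near the C-terminus; instead a
  basic/aromatic/hydrophobic terminal stretch (eudicot consensus
  `SRxxKRWI`, monocot `KGSDFS`).
* **C** — a long (~70–350 aa) cysteine-rich (~19–38% Cys) C-terminal
  extension, often with 5–10 aa tandem repeats.

All types share a conserved ~60-aa central domain carrying the
[D/E]-P-L-[L/I] anchor block and the Gβ-contact residues (L/V12, E25,
S36, D/E51, P52, L53, L/I54). The package dissects each sequence at the
anchor, types it, predicts lipidation sites, derives majority-rule
C-terminal consensi (strict >50% rule, `x` elsewhere), projects gene exon
boundaries onto protein coordinates, detects tandem repeats, and measures
bootstrap monophyly support for the types on a central-domain
neighbor-joining phylogeny. A synthetic-data generator with planted
ground truth makes every stage testable end to end. See
`docs/methods.md` for the full model description.

For sequence analysts and plant G-protein researchers who want these
classifications and statistics reproducibly, from the command line or
from Python.

## Worked example

Generate a 12-sequence cohort (4 per type) and classify it:

```bash
$ ggamma simulate --n-a 4 --n-b 4 --n-c 4 --seed 42 --out-prefix demo
$ ggamma classify demo.faa --out demo.types.tsv
$ head -6 demo.types.tsv | cut -f1-10
# ggamma v0.1.0 | classify | input=demo.faa lc=50 cmin=0.15 window=25
id      species              group    label  tail_len  cys_frac  caax  prenyl_site  sacyl_site  transferase
A001    Arabidopsis thaliana eudicot  A      24        0.0833    CSIL  -4           -6          PGGT-I
A002    Glycine max          eudicot  A      20        0.05      CSIL  -4                       PGGT-I
A003    Carica papaya        eudicot  A      23        0.087     CWIL  -4           -6          PGGT-I
A004    Glycine max          eudicot  A      23        0.0435    CLIL  -4                       PGGT-I
```

Record `A001` ends in `...CGCSIL`: the CaaX box is `CSIL`, the −4
cysteine is the prenylation site (PGGT-I, because X = L) and the −6
cysteine is the S-acylation candidate — the dual-lipidation signature.
All 12 labels match the planted truth in `demo.truth.tsv`.

A majority-rule consensus of the type A C-termini:

```bash
$ ggamma consensus typeA.faa --k 8 --out consA.tsv
consensus: xxxxCxIL
```

Positions supported by strictly more than half of the sequences keep
their residue (here the invariant −4 cysteine and the terminal I/L);
variable positions print `x`.

Bootstrap support for the three types on the central-domain NJ tree
(100 column-resampled replicates, Poisson distances):

```bash
$ ggamma phylo demo.aln.faa --groups demo.groups.tsv \
      --bootstrap 100 --seed 5 --out demo.nwk --support demo.support.tsv
A       1.000
B       0.990
C       0.990
```

Each number is the fraction of replicate trees in which that type's taxa
form one side of a bipartition; `demo.nwk` carries per-node support
percentages. Identical seeds give byte-identical outputs.

The same operations are available as library functions
(`ggamma.classify`, `ggamma.cterm_consensus`, `ggamma.bootstrap_support`,
`ggamma.project_boundaries`, `ggamma.find_tandem_repeats`, ...).

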