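"""Synthetic Gγ cohorts with planted ground truth.

No curated Gγ collection is deposited alongside the analysis, so every
stage of the pipeline is exercised on generated data that emulates the
described sequence architecture:

* a conserved ~60-aa central domain carrying the [D/E]PL[L/I] anchor at
  template positions 51–54 and the seven Gβ-contact residues;
* type A tails: a short linker ending in a terminal CaaX box (CRCWIL
  consensus; CLIL / CSIL / CGCSIL variants);
* type B tails: cysteine-free, ending in the eudicot SR..KRWI or monocot
  KGSDFS dialect;
* type C tails: 70–350 aa cysteine-rich extensions (19–38% Cys), with an
  optional planted tandem repeat array and, for about half of them, a
  CaaX-like terminus;
* gene models with four exons (types A/B) or five (type C), the fifth
  boundary at the tail start, all boundaries at shared template-relative
  protein positions.

Each type carries its own central-domain "signature" (deterministic
substitutions at non-conserved positions) so that types separate on a
central-domain phylogeny; per-record noise is added on top.  Central-domain
substitutions never introduce cysteine, so planted type-B truth (a
Cys-free C-terminal window) cannot be violated by noise.  Everything is
deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .cterminal import GBETA_CONTACTS, find_anchor
from .seq_io import GAP, AlignedBlock, GeneModel, ProteinRecord

AA = tuple("ACDEFGHIKLMNPQRSTVWY")
AA_NO_C = tuple(ch for ch in AA if ch != "C")

# 60-aa central-domain template: L12, E25, S36 and D51-P52-L53-L54 at the
# Gβ-contact coordinates; cysteine-free; no [DE]PL[LI] match before 51.
TEMPLATE = (
    "MASGNTVERI"   # 1-10
    "QLKQTRLDAE"   # 11-20  (L12)
    "MIDNERMKLA"   # 21-30  (E25)
    "KAEIKSTFGH"   # 31-40  (S36)
    "VNEDLAKTLR"   # 41-50
    "DPLLVEGNWK"   # 51-60  (D51 P52 L53 L54)
)
ANCHOR_TEMPLATE_SPAN = (51, 54)
CONSERVED_POSITIONS = frozenset(GBETA_CONTACTS)

TYPE_A_ENDINGS = ("CRCWIL", "CGCSIL", "CLIL", "CSIL")
TYPE_B_MONOCOT_ENDING = "KGSDFS"
TYPE_C_CAAX_X = ("L", "I", "M", "S")

#: template-relative protein positions of the shared exon boundaries;
#: boundaries 1-3 are common to all types, the 4th (tail start) is type C only
TEMPLATE_CUTS = (10, 32, 55)
TYPE_C_EXTRA_CUT = 60

EUDICOT_SPECIES = (
    "Arabidopsis thaliana", "Glycine max", "Carica papaya",
    "Gossypium raimondii",
)
MONOCOT_SPECIES = ("Oryza sativa", "Zea mays", "Hordeum vulgare")
GYMNOSPERM_SPECIES = ("Picea abies", "Pinus taeda")


@dataclass(frozen=True)
class SynthConfig:
    """Generator settings; defaults are the described study conditions."""

    seed: int = 0
    n_per_type: dict = field(
        default_factory=lambda: {"A": 10, "B": 10, "C": 10})
    divergence: float = 0.05            # per-record, non-conserved columns
    between_type_divergence: float = 0.3  # type-signature substitution prob
    nterm_len_range: tuple[int, int] = (10, 75)
    tailA_linker_range: tuple[int, int] = (6, 14)
    tailB_linker_range: tuple[int, int] = (6, 14)
    tailC_len_range: tuple[int, int] = (70, 350)
    tailC_cys_range: tuple[float, float] = (0.19, 0.38)
    typeB_dialect: str = "mixed"        # eudicot | monocot | mixed
    typeC_caax_fraction: float = 0.5
    repeat_spec: Optional[tuple[int, int]] = None   # (unit_len, n_copies)
    exon_counts: dict = field(default_factory=lambda: {"A": 4, "B": 4, "C": 5})

    def __post_init__(self) -> None:
        for p in (self.divergence, self.between_type_divergence,
                  self.typeC_caax_fraction):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability out of [0,1]: {p}")
        for lo, hi in (self.nterm_len_range, self.tailC_len_range,
                       self.tailA_linker_range, self.tailB_linker_range):
            if lo > hi or lo < 0:
                raise ValueError(f"degenerate range ({lo}, {hi})")
        lo, hi = self.tailC_cys_range
        if not 0.0 <= lo <= hi <= 1.0:
            raise ValueError(f"invalid cysteine range ({lo}, {hi})")
        if self.typeB_dialect not in ("eudicot", "monocot", "mixed"):
            raise ValueError(f"unknown type B dialect {self.typeB_dialect!r}")
        if any(n < 0 for n in self.n_per_type.values()):
            raise ValueError("negative sequence count")


@dataclass(frozen=True)
class TruthRecord:
    """Planted ground truth for one generated sequence."""

    id: str
    true_type: str
    species: str
    group: str
    nterm_len: int
    tail_len: int
    tail_cys_frac: float
    ending: str
    true_tree_group: str
    repeat: Optional[tuple[int, int, int]] = None   # (start-in-tail, unit, copies)


@dataclass(frozen=True)
class Cohort:
    records: tuple[ProteinRecord, ...]
    alignment: AlignedBlock
    truth: tuple[TruthRecord, ...]

    @property
    def truth_table(self) -> pd.DataFrame:
        return pd.DataFrame([
            {
                "id": t.id, "true_type": t.true_type, "species": t.species,
                "group": t.group, "nterm_len": t.nterm_len,
                "tail_len": t.tail_len, "tail_cys_frac": t.tail_cys_frac,
                "ending": t.ending,
                "repeat": (";".join(map(str, t.repeat)) if t.repeat else ""),
            }
            for t in self.truth
        ])


def make_template() -> tuple[str, dict[int, frozenset[str]]]:
    """The central-domain template and its conserved-position map."""
    return TEMPLATE, dict(GBETA_CONTACTS)


def _mutate(seq: str, prob: float, rng: np.random.Generator,
            immune: frozenset[int] = CONSERVED_POSITIONS,
            alphabet: Sequence[str] = AA_NO_C) -> str:
    out = list(seq)
    for i in range(len(out)):
        if (i + 1) in immune:
            continue
        if rng.random() < prob:
            choices = [ch for ch in alphabet if ch != out[i]]
            out[i] = choices[rng.integers(len(choices))]
    return "".join(out)


def _random_seq(n: int, rng: np.random.Generator,
                alphabet: Sequence[str] = AA) -> str:
    return "".join(alphabet[i] for i in rng.integers(len(alphabet), size=n))


def make_type_templates(config: SynthConfig) -> dict[str, str]:
    """Per-type central-domain templates: the base template with a
    deterministic signature of substitutions at non-conserved positions."""
    out = {}
    for idx, label in enumerate(("A", "B", "C")):
        rng = np.random.default_rng((config.seed, 1000 + idx))
        out[label] = _mutate(TEMPLATE, config.between_type_divergence, rng)
    return out


def _pick_species(label: str, rng: np.random.Generator,
                  dialect: str) -> tuple[str, str]:
    if label == "B":
        # type B is absent from gymnosperms
        if dialect == "eudicot":
            pool = [(s, "eudicot") for s in EUDICOT_SPECIES]
        elif dialect == "monocot":
            pool = [(s, "monocot") for s in MONOCOT_SPECIES]
        else:
            pool = ([(s, "eudicot") for s in EUDICOT_SPECIES]
                    + [(s, "monocot") for s in MONOCOT_SPECIES])
    else:
        pool = ([(s, "eudicot") for s in EUDICOT_SPECIES]
                + [(s, "monocot") for s in MONOCOT_SPECIES]
                + [(s, "gymnosperm") for s in GYMNOSPERM_SPECIES])
    return pool[rng.integers(len(pool))]


def _type_a_tail(config: SynthConfig, rng: np.random.Generator) -> tuple[str, str]:
    lo, hi = config.tailA_linker_range
    linker = _random_seq(int(rng.integers(lo, hi + 1)), rng, AA_NO_C)
    ending = TYPE_A_ENDINGS[rng.integers(len(TYPE_A_ENDINGS))]
    return linker + ending, ending


def _type_b_tail(config: SynthConfig, rng: np.random.Generator,
                 group: str) -> tuple[str, str]:
    lo, hi = config.tailB_linker_range
    linker = _random_seq(int(rng.integers(lo, hi + 1)), rng, AA_NO_C)
    if group == "monocot":
        ending = TYPE_B_MONOCOT_ENDING
    else:
        ending = "SR" + _random_seq(2, rng, AA_NO_C) + "KRWI"
    return linker + ending, ending


def _type_c_tail(config: SynthConfig, rng: np.random.Generator
                 ) -> tuple[str, str, float, Optional[tuple[int, int, int]]]:
    lo, hi = config.tailC_len_range
    length = int(rng.integers(lo, hi + 1))
    f_lo, f_hi = config.tailC_cys_range
    frac = rng.uniform(f_lo, f_hi)
    tail = list(_random_seq(length, rng, AA_NO_C))
    n_cys = int(round(frac * length))
    cys_positions = rng.choice(length, size=n_cys, replace=False)
    for p in cys_positions:
        tail[p] = "C"
    repeat = None
    if config.repeat_spec is not None:
        unit_len, n_copies = config.repeat_spec
        span = unit_len * n_copies
        if span <= length:
            unit = _random_seq(unit_len, rng, AA)
            start0 = int(rng.integers(0, length - span + 1))
            tail[start0:start0 + span] = list(unit * n_copies)
            repeat = (start0 + 1, unit_len, n_copies)
    ending = ""
    if rng.random() < config.typeC_caax_fraction:
        caax = ("C" + _random_seq(2, rng, ("V", "I", "L", "W"))
                + TYPE_C_CAAX_X[rng.integers(len(TYPE_C_CAAX_X))])
        tail[-4:] = list(caax)
        ending = caax
    realized = "".join(tail)
    return realized, ending, realized.count("C") / len(realized), repeat


def make_record(
    label: str, config: SynthConfig, rng: np.random.Generator,
    rid: str = "seq1", type_template: str | None = None,
) -> tuple[ProteinRecord, TruthRecord, tuple[str, str, str]]:
    """Generate one record of the given type plus its truth.

    Returns (record, truth, (nterm, central, tail)) — the segments are what
    :func:`make_cohort` pads into the native alignment.  The final sequence
    is resampled (bounded retries) until its first anchor match is the
    template one, keeping planted truth exact."""
    if label not in ("A", "B", "C"):
        raise ValueError(f"unknown type {label!r}")
    template = type_template or make_type_templates(config)[label]
    dialect = config.typeB_dialect
    for _ in range(100):
        species, group = _pick_species(label, rng, dialect)
        lo, hi = config.nterm_len_range
        nterm = _random_seq(int(rng.integers(lo, hi + 1)), rng)
        central = _mutate(template, config.divergence, rng)
        repeat = None
        if label == "A":
            tail, ending = _type_a_tail(config, rng)
            cys_frac = tail.count("C") / len(tail)
        elif label == "B":
            tail, ending = _type_b_tail(config, rng, group)
            cys_frac = 0.0
        else:
            tail, ending, cys_frac, repeat = _type_c_tail(config, rng)
        seq = nterm + central + tail
        expected = (len(nterm) + ANCHOR_TEMPLATE_SPAN[0],
                    len(nterm) + ANCHOR_TEMPLATE_SPAN[1])
        if find_anchor(seq) == expected:
            break
    else:
        raise RuntimeError("could not place a unique anchor in 100 attempts")
    record = ProteinRecord(id=rid, seq=seq, species=species, group=group)
    truth = TruthRecord(
        id=rid, true_type=label, species=species, group=group,
        nterm_len=len(nterm), tail_len=len(tail), tail_cys_frac=cys_frac,
        ending=ending, true_tree_group=label, repeat=repeat,
    )
    return record, truth, (nterm, central, tail)


def make_cohort(config: SynthConfig) -> Cohort:
    """Generate a full cohort: records, natively aligned MSA, truth table.

    The alignment pads the variable N-terminus on the left and the tail on
    the right with gaps, so template columns (and hence the anchor) are
    shared across all rows and de-gapping a row recovers its sequence."""
    total = sum(config.n_per_type.get(t, 0) for t in ("A", "B", "C"))
    if total == 0:
        raise ValueError("cohort with zero sequences")
    rng = np.random.default_rng((config.seed, 0))
    templates = make_type_templates(config)
    entries = []
    for label in ("A", "B", "C"):
        for i in range(config.n_per_type.get(label, 0)):
            rid = f"{label}{i + 1:03d}"
            entries.append(make_record(label, config, rng, rid=rid,
                                       type_template=templates[label]))
    records = tuple(rec for rec, _, _ in entries)
    truths = tuple(tr for _, tr, _ in entries)
    nterm_max = max(len(seg[0]) for _, _, seg in entries)
    tail_max = max(len(seg[2]) for _, _, seg in entries)
    rows = []
    for rec, _, (nterm, central, tail) in entries:
        row = (GAP * (nterm_max - len(nterm)) + nterm + central
               + tail + GAP * (tail_max - len(tail)))
        rows.append((rec.id, row))
    return Cohort(records=records, alignment=AlignedBlock.from_rows(rows),
                  truth=truths)


def make_gene_models(
    records: Sequence[ProteinRecord], config: SynthConfig,
    rng: np.random.Generator,
) -> list[GeneModel]:
    """Gene models with 4 exons (types A/B) or 5 (type C).

    Exon boundaries sit at shared template-relative protein positions
    (phases drawn once per call and shared), so boundary projection maps
    all cohort members onto the same alignment columns; the type C extra
    boundary sits at the tail start.  CDS length is 3×(protein+stop)."""
    phases = [int(p) for p in rng.integers(0, 3, size=len(TEMPLATE_CUTS))]
    models = []
    for rec in records:
        anchor = find_anchor(rec.seq)
        if anchor is None:
            raise ValueError(f"{rec.id}: no anchor; not a generated record?")
        nterm_len = anchor[0] - ANCHOR_TEMPLATE_SPAN[0]
        tail_len = len(rec.seq) - nterm_len - len(TEMPLATE)
        total_nt = 3 * (len(rec.seq) + 1)
        cuts = []
        for tpos, phase in zip(TEMPLATE_CUTS, phases):
            residue = nterm_len + tpos
            cuts.append(3 * residue if phase == 0
                        else 3 * (residue - 1) + phase)
        is_type_c = tail_len >= config.tailC_len_range[0]
        if is_type_c:
            cuts.append(3 * (nterm_len + TYPE_C_EXTRA_CUT))
        edges = [0] + cuts + [total_nt]
        lengths = [b - a for a, b in zip(edges, edges[1:])]
        exons = []
        g = 1
        for idx, ln in enumerate(lengths):
            exons.append((g, g + ln - 1))
            if idx < len(lengths) - 1:
                g += ln + int(rng.integers(80, 500))
        models.append(GeneModel(gene_id=rec.id, exons=tuple(exons),
                                includes_stop=True))
    return models


def sample_from_consensus(
    consensus: str, n: int, noise, rng: np.random.Generator,
) -> list[str]:
    """Emit ``n`` sequences from a planted consensus with per-position
    substitution probability ``noise`` (scalar or per-position sequence).
    A substituted position receives a uniformly random *different* residue,
    so a position with noise ≥ 0.5 has no >50% majority in expectation."""
    k = len(consensus)
    probs = ([float(noise)] * k if np.isscalar(noise) else
             [float(p) for p in noise])
    if len(probs) != k:
        raise ValueError("noise vector length must match consensus length")
    out = []
    for _ in range(n):
        chars = []
        for ch, p in zip(consensus, probs):
            if rng.random() < p:
                choices = [a for a in AA if a != ch]
                chars.append(choices[rng.integers(len(choices))])
            else:
                chars.append(ch)
        out.append("".join(chars))
    return out
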