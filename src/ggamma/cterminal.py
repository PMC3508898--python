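"""C-terminal dissection and structural typing of plant Gγ subunits.

Plant Gγ subunits fall into three structural types distinguished purely by
their C-terminal architecture downstream of the conserved central domain:

* **type A** — short proteins ending in a terminal CaaX prenylation box
  (cysteine at −4, counted from the last residue as −1).  When a second
  cysteine sits at −6 with one residue between the two (the CxC spacing seen
  in the CGCSIL terminus), the −6 cysteine is an S-acylation candidate on
  top of the −4 prenylation site: dual lipidation.
* **type B** — no CaaX box and not a single cysteine near the C-terminus;
  membrane affinity is instead attributed to a basic/aromatic/hydrophobic
  amphipathic stretch, which :func:`anchor_composition` quantifies.
* **type C** — a long (~70–350 aa) cysteine-rich C-terminal extension
  (roughly 19–38% cysteine).

The classification anchors on the conserved [D/E]-P-L-[L/I] block of the
central domain; everything after that anchor is "the tail".
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, asdict
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .seq_io import AA20, GAP, ProteinRecord

ANCHOR_PATTERN = re.compile(r"[DE]PL[LI]")

#: CaaX X-residue preferences of the two relevant prenyltransferases.
PFT_X = frozenset("MQACS")       # protein farnesyltransferase
PGGT1_X = frozenset("LI")        # protein geranylgeranyltransferase type I

BASIC = frozenset("KR")
AROMATIC = frozenset("WF")
HYDROPHOBIC = frozenset("IL")

#: Gβ-contact residues of the central domain, template coordinates.
GBETA_CONTACTS: dict[int, frozenset[str]] = {
    12: frozenset("LV"),
    25: frozenset("E"),
    36: frozenset("S"),
    51: frozenset("DE"),
    52: frozenset("P"),
    53: frozenset("L"),
    54: frozenset("LI"),
}


@dataclass(frozen=True)
class ClassifyParams:
    """Thresholds of the typing decision procedure.

    l_c: minimum tail length (aa) for a type C call; below the shortest
        observed cysteine-rich extension (~70 aa) to leave margin.
    c_min: minimum cysteine fraction of the tail for type C; below the
        observed 19% lower bound.
    window: size (aa) of the C-terminal window that must be cysteine-free
        for a type B call, and over which anchor composition is scored.
    """

    l_c: int = 50
    c_min: float = 0.15
    window: int = 25


@dataclass(frozen=True)
class CaaxCall:
    caax: Optional[str]
    prenyl_site: Optional[int]
    sacyl_site: Optional[int]


@dataclass(frozen=True)
class AnchorScore:
    """Composition of the last ``window`` residues by membrane-anchor class."""

    basic: float
    aromatic: float
    hydrophobic: float
    basic_enriched: bool
    aromatic_enriched: bool
    hydrophobic_enriched: bool


@dataclass(frozen=True)
class CTerminalReport:
    anchor_span: Optional[tuple[int, int]]
    tail: str
    caax: Optional[str]
    prenyl_site: Optional[int]
    sacyl_site: Optional[int]
    transferase: str                # PFT | PGGT-I | ambiguous | none
    tail_len: int
    cys_frac_tail: float
    anchor_score: AnchorScore


@dataclass(frozen=True)
class TypeCall:
    label: str                      # A | B | C | unclassified
    evidence: dict
    params_used: ClassifyParams
    report: CTerminalReport


def find_anchor(seq: str) -> Optional[tuple[int, int]]:
    """First occurrence of the [D/E]-P-L-[L/I] block, 1-based inclusive span.

    Returns ``None`` when the motif is absent (absence is a value, not an
    error)."""
    if not seq:
        raise ValueError("empty sequence")
    m = ANCHOR_PATTERN.search(seq)
    if m is None:
        return None
    return (m.start() + 1, m.end())


def detect_caax(seq: str) -> CaaxCall:
    """Detect a terminal CaaX box and the dual-lipidation cysteine pair.

    The motif must be terminal: the prenylatable cysteine sits exactly at
    −4 with nothing after position −1.  The S-acylation candidate is the
    additional cysteine at −6 (two cysteines separated by one residue, as
    in the CGCSIL terminus), reported only when the CaaX itself is present.
    """
    if len(seq) < 4:
        raise ValueError("sequence shorter than 4 residues has no CaaX box")
    if seq[-4] != "C":
        return CaaxCall(caax=None, prenyl_site=None, sacyl_site=None)
    sacyl = -6 if len(seq) >= 6 and seq[-6] == "C" else None
    return CaaxCall(caax=seq[-4:], prenyl_site=-4, sacyl_site=sacyl)


def predict_transferase(caax: str) -> str:
    """Assign the prenyltransferase from the CaaX X residue alone.

    X ∈ {L, I} → PGGT-I (geranylgeranyl); X ∈ {M, Q, A, C, S} → PFT
    (farnesyl); any other X → ambiguous.  The two preference sets are
    disjoint, so dual membership is impossible.
    """
    if (
        not isinstance(caax, str)
        or len(caax) != 4
        or caax[0] != "C"
        or any(ch not in AA20 | {"X"} for ch in caax)
    ):
        raise ValueError(f"malformed CaaX box: {caax!r}")
    x = caax[-1]
    if x in PGGT1_X:
        return "PGGT-I"
    if x in PFT_X:
        return "PFT"
    return "ambiguous"


def anchor_composition(seq: str, window: int = 25) -> AnchorScore:
    """Fractions of basic (K/R), aromatic (W/F) and hydrophobic (I/L)
    residues over the last ``min(window, len)`` residues.

    Each class is flagged enriched when its fraction exceeds the uniform
    background (class size / 20)."""
    if window < 1:
        raise ValueError("window must be >= 1")
    tail = seq[-window:]
    n = len(tail)
    fractions = {}
    for name, cls in (("basic", BASIC), ("aromatic", AROMATIC),
                      ("hydrophobic", HYDROPHOBIC)):
        fractions[name] = sum(ch in cls for ch in tail) / n if n else 0.0
    bg = {"basic": len(BASIC) / 20, "aromatic": len(AROMATIC) / 20,
          "hydrophobic": len(HYDROPHOBIC) / 20}
    return AnchorScore(
        basic=fractions["basic"],
        aromatic=fractions["aromatic"],
        hydrophobic=fractions["hydrophobic"],
        basic_enriched=fractions["basic"] > bg["basic"],
        aromatic_enriched=fractions["aromatic"] > bg["aromatic"],
        hydrophobic_enriched=fractions["hydrophobic"] > bg["hydrophobic"],
    )


def cys_fraction(region: str) -> float:
    """Fraction of cysteines in a region; errors on an empty region."""
    if not region:
        raise ValueError("empty region")
    return region.count("C") / len(region)


def dissect(seq: str, params: ClassifyParams | None = None) -> CTerminalReport:
    """Full C-terminal dissection of one sequence (no type decision)."""
    params = params or ClassifyParams()
    anchor = find_anchor(seq)
    tail = seq[anchor[1]:] if anchor is not None else ""
    caax_call = (detect_caax(seq) if len(seq) >= 4
                 else CaaxCall(None, None, None))
    transferase = (predict_transferase(caax_call.caax)
                   if caax_call.caax is not None else "none")
    return CTerminalReport(
        anchor_span=anchor,
        tail=tail,
        caax=caax_call.caax,
        prenyl_site=caax_call.prenyl_site,
        sacyl_site=caax_call.sacyl_site,
        transferase=transferase,
        tail_len=len(tail),
        cys_frac_tail=cys_fraction(tail) if tail else 0.0,
        anchor_score=anchor_composition(seq, params.window),
    )


def classify(record: ProteinRecord | str,
             params: ClassifyParams | None = None) -> TypeCall:
    """Assign the structural type A / B / C / unclassified.

    Decision order (type C pre-empts the CaaX test because roughly half of
    the cysteine-rich extensions also end in a CaaX-like motif):

    1. no [D/E]PL[L/I] anchor → unclassified;
    2. tail = residues after the anchor;
    3. tail_len ≥ l_c and cys_fraction(tail) ≥ c_min → **C**;
    4. else terminal CaaX present → **A**;
    5. else no cysteine within the last ``window`` residues → **B**;
    6. else unclassified.

    Tail length is measured from the anchor end (recorded in the evidence).
    """
    params = params or ClassifyParams()
    seq = record.seq if isinstance(record, ProteinRecord) else record
    report = dissect(seq, params)
    evidence: dict = {
        "anchor_found": report.anchor_span is not None,
        "anchor_span": report.anchor_span,
        "tail_measured_from": "anchor_end",
        "tail_len": report.tail_len,
        "tail_len_ge_l_c": report.tail_len >= params.l_c,
        "cys_frac_tail": report.cys_frac_tail,
        "cys_frac_ge_c_min": report.cys_frac_tail >= params.c_min,
        "caax_present": report.caax is not None,
        "caax": report.caax,
        "cys_free_window": "C" not in seq[-params.window:],
    }
    if report.anchor_span is None:
        label = "unclassified"
    elif evidence["tail_len_ge_l_c"] and evidence["cys_frac_ge_c_min"]:
        label = "C"
        # sub-annotation only: CaaX-bearing vs CaaX-less cys-rich tails
        evidence["type_c_has_caax"] = report.caax is not None
    elif report.caax is not None:
        label = "A"
    elif evidence["cys_free_window"]:
        label = "B"
    else:
        label = "unclassified"
    return TypeCall(label=label, evidence=evidence, params_used=params,
                    report=report)


def validate_gbeta_contacts(
    aligned_seq: str,
    column_map: Mapping[int, int],
    contacts: Mapping[int, frozenset[str]] = GBETA_CONTACTS,
) -> list[int]:
    """Check the seven Gβ-contact residues on an aligned row.

    ``column_map`` maps template positions (12, 25, 36, 51, 52, 53, 54) to
    1-based alignment columns.  Returns the template positions whose residue
    is outside the allowed set (empty list = fully conformant)."""
    failing = []
    for pos in sorted(contacts):
        if pos not in column_map:
            raise ValueError(f"column map missing template position {pos}")
        col = column_map[pos]
        if not 1 <= col <= len(aligned_seq):
            raise ValueError(f"column {col} outside alignment row")
        if aligned_seq[col - 1] not in contacts[pos]:
            failing.append(pos)
    return failing


def _species_prefix(species: str) -> str:
    parts = species.split()
    if len(parts) >= 2:
        return parts[0][0].upper() + parts[1][0].lower()
    return species[0].upper() + species[1:2].lower()


def assign_names(
    records_with_calls: Iterable[tuple[ProteinRecord, TypeCall]],
) -> pd.DataFrame:
    """Systematic names: species initials + "GG" + type letter + ordinal.

    e.g. the first type A subunit of *Arabidopsis thaliana* becomes
    ``AtGGA1``.  Ordinals count per (species, type) in input order.
    Unclassified records receive no name.  Records lacking a species raise,
    listing the offending ids.
    """
    pairs = list(records_with_calls)
    missing = [rec.id for rec, _ in pairs if not rec.species]
    if missing:
        raise ValueError(f"records missing species: {missing}")
    counters: dict[tuple[str, str], int] = {}
    rows = []
    for rec, call in pairs:
        if call.label == "unclassified":
            rows.append({"old_id": rec.id, "new_name": ""})
            continue
        key = (rec.species, call.label)
        counters[key] = counters.get(key, 0) + 1
        name = f"{_species_prefix(rec.species)}GG{call.label}{counters[key]}"
        rows.append({"old_id": rec.id, "new_name": name})
    return pd.DataFrame(rows, columns=["old_id", "new_name"])
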