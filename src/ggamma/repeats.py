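"""Tandem repeat detection in cysteine-rich C-terminal tails.

Short repeats of 5–10 residues are common in the cysteine-rich extensions
of type C Gγ subunits and point at recent amplification events.  The
detector scans every (start, unit length) pair, grows an array while each
next unit stays above an identity floor against the running column-majority
consensus of the copies accepted so far, and reports maximal arrays with
overlaps resolved greedily by span length.  Identity is exact residue
matches over the unit length; unknown residues ('X') never match.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Sequence


@dataclass(frozen=True)
class RepeatArray:
    """One tandem array: ``n_copies`` units of ``unit_len`` residues
    starting at 1-based ``start``; ``mean_identity`` is the average
    identity of the copies to the final unit consensus."""

    start: int
    unit_len: int
    n_copies: int
    mean_identity: float
    unit_consensus: str

    @property
    def span(self) -> int:
        return self.n_copies * self.unit_len


def _identity(unit: str, consensus: str) -> float:
    assert len(unit) == len(consensus)
    matches = sum(
        a == b and a != "X" for a, b in zip(unit, consensus)
    )
    return matches / len(unit)


def _column_majority(copies: Sequence[str]) -> str:
    """Per-column majority; ties resolved toward the first copy's residue,
    else alphabetically."""
    out = []
    for col in range(len(copies[0])):
        votes = Counter(c[col] for c in copies)
        top = max(votes.values())
        tied = sorted(ch for ch, n in votes.items() if n == top)
        first = copies[0][col]
        out.append(first if first in tied else tied[0])
    return "".join(out)


def _grow_array(region: str, start0: int, unit_len: int,
                min_identity: float) -> tuple[int, float, str]:
    """Extend copies from 0-based start0; returns (n_copies, mean_identity,
    consensus) for the maximal extension."""
    copies = [region[start0:start0 + unit_len]]
    consensus = copies[0]
    pos = start0 + unit_len
    while pos + unit_len <= len(region):
        nxt = region[pos:pos + unit_len]
        if _identity(nxt, consensus) < min_identity:
            break
        copies.append(nxt)
        consensus = _column_majority(copies)
        pos += unit_len
    mean_id = sum(_identity(c, consensus) for c in copies) / len(copies)
    return len(copies), mean_id, consensus


def find_tandem_repeats(
    region: str,
    unit_range: tuple[int, int] = (5, 10),
    min_identity: float = 0.7,
) -> list[RepeatArray]:
    """Find tandem repeat arrays of unit length within ``unit_range``.

    Every start position and unit length is scanned; an array needs at
    least two copies and a mean copy-to-consensus identity of at least
    ``min_identity``.  Overlapping candidates are resolved greedily:
    longest span first, then leftmost, then shortest unit.
    """
    lo, hi = unit_range
    if lo < 1 or hi < lo:
        raise ValueError(f"invalid unit range {unit_range}")
    candidates: list[RepeatArray] = []
    for unit_len in range(lo, hi + 1):
        for start0 in range(0, len(region) - 2 * unit_len + 1):
            n, mean_id, cons = _grow_array(region, start0, unit_len,
                                           min_identity)
            if n >= 2 and mean_id >= min_identity:
                candidates.append(RepeatArray(
                    start=start0 + 1, unit_len=unit_len, n_copies=n,
                    mean_identity=mean_id, unit_consensus=cons,
                ))
    candidates.sort(key=lambda a: (-a.span, a.start, a.unit_len))
    selected: list[RepeatArray] = []
    occupied: list[tuple[int, int]] = []
    for cand in candidates:
        s, e = cand.start, cand.start + cand.span - 1
        if any(s <= oe and os <= e for os, oe in occupied):
            continue
        selected.append(cand)
        occupied.append((s, e))
    return selected
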