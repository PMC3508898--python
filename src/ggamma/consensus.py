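"""Majority-rule C-terminal consensus strings and logo matrices.

The consensus over a set of C-termini is computed per position on
right-anchored sequences (position −1 = last residue): the residue present
in strictly more than 50% of contributing sequences wins, otherwise the
position is written as lowercase ``x``.  Sequences shorter than the offset,
gap characters, unknown residues (uppercase ``X``) and ``x`` placeholders
do not contribute to a column's denominator.

A hierarchical variant reproduces the two-stage kingdom consensus: first a
consensus per group (phylum), then a consensus of the group consensi, so a
large group cannot swamp a small one.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .seq_io import GAP, AlignedBlock

_AA_ORDER = tuple("ACDEFGHIKLMNPQRSTVWY")
_NONVOTING = {GAP, "X", "x"}


@dataclass(frozen=True)
class ConsensusResult:
    """Majority-rule consensus over the last ``k`` positions.

    ``support[j]`` is the winning residue's fraction at position j (left to
    right, ending at −1); for an ``x`` position it is the best fraction that
    failed the >0.5 rule.  ``n_contributing[j]`` counts voting sequences.
    """

    consensus: str
    k: int
    support: tuple[float, ...]
    n_contributing: tuple[int, ...]

    @property
    def positions(self) -> list[int]:
        """Negative C-terminal indices, −k … −1."""
        return list(range(-self.k, 0))


def _column_votes(seqs: Sequence[str], offset: int) -> Counter:
    """Residue counts at C-terminal offset (1 = last residue)."""
    votes: Counter = Counter()
    for s in seqs:
        if len(s) >= offset:
            ch = s[-offset]
            if ch not in _NONVOTING:
                votes[ch] += 1
    return votes


def cterm_consensus(seqs: Iterable[str], k: int = 20) -> ConsensusResult:
    """Majority-rule consensus of right-anchored C-termini.

    A residue wins a position only with frequency strictly greater than 0.5
    among the sequences long enough to contribute there; ties at exactly 50%
    and positions with no contributors are written ``x``.
    """
    seqs = [s for s in seqs]
    if not seqs:
        raise ValueError("consensus of an empty sequence set")
    if k < 1:
        raise ValueError("k must be >= 1")
    chars, support, ns = [], [], []
    for offset in range(k, 0, -1):
        votes = _column_votes(seqs, offset)
        n = sum(votes.values())
        ns.append(n)
        if n == 0:
            chars.append("x")
            support.append(0.0)
            continue
        # deterministic winner: highest count, then alphabetical
        best, best_count = min(votes.items(), key=lambda kv: (-kv[1], kv[0]))
        frac = best_count / n
        if frac > 0.5:
            chars.append(best)
        else:
            chars.append("x")
        support.append(frac)
    return ConsensusResult(
        consensus="".join(chars), k=k,
        support=tuple(support), n_contributing=tuple(ns),
    )


def hierarchical_consensus(
    groups: Mapping[str, Iterable[str]], k: int = 20,
) -> ConsensusResult:
    """Two-stage consensus: per-group consensi joined by a second
    majority-rule pass in which each group weighs equally.

    ``x`` positions of a group consensus abstain in the joining pass.
    Empty groups are skipped; all groups empty is an error.
    """
    group_consensi = []
    for name in groups:
        seqs = list(groups[name])
        if seqs:
            group_consensi.append(cterm_consensus(seqs, k=k).consensus)
    if not group_consensi:
        raise ValueError("all groups empty")
    return cterm_consensus(group_consensi, k=k)


@dataclass(frozen=True)
class FrequencyMatrix:
    """Per-position residue frequencies and information content (bits).

    ``frequencies`` is positions × 20 (rows sum to 1 where anything
    contributes); ``information`` is log2(20) − Shannon entropy, NaN for
    positions with no contributing residues.  This is the numeric layer
    under a sequence logo."""

    frequencies: pd.DataFrame
    information: pd.Series


def frequency_matrix(
    data: AlignedBlock | Sequence[str], k: int | None = None,
) -> FrequencyMatrix:
    """Position-frequency matrix from an alignment (per column) or from
    unaligned sequences (right-anchored over the last ``k`` positions,
    default the longest sequence)."""
    if isinstance(data, AlignedBlock):
        columns = [
            [s[j] for _, s in data.records] for j in range(data.ncols)
        ]
        index = list(range(1, data.ncols + 1))
    else:
        seqs = list(data)
        if not seqs:
            raise ValueError("no sequences")
        kk = k or max(len(s) for s in seqs)
        columns = []
        for offset in range(kk, 0, -1):
            columns.append([s[-offset] for s in seqs if len(s) >= offset])
        index = list(range(-kk, 0))
    freq = np.zeros((len(columns), len(_AA_ORDER)))
    info = np.full(len(columns), np.nan)
    for i, col in enumerate(columns):
        votes = Counter(ch for ch in col if ch not in _NONVOTING)
        n = sum(votes.values())
        if n == 0:
            continue
        for j, aa in enumerate(_AA_ORDER):
            freq[i, j] = votes.get(aa, 0) / n
        entropy = -sum(
            (c / n) * math.log2(c / n) for c in votes.values() if c > 0
        )
        info[i] = math.log2(20) - entropy
    frequencies = pd.DataFrame(freq, index=index, columns=list(_AA_ORDER))
    return FrequencyMatrix(
        frequencies=frequencies,
        information=pd.Series(info, index=index, name="information_bits"),
    )
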