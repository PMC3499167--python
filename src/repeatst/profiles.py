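"""Anchored-alignment profiles: sequence-logo information content and
two-group enrichment.

Repeats of equal length, anchored at their motif, form an ungapped
alignment. Per-column information content is log2(20) - H (max 4.32
bits for a unanimous column, no small-sample correction), matching the
logo convention. Two-group comparison reports residues whose
per-column frequencies differ significantly between groups (two-sided
Fisher exact test), split into enriched and depleted sets -- the
two-sample-logo statistic used to contrast type I and type IIa repeats.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

from scipy.stats import fisher_exact

MAX_BITS = math.log2(20)


@dataclass
class ProfileMatrix:
    """Per-column residue counts, frequencies and information content."""

    length: int
    n_sequences: int
    counts: list            # per column: residue -> int
    freqs: list             # per column: residue -> frequency
    bits: list              # per column: log2(20) - H


@dataclass
class TwoSampleColumn:
    position: int                       # 1-based column
    enriched: list = field(default_factory=list)   # (residue, dfreq, p)
    depleted: list = field(default_factory=list)


def _check_equal_length(repeats: Sequence[str]) -> int:
    lengths = {len(r) for r in repeats}
    if len(lengths) != 1:
        raise ValueError(f"repeats of unequal length: {sorted(lengths)}")
    return lengths.pop()


def build_profile(repeats: Sequence[str]) -> ProfileMatrix:
    """Frequency/information profile of >=2 equal-length repeats."""
    repeats = [r.upper() for r in repeats]
    if len(repeats) < 2:
        raise ValueError("profile requires >=2 repeats")
    length = _check_equal_length(repeats)
    n = len(repeats)
    counts, freqs, bits = [], [], []
    for col in range(length):
        c: dict[str, int] = {}
        for r in repeats:
            c[r[col]] = c.get(r[col], 0) + 1
        f = {res: k / n for res, k in c.items()}
        entropy = -sum(p * math.log2(p) for p in f.values() if p > 0)
        counts.append(c)
        freqs.append(f)
        bits.append(MAX_BITS - entropy)
    return ProfileMatrix(length=length, n_sequences=n,
                         counts=counts, freqs=freqs, bits=bits)


def two_sample_logo(group_a: Sequence[str], group_b: Sequence[str],
                    alpha: float = 0.05) -> list[TwoSampleColumn]:
    """Per-column residue enrichment of group A over group B.

    For each column and residue, the 2x2 count table (residue vs other,
    A vs B) is tested with a two-sided Fisher exact test; residues with
    p <= alpha and a nonzero frequency difference are reported, split
    into enriched (df > 0) and depleted (df < 0), ordered by |df|.
    Columns with no significant residue are omitted, so fully conserved
    shared positions never appear.
    """
    group_a = [r.upper() for r in group_a]
    group_b = [r.upper() for r in group_b]
    if not group_a or not group_b:
        raise ValueError("both groups must be non-empty")
    la = _check_equal_length(group_a)
    lb = _check_equal_length(group_b)
    if la != lb:
        raise ValueError(f"group repeat lengths differ: {la} vs {lb}")
    na, nb = len(group_a), len(group_b)

    out: list[TwoSampleColumn] = []
    for col in range(la):
        col_a = [r[col] for r in group_a]
        col_b = [r[col] for r in group_b]
        column = TwoSampleColumn(position=col + 1)
        for res in sorted(set(col_a) | set(col_b)):
            a = col_a.count(res)
            b = col_b.count(res)
            df = a / na - b / nb
            if df == 0:
                continue
            _, p = fisher_exact([[a, na - a], [b, nb - b]], alternative="two-sided")
            if p <= alpha:
                (column.enriched if df > 0 else column.depleted).append((res, df, p))
        if column.enriched or column.depleted:
            column.enriched.sort(key=lambda t: -abs(t[1]))
            column.depleted.sort(key=lambda t: -abs(t[1]))
            out.append(column)
    return out
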