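"""ST signature detection, repeat segmentation, consensus and perfection.

The ST family signature is the repeat-initial motif (D/E)FEPRP-X4-Y: a
hexapeptide whose first residue may be Asp or Glu, four partially
conserved residues (X4, repeat positions 7-10), and a fully conserved
tyrosine at repeat position 11. Every occurrence of the motif opens a
new repeat unit, including the final truncated one, so the repeat
region partitions the span from the first anchor to the C-terminus.

Repeat perfection (Psim) is the fraction of repeat positions that agree
with the column-wise majority consensus of the anchored repeat
alignment: 1.0 for perfect tandem repeats, lower as units degenerate.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Literal, Sequence

HEXAMER = "DFEPRP"          # first position admits D or E
HEXAMER_FIRST = "DE"
ANCHOR_TYR_OFFSET = 10      # 0-based offset of the conserved Tyr (position 11)
MOTIF_SPAN = 11
MIN_CANONICAL_LEN = 22      # shortest typical full repeat (family range 22-27)

UnitStatus = Literal["canonical", "imperfect_leading", "truncated_terminal"]


@dataclass
class RepeatUnit:
    """One repeat unit anchored at its (D/E)FEPRP motif."""

    index: int                      # ordinal from the N-terminus, 0-based
    start: int                      # 0-based, half-open span in the scanned string
    end: int
    residues: str
    status: UnitStatus = "canonical"
    anchor_tyr_offset: int = MOTIF_SPAN  # 1-based position of the conserved Tyr

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def hexamer_first(self) -> str:
        return self.residues[0]

    @property
    def x4(self) -> str:
        return self.residues[6:10]


@dataclass
class RepeatRegion:
    """The ordered, contiguous set of repeat units of one protein."""

    units: list[RepeatUnit]
    modal_length: int
    length_pattern: Literal["uniform", "alternating", "heterogeneous"]
    psim: float | None = None
    consensus: str | None = None

    @property
    def start(self) -> int:
        return self.units[0].start

    @property
    def end(self) -> int:
        return self.units[-1].end

    def canonical_units(self) -> list[RepeatUnit]:
        return [u for u in self.units if u.status == "canonical"]


def _hexamer_mismatches(window: str) -> int:
    mm = 0 if window[0] in HEXAMER_FIRST else 1
    mm += sum(1 for a, b in zip(window[1:6], HEXAMER[1:6]) if a != b)
    return mm


def scan_motif(residues: str, max_hexamer_mismatch: int = 0,
               start: int = 0, stop: int | None = None) -> list[int]:
    """Return sorted 0-based anchor positions of the (D/E)FEPRP-X4-Y motif.

    An anchor i requires residues[i:i+6] within ``max_hexamer_mismatch``
    of the hexapeptide and residues[i+10] == 'Y' (the tyrosine is never
    relaxed). Overlapping candidates are resolved leftmost-first.
    """
    residues = residues.upper()
    stop = len(residues) if stop is None else stop
    anchors: list[int] = []
    i = start
    limit = min(stop, len(residues)) - MOTIF_SPAN
    while i <= limit:
        if (residues[i + ANCHOR_TYR_OFFSET] == "Y"
                and _hexamer_mismatches(residues[i:i + 6]) <= max_hexamer_mismatch):
            anchors.append(i)
            i += MOTIF_SPAN  # candidates overlapping an accepted motif are dropped
        else:
            i += 1
    return anchors


def is_st_protein(residues: str, max_hexamer_mismatch: int = 0) -> bool:
    """True if the sequence carries at least one ST signature motif."""
    return bool(scan_motif(residues, max_hexamer_mismatch))


def _is_canonical(unit_residues: str) -> bool:
    return (len(unit_residues) >= MOTIF_SPAN
            and unit_residues[0] in HEXAMER_FIRST
            and unit_residues[1:6] == HEXAMER[1:6]
            and unit_residues[ANCHOR_TYR_OFFSET] == "Y")


def _length_pattern(lengths: Sequence[int]) -> str:
    if len(set(lengths)) <= 1:
        return "uniform"
    if len(set(lengths)) == 2:
        # alternating means the two lengths strictly interleave
        if all(lengths[i] != lengths[i + 1] for i in range(len(lengths) - 1)):
            return "alternating"
    return "heterogeneous"


def segment_repeats(residues: str, anchors: Sequence[int],
                    fuzzy_leading: bool = False) -> RepeatRegion:
    """Partition the span from the first anchor to the C-terminus into units.

    Unit k runs from anchor k to the residue before anchor k+1; the last
    unit runs to the C-terminus and is flagged ``truncated_terminal``
    when shorter than the modal canonical length. With ``fuzzy_leading``
    a pre-scan tolerating one hexamer mismatch over at most two modal
    lengths before the first anchor may add ``imperfect_leading`` units.
    """
    residues = residues.upper()
    anchors = sorted(anchors)
    if not anchors:
        raise ValueError("not an ST signature: no repeat anchors")

    body_lengths = [anchors[k + 1] - anchors[k] for k in range(len(anchors) - 1)]
    if body_lengths:
        counts = Counter(body_lengths)
        top = max(counts.values())
        modal = min(length for length, c in counts.items() if c == top)
    else:
        last_len = len(residues) - anchors[0]
        modal = last_len if last_len >= MIN_CANONICAL_LEN else MIN_CANONICAL_LEN

    if fuzzy_leading:
        lead_start = max(0, anchors[0] - 2 * modal)
        fuzzy = scan_motif(residues, max_hexamer_mismatch=1,
                           start=lead_start, stop=anchors[0])
        anchors = sorted(set(a for a in fuzzy if a < anchors[0])) + list(anchors)

    units: list[RepeatUnit] = []
    for k, a in enumerate(anchors):
        end = anchors[k + 1] if k + 1 < len(anchors) else len(residues)
        seg = residues[a:end]
        if k == len(anchors) - 1 and end - a < modal:
            status: UnitStatus = "truncated_terminal"
        elif _is_canonical(seg):
            status = "canonical"
        else:
            status = "imperfect_leading"
        units.append(RepeatUnit(index=k, start=a, end=end, residues=seg, status=status))

    canon_lengths = [u.length for u in units if u.status == "canonical"]
    region = RepeatRegion(units=units, modal_length=modal,
                          length_pattern=_length_pattern(canon_lengths))
    if len(units) >= 2:
        region.psim = psim(region)
    eligible = [u for u in region.canonical_units() if u.length == modal]
    if len(eligible) >= 2:
        region.consensus = derive_consensus(region)
    return region


def _column_consensus(unit_strings: Sequence[str], column: int) -> str | None:
    """Majority residue at a column; ties broken by the earliest unit."""
    observed = [(i, s[column]) for i, s in enumerate(unit_strings) if column < len(s)]
    if not observed:
        return None
    counts = Counter(res for _, res in observed)
    top = max(counts.values())
    tied = {res for res, c in counts.items() if c == top}
    for _, res in observed:
        if res in tied:
            return res
    return None  # pragma: no cover


def derive_consensus(region: RepeatRegion, consensus_threshold: float = 0.5) -> str:
    """Column-wise consensus of canonical modal-length units.

    Emits the most frequent residue where its frequency reaches the
    threshold, else 'X'; ties go to the residue of the earliest unit.
    """
    units = [u.residues for u in region.canonical_units()
             if u.length == region.modal_length]
    if len(units) < 2:
        raise ValueError("consensus requires >=2 canonical units of modal length")
    out = []
    n = len(units)
    for col in range(region.modal_length):
        counts = Counter(u[col] for u in units)
        top = max(counts.values())
        if top / n >= consensus_threshold:
            out.append(_column_consensus(units, col))
        else:
            out.append("X")
    return "".join(out)


def psim(region: RepeatRegion | Sequence[str]) -> float:
    """Repeat perfection: fraction of unit positions matching the
    plain-majority column consensus (threshold 0, earliest-unit
    tie-break). Truncated units are compared over their own length.
    """
    if isinstance(region, RepeatRegion):
        unit_strings = [u.residues for u in region.units]
    else:
        unit_strings = list(region)
    if len(unit_strings) < 2:
        raise ValueError("Psim requires >=2 repeat units")
    max_len = max(len(u) for u in unit_strings)
    matches = 0
    total = 0
    for col in range(max_len):
        cons = _column_consensus(unit_strings, col)
        for s in unit_strings:
            if col < len(s):
                total += 1
                if s[col] == cons:
                    matches += 1
    return matches / total


def count_duf_like_domains(region: RepeatRegion, nterm_len: int | None = None
                           ) -> tuple[int, int]:
    """Proxy count of DUF2775-like domains.

    The diagnostic ST domain spans roughly 20 residues of the
    non-repeating area plus 2 tandem repeats and 1 truncated repeat.
    Here a complete domain is a non-overlapping window of 3 consecutive
    units (at least 2 canonical) scanned from the N-terminus; 1-2
    trailing units yield one truncated domain. This is an explicit
    proxy, not a CDD/BLAST reproduction. ``nterm_len`` is accepted for
    interface symmetry but does not enter the window arithmetic.
    """
    units = region.units
    complete = 0
    for w in range(0, len(units) - 2, 3):
        window = units[w:w + 3]
        if sum(1 for u in window if u.status == "canonical") >= 2:
            complete += 1
    truncated = 1 if len(units) % 3 in (1, 2) else 0
    return complete, truncated
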