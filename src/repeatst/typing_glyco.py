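"""N-glycosylation sequons and the ST type I / IIa / IIb / III scheme.

The four partially conserved residues between the repeat hexapeptide
and the conserved Tyr (X4, repeat positions 7-10) determine whether a
repeat carries an N-glycosylation sequon and sort the family into
types: SxTx (type I, no sequon), NxSx (type IIa, a sequon in nearly
every repeat), Nx[FL]x (type IIb, no sequon) and DxT/Sx (type III, no
sequon). Proteins are typed by majority vote over their canonical
repeats; within a species the unique type-I member is named ST1 and
the rest ST2 onward.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .motif_repeats import RepeatRegion, RepeatUnit

ST_TYPES = ("I", "IIa", "IIb", "III")


@dataclass
class GlycoSite:
    """One PROSITE PS00001 match: N-{P}-[ST], following residue not P."""

    position: int           # 1-based position of the Asn
    sequon: str             # the three sequon residues
    within_repeat: Optional[int] = None   # repeat unit index, if inside one


@dataclass
class TypeCall:
    st_type: str                                  # I, IIa, IIb, III, mixed, other
    per_repeat_patterns: list = field(default_factory=list)  # (x4, category)
    majority_fraction: float = 0.0
    mixture: Optional[list] = None                # components sorted by share


def nglyc_sites(residues: str, region: RepeatRegion | None = None
                ) -> list[GlycoSite]:
    """All matches of N-{P}-[ST]-{P}; overlapping matches all reported."""
    residues = residues.upper()
    sites = []
    for i in range(len(residues) - 2):
        if (residues[i] == "N" and residues[i + 1] != "P"
                and residues[i + 2] in "ST"
                and (i + 3 >= len(residues) or residues[i + 3] != "P")):
            within = None
            if region is not None:
                for u in region.units:
                    if u.start <= i < u.end:
                        within = u.index
                        break
            sites.append(GlycoSite(position=i + 1, sequon=residues[i:i + 3],
                                   within_repeat=within))
    return sites


def x4_category(unit: RepeatUnit | str) -> str:
    """Type category of one repeat from its X4 (repeat positions 7-10).

    Position 7 carries the main signal (S / N / D,T); position 9
    separates IIa (S,T -> sequon present) from IIb (F,L -> no sequon).
    """
    residues = unit.residues if isinstance(unit, RepeatUnit) else str(unit)
    if len(residues) < 11:
        raise ValueError("repeat shorter than 11 residues has no complete X4")
    p7, p9 = residues[6], residues[8]
    if p7 == "S":
        return "I"
    if p7 == "N":
        if p9 in "ST":
            return "IIa"
        if p9 in "FL":
            return "IIb"
        return "other"
    if p7 in "DT":
        return "III"
    return "other"


def classify_protein(region: RepeatRegion) -> TypeCall:
    """Majority vote over canonical repeats (truncated units excluded).

    A strict majority (> 0.5) fixes the type; otherwise the call is
    ``mixed`` with components sorted by share.
    """
    canonical = region.canonical_units()
    if not canonical:
        raise ValueError("no canonical repeats to classify")
    patterns = [(u.x4, x4_category(u)) for u in canonical]
    counts: dict[str, int] = {}
    for _, cat in patterns:
        counts[cat] = counts.get(cat, 0) + 1
    total = len(patterns)
    order = {t: i for i, t in enumerate((*ST_TYPES, "other"))}
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], order.get(kv[0], 9)))
    top_cat, top_n = ranked[0]
    frac = top_n / total
    if frac > 0.5:
        return TypeCall(st_type=top_cat, per_repeat_patterns=patterns,
                        majority_fraction=frac)
    return TypeCall(st_type="mixed", per_repeat_patterns=patterns,
                    majority_fraction=frac,
                    mixture=[cat for cat, _ in ranked])


def assign_family_names(calls: Sequence[tuple[str, TypeCall]], species_code: str
                        ) -> dict[str, str]:
    """Family naming within one species: the unique type-I sequence gets
    suffix 1; all others are numbered from 2 in input order. Two type-I
    sequences trigger a warning; the first keeps the name.
    """
    type1_ids = [sid for sid, call in calls if call.st_type == "I"]
    if len(type1_ids) > 1:
        warnings.warn(f"{species_code}: {len(type1_ids)} type-I sequences; "
                      f"keeping {type1_ids[0]} as {species_code}ST1")
    mapping: dict[str, str] = {}
    next_n = 2
    for sid, call in calls:
        if type1_ids and sid == type1_ids[0]:
            mapping[sid] = f"{species_code}ST1"
        else:
            mapping[sid] = f"{species_code}ST{next_n}"
            next_n += 1
    return mapping
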