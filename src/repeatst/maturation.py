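"""Signal peptide delineation, mature N-terminal features, completeness.

ST precursors carry a 19-28 residue signal peptide; the mature protein
starts with Arg (nearly without exception in the family), shows a
Tyr-Trp dyad at mature positions 7-8 (offset to 8-9 in a few members),
and holds the single Cys of the mature sequence before the first
repeat. These landmarks, together with the C-terminal convention that
complete proteins end with Tyr followed by two or three residues,
drive the completeness classification of EST-derived fragments.

The cleavage-site heuristic is a deliberate rule-based stand-in for
probabilistic signal-peptide predictors: candidate cleavage points
19-28 are screened for a hydrophobic core (Kyte-Doolittle mean > 1.0
over positions 6..cleavage-4) and an Arg as the first mature residue.
Externally determined cleavage sites can be supplied and are used
verbatim.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Optional

from .composition import KYTE_DOOLITTLE
from .motif_repeats import RepeatRegion

SIGNAL_MIN = 19
SIGNAL_MAX = 28
HYDROPHOBIC_CORE_THRESHOLD = 1.0


@dataclass
class MatureModel:
    """Signal-peptide cleavage and conserved mature N-terminal features.

    Positions are 1-based in mature-protein coordinates; distances are
    differences of 1-based positions.
    """

    cleavage_after: int
    mature_start_residue: str
    low_confidence: bool = False
    nterm_len: Optional[int] = None
    yw_position: Optional[int] = None
    yw_offset_flag: bool = False
    cys_position: Optional[int] = None
    dist_yw_to_cys: Optional[int] = None
    dist_cys_to_repeat1: Optional[int] = None


@dataclass
class NucleotideContext:
    """Evidence from the source nucleotide sequence, when available."""

    stop_before_first_met: bool = False
    terminal_stop: bool = False
    frameshift_detected: bool = False


@dataclass
class CompletenessCall:
    value: Literal["full", "n_complete", "c_complete", "internal"]
    evidence: list[str] = field(default_factory=list)


def _core_hydropathy(residues: str, cleavage: int) -> float | None:
    """Mean Kyte-Doolittle hydropathy over positions 6..cleavage-4 (1-based)."""
    window = residues[5:cleavage - 4]
    if not window:
        return None
    vals = [KYTE_DOOLITTLE[r] for r in window if r in KYTE_DOOLITTLE]
    return sum(vals) / len(vals) if vals else None


def predict_mature_start(residues: str, supplied_cleavage: int | None = None
                         ) -> MatureModel | None:
    """Locate the signal-peptide cleavage point.

    A supplied cleavage site is used verbatim. Otherwise the first
    candidate in 19..28 whose next residue is Arg and whose core window
    passes the hydropathy threshold wins; failing that, the
    highest-hydropathy passing candidate is returned flagged low
    confidence; with no passing candidate the result is None with a
    warning (typical of mature-only fragments).
    """
    residues = residues.upper()
    if len(residues) < 40:
        raise ValueError("sequence shorter than 40 residues: cannot model maturation")
    if supplied_cleavage is not None:
        return MatureModel(cleavage_after=supplied_cleavage,
                           mature_start_residue=residues[supplied_cleavage])

    viable: list[tuple[int, float]] = []
    for c in range(SIGNAL_MIN, SIGNAL_MAX + 1):
        if c >= len(residues):
            break
        h = _core_hydropathy(residues, c)
        if h is not None and h > HYDROPHOBIC_CORE_THRESHOLD:
            viable.append((c, h))
    for c, _ in viable:
        if residues[c] == "R":
            return MatureModel(cleavage_after=c, mature_start_residue="R")
    if viable:
        c = max(viable, key=lambda t: t[1])[0]
        return MatureModel(cleavage_after=c, mature_start_residue=residues[c],
                           low_confidence=True)
    warnings.warn("no candidate signal-peptide window passes the hydropathy "
                  "threshold; sequence treated as lacking a signal peptide")
    return None


def nterm_features(mature_residues: str, first_anchor: int,
                   model: MatureModel | None = None) -> MatureModel:
    """Extract the conserved mature N-terminal landmarks.

    ``first_anchor`` is the 0-based start of the first repeat in mature
    coordinates. The Tyr-Trp dyad is scanned at mature positions 7-9
    (admitting the one-residue offset seen in a minority of family
    members); the single Cys expected before the repeats is recorded
    when present; absent features stay None.
    """
    mature_residues = mature_residues.upper()
    if first_anchor < 2:
        raise ValueError("first repeat anchor too close to the mature start")
    if model is None:
        model = MatureModel(cleavage_after=0, mature_start_residue=mature_residues[0])
    model.nterm_len = first_anchor

    for p in (6, 7, 8):  # 0-based candidates for mature positions 7-9
        if p + 1 < first_anchor and mature_residues[p:p + 2] == "YW":
            model.yw_position = p + 1
            model.yw_offset_flag = p != 6
            break

    cys_idx = mature_residues.find("C", 0, first_anchor)
    if cys_idx != -1:
        model.cys_position = cys_idx + 1

    if model.yw_position is not None and model.cys_position is not None:
        model.dist_yw_to_cys = model.cys_position - model.yw_position
    if model.cys_position is not None:
        model.dist_cys_to_repeat1 = (first_anchor + 1) - model.cys_position
    return model


def _ends_with_tyr_tail(residues: str) -> bool:
    """C-terminal rule: Tyr followed by two or three residues."""
    return len(residues) >= 4 and (residues[-3] == "Y" or residues[-4] == "Y")


def classify_completeness(residues: str,
                          repeat_region: RepeatRegion | None,
                          mature_model: MatureModel | None,
                          nucleotide_context: NucleotideContext | None = None
                          ) -> CompletenessCall:
    """Classify a sequence as full / N-complete / C-complete / internal.

    N-completeness: an in-frame stop before the first Met (nucleotide
    mode) or a detected signal peptide together with the Tyr-Trp dyad.
    C-completeness: a terminal stop codon without frameshift, or the
    Tyr-plus-2-3-residue ending. Full requires both; internal, neither.
    """
    residues = residues.upper()
    evidence: list[str] = []

    n_ok = False
    if nucleotide_context is not None and nucleotide_context.stop_before_first_met:
        n_ok = True
        evidence.append("stop codon before first Met")
    if mature_model is not None and mature_model.yw_position is not None:
        n_ok = True
        evidence.append("signal peptide and Tyr-Trp dyad")

    c_ok = False
    if (nucleotide_context is not None and nucleotide_context.terminal_stop
            and not nucleotide_context.frameshift_detected):
        c_ok = True
        evidence.append("terminal stop codon without frameshift")
    if _ends_with_tyr_tail(residues):
        c_ok = True
        evidence.append("ends with Tyr followed by 2-3 residues")

    if n_ok and c_ok:
        value = "full"
    elif n_ok:
        value = "n_complete"
    elif c_ok:
        value = "c_complete"
    else:
        value = "internal"
    return CompletenessCall(value=value, evidence=evidence)
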