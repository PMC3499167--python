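"""Sequence-level descriptive statistics.

Composition classes (the family literature counts DEKRHYC as the
charged set), average-mass molecular weight, isoelectric point by
Henderson-Hasselbalch bisection on the EMBOSS pKa set, and
Kyte-Doolittle hydropathy profiles. ST mature proteins are expected to
be hydrophilic (GRAVY < 0) with an acidic pI and a charged fraction of
roughly 30-49%.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

# Kyte & Doolittle hydropathy scale
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

# Average residue masses (Da); peptide MW = sum + one water
AVERAGE_RESIDUE_MASS = {
    "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886,
    "C": 103.1388, "E": 129.1155, "Q": 128.1307, "G": 57.0519,
    "H": 137.1411, "I": 113.1594, "L": 113.1594, "K": 128.1741,
    "M": 131.1926, "F": 147.1766, "P": 97.1167, "S": 87.0782,
    "T": 101.1051, "W": 186.2132, "Y": 163.1760, "V": 99.1326,
}
WATER_MASS = 18.01528

# EMBOSS ionizable-group pKa values
PKA = {
    "nterm": 8.6, "cterm": 3.6,
    "C": 8.5, "D": 3.9, "E": 4.1, "Y": 10.1,   # acidic side chains
    "H": 6.5, "K": 10.8, "R": 12.5,            # basic side chains
}
_ACIDIC_SIDE = "CDEY"
_BASIC_SIDE = "HKR"

CHARGED_SET = set("DEKRHYC")
ACIDIC_SET = set("DE")
BASIC_SET = set("KRH")


@dataclass
class CompositionReport:
    length: int
    mw_da: float
    pi: float
    frac_charged: float
    frac_acidic: float
    frac_basic: float
    residue_fractions: dict = field(default_factory=dict)
    gravy: Optional[float] = None
    hydropathy_profile: Optional[list] = None


def molecular_weight(residues: str) -> float:
    """Average-mass MW in daltons; unknown residues (X) are skipped."""
    masses = [AVERAGE_RESIDUE_MASS[r] for r in residues if r in AVERAGE_RESIDUE_MASS]
    if not masses:
        raise ValueError("no defined residues for molecular weight")
    return sum(masses) + WATER_MASS


def net_charge(residues: str, ph: float) -> float:
    """Net charge at a given pH (Henderson-Hasselbalch per group)."""
    q = 1.0 / (1.0 + 10 ** (ph - PKA["nterm"]))
    q -= 1.0 / (1.0 + 10 ** (PKA["cterm"] - ph))
    for r in residues:
        if r in _BASIC_SIDE:
            q += 1.0 / (1.0 + 10 ** (ph - PKA[r]))
        elif r in _ACIDIC_SIDE:
            q -= 1.0 / (1.0 + 10 ** (PKA[r] - ph))
    return q


def isoelectric_point(residues: str, tol: float = 1e-4) -> float:
    """pH where the net charge vanishes, by bisection on [0, 14].

    Q(pH) is strictly decreasing, so the root is unique; iteration
    stops when |Q| < tol.
    """
    residues = residues.upper()
    lo, hi = 0.0, 14.0
    ph = 7.0
    for _ in range(80):
        ph = (lo + hi) / 2.0
        q = net_charge(residues, ph)
        if abs(q) < tol and hi - lo < 1e-9:
            break
        if q > 0:
            lo = ph
        else:
            hi = ph
    return ph


def hydropathy_profile(residues: str, window: int = 9
                       ) -> tuple[list[float], float]:
    """Centered sliding Kyte-Doolittle mean and the grand mean (GRAVY).

    The window must be odd and no longer than the sequence; undefined
    residues (X) are excluded from each window mean.
    """
    residues = residues.upper()
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if window > len(residues):
        raise ValueError("window longer than sequence")
    vals = [KYTE_DOOLITTLE.get(r) for r in residues]
    profile = []
    for i in range(len(residues) - window + 1):
        seen = [v for v in vals[i:i + window] if v is not None]
        profile.append(sum(seen) / len(seen) if seen else 0.0)
    defined = [v for v in vals if v is not None]
    gravy = sum(defined) / len(defined) if defined else 0.0
    return profile, gravy


def composition_report(mature_residues: str, window: int = 9) -> CompositionReport:
    """Full descriptive report for one (typically mature) sequence.

    Class fractions use only defined residues as the denominator; the
    charged set is exactly {D,E,K,R,H,Y,C}.
    """
    residues = mature_residues.upper()
    if not residues:
        raise ValueError("empty sequence")
    defined = [r for r in residues if r in AVERAGE_RESIDUE_MASS]
    n = len(defined)
    if n == 0:
        raise ValueError("no defined residues")
    frac = {r: defined.count(r) / n for r in sorted(set(defined))}
    profile, gravy = (None, None)
    if len(residues) >= window:
        profile, gravy = hydropathy_profile(residues, window)
    else:
        _, gravy = hydropathy_profile(residues, window=1)
    return CompositionReport(
        length=len(residues),
        mw_da=molecular_weight(residues),
        pi=isoelectric_point(residues),
        frac_charged=sum(1 for r in defined if r in CHARGED_SET) / n,
        frac_acidic=sum(1 for r in defined if r in ACIDIC_SET) / n,
        frac_basic=sum(1 for r in defined if r in BASIC_SET) / n,
        residue_fractions=frac,
        gravy=gravy,
        hydropathy_profile=profile,
    )
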