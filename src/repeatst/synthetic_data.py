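"""Ground-truthed synthetic ST precursors, fragments, families, decoys.

The generator emulates the family architecture the annotator assumes:
a 19-28 residue signal peptide (Met + hydrophobic core + an A-S-A
cleavage boundary), a hydrophilic mature N-terminal region starting
Arg-Lys with a Tyr-Trp dyad at mature positions 7-8 and a single Cys
before the repeats, a block of tandem repeats of 22-27 residues each
opening with the (D/E)FEPRP-X4-Y motif with a type-conditioned X4 and
a consensus-shaped tail (D/N-rich spacer, then K.KK.F.K), and a final
truncated repeat (13 residues by default). Each emitted record carries
a ground-truth sidecar; at substitution rate zero, re-annotating a
record reproduces the truth exactly.

Decoy generators emulate the cell-wall protein families used as
negative controls (PRP, HRGP, GRP, AGP motif grammars, plus
composition-preserving shuffles of real ST output); all are
rejection-resampled so they never contain the ST signature. Hyp in
HRGP/AGP motifs is written as P (plain amino-acid alphabet).

All sequences and truths produced here are synthetic: they are
stand-ins constructed for testing, not curated database material.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np

from .motif_repeats import scan_motif, segment_repeats
from .seqio import SequenceRecord

ST_TYPES = ("I", "IIa", "IIb", "III", "mixed")
FRAGMENT_MODES = ("full", "n_only", "c_only", "internal")

_SP_CORE = "ALVIF"                  # hydrophobic signal-peptide core
_FILLER = "ADEGKNQSTVHP"            # hydrophilic; no F/C/W/Y/M/R by design
_MID_POOL = "DDDNNNKESTAG"          # D/N-rich spacer between Tyr and K-block
_TAIL_X = "AVSDNET"                 # variable slots of the K.KK.F.K block
_SUBSTITUTION_POOL = "ADEFGHIKLMNPQRSTVY"   # no C/W outside designated spots

_X4_X = {"I": "KVAG", "IIa": "IVA", "IIb": "FSAL", "III": "KVA"}


def _choice(rng: np.random.Generator, pool: str) -> str:
    return pool[int(rng.integers(len(pool)))]


def _draw(rng: np.random.Generator, pool: str, n: int) -> str:
    return "".join(_choice(rng, pool) for _ in range(n))


@dataclass
class GeneratorConfig:
    """Study-condition parameters of one synthetic ST precursor."""

    seed: int = 0
    sp_len: int = 22
    nterm_len: int = 55
    n_repeats: int = 6
    repeat_len: int = 25
    st_type: str = "IIa"
    truncated_len: int = 13
    substitution_rate: float = 0.0
    protect_anchor: bool = True
    fragment_mode: str = "full"
    hexamer_first: str = "D"

    def __post_init__(self) -> None:
        if not 19 <= self.sp_len <= 28:
            raise ValueError("sp_len must be in [19, 28]")
        if not 30 <= self.nterm_len <= 114:
            raise ValueError("nterm_len must be in [30, 114]")
        if not 2 <= self.n_repeats <= 17:
            raise ValueError("n_repeats must be in [2, 17]")
        if not 22 <= self.repeat_len <= 27:
            raise ValueError("repeat_len must be in [22, 27]")
        if not 12 <= self.truncated_len < self.repeat_len:
            raise ValueError("truncated_len must be in [12, repeat_len)")
        if self.st_type not in ST_TYPES:
            raise ValueError(f"st_type must be one of {ST_TYPES}")
        if self.fragment_mode not in FRAGMENT_MODES:
            raise ValueError(f"fragment_mode must be one of {FRAGMENT_MODES}")
        if self.hexamer_first not in "DE":
            raise ValueError("hexamer_first must be D or E")
        if not 0.0 <= self.substitution_rate < 1.0:
            raise ValueError("substitution_rate must be in [0, 1)")


@dataclass
class GroundTruth:
    """Construction-time truth for one emitted record (emitted coords)."""

    seq_id: str
    st_type: str
    completeness: str
    unit_spans: list            # (start, end, status), 0-based half-open
    x4_strings: list
    per_unit_types: list
    cleavage_after: Optional[int] = None    # signal-peptide length
    yw_position: Optional[int] = None       # mature 1-based
    cys_position: Optional[int] = None      # mature 1-based
    clade: Optional[str] = None
    seed: Optional[int] = None


def _draw_x4(rng: np.random.Generator, st_type: str) -> str:
    x = _X4_X[st_type]
    if st_type == "I":
        return "S" + _choice(rng, x) + "T" + _choice(rng, x)
    if st_type == "IIa":
        return "N" + _choice(rng, x) + "S" + _choice(rng, x)
    if st_type == "IIb":
        return "N" + _choice(rng, x) + _choice(rng, "FL") + _choice(rng, x)
    return _choice(rng, "DT") + _choice(rng, x) + _choice(rng, "TS") + _choice(rng, x)


def _unit_prototype(rng: np.random.Generator, cfg: GeneratorConfig) -> str:
    """One repeat unit shaped like the family consensus
    (D/E)FEPRP-X4-Y-X(6-7)-K.KK.F.K, sized to repeat_len."""
    hexamer = cfg.hexamer_first + "FEPRP"
    head = hexamer + "XXXX" + "Y"          # X4 filled per unit
    mid_len = max(0, cfg.repeat_len - len(head) - 8)
    mid = _draw(rng, _MID_POOL, mid_len)
    tail = ("K" + _choice(rng, _TAIL_X) + "KK" + _choice(rng, _TAIL_X)
            + "F" + _choice(rng, _TAIL_X) + "K")
    unit = head + mid + tail
    return unit[:cfg.repeat_len]


def _unit_types(cfg: GeneratorConfig) -> list[str]:
    if cfg.st_type != "mixed":
        return [cfg.st_type] * cfg.n_repeats
    # mixtures alternate the two most common co-occurring patterns
    return ["IIa" if k % 2 == 0 else "III" for k in range(cfg.n_repeats)]


def _build_unit(rng: np.random.Generator, proto: str, unit_type: str,
                cfg: GeneratorConfig) -> str:
    unit = list(proto)
    unit[6:10] = _draw_x4(rng, unit_type)
    # small within-protein divergence: one non-anchor position redrawn
    eligible = [i for i in range(11, len(unit))
                if i not in (11 + 0,) and unit[i] not in "KF"]
    if eligible:
        i = eligible[int(rng.integers(len(eligible)))]
        unit[i] = _choice(rng, _MID_POOL)
    return "".join(unit)


def _apply_noise(rng: np.random.Generator, residues: str,
                 protected: set[int], rate: float) -> str:
    if rate <= 0:
        return residues
    out = list(residues)
    for i in range(len(out)):
        if i in protected:
            continue
        if rng.random() < rate:
            pool = _SUBSTITUTION_POOL.replace(out[i], "")
            out[i] = _choice(rng, pool)
    return "".join(out)


def _avoid_tyr_tail(residues: str, cut: int) -> int:
    """Move a cut point left until the prefix does not end Tyr+2-3
    residues (which would mimic a complete C-terminus)."""
    while cut >= 4 and (residues[cut - 3] == "Y" or residues[cut - 4] == "Y"):
        cut -= 1
    return cut


def generate_st(config: GeneratorConfig, seq_id: str | None = None
                ) -> tuple[SequenceRecord, GroundTruth]:
    """Generate one ST-like record plus its ground truth.

    Deterministic given the config seed. The full precursor satisfies
    sp_len + nterm_len + (n_repeats-1)*repeat_len + truncated_len ==
    sequence length; fragment modes then trim the precursor so the
    emitted record carries exactly the completeness evidence of its
    class (N-only fragments never end Tyr+2-3; C-only/internal
    fragments start in the hydrophilic region, after the Tyr-Trp dyad).
    """
    rng = np.random.default_rng(config.seed)
    sp = "M" + _draw(rng, _SP_CORE, config.sp_len - 4) + "ASA"

    cys_idx = config.nterm_len - 14          # 0-based in mature coords
    nterm = ["R", "K"] + list(_draw(rng, _FILLER, 4)) + ["Y", "W"]
    nterm += list(_draw(rng, _FILLER, cys_idx - len(nterm)))
    nterm += ["C"] + list(_draw(rng, _FILLER, config.nterm_len - cys_idx - 1))
    nterm = "".join(nterm)

    proto = _unit_prototype(rng, config)
    unit_types = _unit_types(config)
    units = [_build_unit(rng, proto, t, config) for t in unit_types]
    units[-1] = units[-1][:config.truncated_len]

    precursor = sp + nterm + "".join(units)
    anchors = []
    pos = config.sp_len + config.nterm_len
    for u in units:
        anchors.append(pos)
        pos += len(u)

    protected: set[int] = set()
    if config.protect_anchor:
        for a in anchors:
            protected.update(range(a, a + 6))
            protected.add(a + 10)
    precursor = _apply_noise(rng, precursor, protected, config.substitution_rate)

    # fragment trimming
    start, end = 0, len(precursor)
    if config.fragment_mode in ("n_only", "internal"):
        end = _avoid_tyr_tail(precursor, anchors[-1] - 5)
    if config.fragment_mode in ("c_only", "internal"):
        start = config.sp_len + 10
    emitted = precursor[start:end]
    kept_anchors = [a - start for a in anchors
                    if a >= start and a - start + 11 <= len(emitted)]
    region = segment_repeats(emitted, kept_anchors)

    completeness = {"full": "full", "n_only": "n_complete",
                    "c_only": "c_complete", "internal": "internal"}[config.fragment_mode]
    has_nterm = config.fragment_mode in ("full", "n_only")
    kept_units = region.units
    truth = GroundTruth(
        seq_id=seq_id or f"SynST{config.seed}",
        st_type=config.st_type,
        completeness=completeness,
        unit_spans=[(u.start, u.end, u.status) for u in kept_units],
        x4_strings=[u.x4 for u in kept_units if u.length >= 11],
        per_unit_types=unit_types[:len(kept_units)],
        cleavage_after=config.sp_len if has_nterm else None,
        yw_position=7 if has_nterm else None,
        cys_position=cys_idx + 1 if has_nterm else None,
        seed=config.seed,
    )
    record = SequenceRecord(
        id=truth.seq_id,
        residues=emitted,
        description=(f"synthetic ST type={config.st_type} seed={config.seed} "
                     f"fragment={config.fragment_mode}"),
    )
    return record, truth


# ---------------------------------------------------------------------------
# decoys

_PRP_MOTIFS = ["PPVYK", "PPVEK", "PPVTK", "PPHEK", "PPYV", "PPTPRPS",
               "PPV", "PIYK", "KKPCPP", "PEPK", "PKPE", "PVPPK", "PEPPK"]
_HRGP_MOTIFS = ["SPPPP", "SPPPPSP", "SPPPPVYK", "SPPPPKHEY"]
_AGP_MOTIFS = ["AP", "SP", "TP"]

DECOY_KINDS = ("prp", "hrgp", "grp", "agp", "shuffled_st")


def generate_decoy(kind: str, seed: int) -> SequenceRecord:
    """A non-ST cell-wall-like decoy; guaranteed to lack the signature."""
    if kind not in DECOY_KINDS:
        raise ValueError(f"unknown decoy kind {kind!r}")
    rng = np.random.default_rng(seed)
    for _ in range(50):   # rejection resampling; first draw virtually always passes
        if kind == "prp":
            seq = "".join(_PRP_MOTIFS[int(rng.integers(len(_PRP_MOTIFS)))]
                          for _ in range(40))
        elif kind == "hrgp":
            seq = "".join(_HRGP_MOTIFS[int(rng.integers(len(_HRGP_MOTIFS)))]
                          for _ in range(35))
        elif kind == "grp":
            seq = "".join("G" + _choice(rng, "GASERYFH") for _ in range(90))
        elif kind == "agp":
            seq = "".join(_AGP_MOTIFS[int(rng.integers(len(_AGP_MOTIFS)))]
                          for _ in range(90))
        else:  # shuffled_st: composition-preserving shuffle of a real ST
            src, _ = generate_st(GeneratorConfig(seed=seed))
            letters = list(src.residues)
            rng.shuffle(letters)
            seq = "".join(letters)
        if not scan_motif(seq):
            return SequenceRecord(
                id=f"DECOY_{kind.upper()}_{seed}",
                residues=seq,
                description=f"synthetic {kind} decoy seed={seed}",
            )
    raise RuntimeError(f"could not build a signature-free {kind} decoy")  # pragma: no cover


# ---------------------------------------------------------------------------
# families and the reference cohort

def _species_code(i: int) -> str:
    return (chr(ord("A") + i // 26 % 26)
            + chr(ord("a") + i * 7 % 26)
            + chr(ord("a") + i * 13 % 26))


def generate_family(n_species: int, sequences_per_species: int,
                    clade_templates: Sequence[GeneratorConfig], seed: int,
                    within_noise: float = 0.02
                    ) -> tuple[list[SequenceRecord], list[GroundTruth]]:
    """Clade-structured family dataset.

    Each species derives from one clade template (round-robin); all
    members of a clade are small perturbations (``within_noise``
    substitutions away from the clade prototype, anchors and N-terminal
    landmarks protected), so between-clade divergence dominates and
    trees should group leaves by template.
    """
    if len(clade_templates) < 2:
        raise ValueError("need >=2 clade templates")
    master = np.random.default_rng(seed)
    prototypes = []
    for t_idx, template in enumerate(clade_templates):
        proto_cfg = replace(template, seed=int(master.integers(2 ** 31)))
        prototypes.append(generate_st(proto_cfg))

    records, truths = [], []
    for s in range(n_species):
        code = _species_code(s)
        t_idx = s % len(clade_templates)
        proto_rec, proto_truth = prototypes[t_idx]
        cfg = clade_templates[t_idx]
        protected: set[int] = {0, cfg.sp_len, cfg.sp_len + 6, cfg.sp_len + 7,
                               cfg.sp_len + cfg.nterm_len - 14}
        for a, _, _ in [(sp[0], sp[1], sp[2]) for sp in proto_truth.unit_spans]:
            protected.update(range(a, a + 6))
            protected.add(a + 10)
        for j in range(sequences_per_species):
            rng = np.random.default_rng(int(master.integers(2 ** 31)))
            seq = _apply_noise(rng, proto_rec.residues, protected, within_noise)
            sid = f"{code}_{j + 1}"
            records.append(SequenceRecord(
                id=sid, residues=seq,
                description=f"synthetic family member clade={t_idx} species={code}"))
            truth = replace(proto_truth, seq_id=sid, clade=f"clade{t_idx}")
            truths.append(truth)
    return records, truths


def generate_reference_cohort(seed: int
                              ) -> tuple[list[SequenceRecord], list[GroundTruth]]:
    """Synthetic stand-in for the curated 136-member family census.

    The census is fixed to the study population the family literature
    reports: 136 sequences of which 72 are full-length (including one
    103-residue and one 493-residue member, repeat counts spanning 2 to
    17), 38 N-complete, 7 C-complete and 19 internal fragments; type
    mix 29 I / 75 IIa / 3 IIb / 18 III / 11 mixed. This is a synthetic
    reconstruction for pipeline-recovery testing, not curated data.
    """
    rng = np.random.default_rng(seed)

    def child_seed() -> int:
        return int(rng.integers(2 ** 31))

    def draw_rl() -> int:
        pool = [25] * 10 + [26] * 7 + [22, 23, 24, 27]
        return pool[int(rng.integers(len(pool)))]

    def clamp_nterm(sp: int, nt: int, n: int, rl: int, lo: int, hi: int) -> int:
        total = sp + nt + (n - 1) * rl + 13
        nt = nt + max(0, lo - total) - max(0, total - hi)
        return int(min(114, max(30, nt)))

    # (fragment_mode, n_repeats, length bounds) plans
    plans: list[tuple[str, int, tuple[int, int] | None]] = []
    full_ns = ([2] * 10 + [3] * 15 + [4] * 9 + [5] * 8 + [6] * 7 + [7] * 6
               + [9] * 4 + [10] * 3 + [11] * 3 + [12] * 2 + [13] * 2 + [14])
    for n in full_ns:
        if n <= 3:
            plans.append(("full", n, (104, 149)))
        elif n <= 7:
            plans.append(("full", n, (150, 250)))
        else:
            plans.append(("full", n, (251, 492)))
    plans += [("n_only", 4 + i % 9, None) for i in range(38)]
    plans += [("c_only", 4 + i % 9, None) for i in range(7)]
    plans += [("internal", 4 + i % 9, None) for i in range(19)]

    types = (["IIa"] * 73 + ["I"] * 29 + ["IIb"] * 3 + ["III"] * 18 + ["mixed"] * 11)
    order = rng.permutation(len(types))
    type_list = [types[i] for i in order]

    configs: list[GeneratorConfig] = [
        # pinned extremes of the full-length size range (both type IIa)
        GeneratorConfig(seed=child_seed(), sp_len=20, nterm_len=45, n_repeats=2,
                        repeat_len=25, st_type="IIa"),
        GeneratorConfig(seed=child_seed(), sp_len=22, nterm_len=58, n_repeats=17,
                        repeat_len=25, st_type="IIa"),
    ]
    for (mode, n, bounds), st_type in zip(plans, type_list):
        # mixture calls need an even number of voting canonical units
        if st_type == "mixed":
            voting = n - 1 if mode in ("full", "c_only") else n - 2
            if voting % 2:
                n += 1
        sp = int(rng.integers(19, 29))
        rl = draw_rl()
        nt = int(rng.integers(30, 81))
        if bounds is not None:
            nt = clamp_nterm(sp, nt, n, rl, *bounds)
        configs.append(GeneratorConfig(seed=child_seed(), sp_len=sp, nterm_len=nt,
                                       n_repeats=n, repeat_len=rl, st_type=st_type,
                                       fragment_mode=mode))

    records, truths = [], []
    for i, cfg in enumerate(configs):
        rec, truth = generate_st(cfg, seq_id=f"SynFam{i:03d}")
        records.append(rec)
        truths.append(truth)
    return records, truths
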