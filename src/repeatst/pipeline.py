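"""Annotate -> classify -> summarize over a FASTA dataset.

Per sequence: signature check, repeat segmentation, maturation
modelling, type and glycosylation calls, composition and repeat
perfection; sequences without the signature are reported as rejected
with a reason. Dataset-level summary statistics mirror the family
survey: completeness census, full-length size range and size classes,
repeat-count range, repeat-length histogram, type fractions, Psim
threshold fractions and the charged-fraction range. The pipeline is a
pure function of its input bytes and options.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path
from statistics import median
from typing import Optional, Sequence

from . import composition as comp
from . import maturation, motif_repeats, typing_glyco
from .seqio import FeatureRow, SequenceRecord, read_fasta


@dataclass
class StAnnotation:
    """Full per-protein annotation result."""

    seq_id: str
    length: int
    accepted: bool
    reject_reason: Optional[str] = None
    anchors: list = field(default_factory=list)
    region: Optional[motif_repeats.RepeatRegion] = None
    mature: Optional[maturation.MatureModel] = None
    type_call: Optional[typing_glyco.TypeCall] = None
    glyco_sites: list = field(default_factory=list)
    completeness: Optional[maturation.CompletenessCall] = None
    composition: Optional[comp.CompositionReport] = None
    psim: Optional[float] = None
    duf_like: tuple = (0, 0)


@dataclass
class DatasetSummary:
    n_input: int = 0
    n_accepted: int = 0
    n_rejected: int = 0
    completeness_counts: dict = field(default_factory=dict)
    full_length_min: Optional[int] = None
    full_length_median: Optional[float] = None
    full_length_max: Optional[int] = None
    length_class_fractions: dict = field(default_factory=dict)   # <150 / 150-250 / >250
    repeat_count_min: Optional[int] = None
    repeat_count_max: Optional[int] = None
    repeat_length_histogram: dict = field(default_factory=dict)
    type_fractions: dict = field(default_factory=dict)
    type_percent: dict = field(default_factory=dict)             # rounded half-up
    psim_fraction_gt: dict = field(default_factory=dict)         # 0.7 / 0.8 / 0.9
    charged_fraction_range: Optional[tuple] = None

    def to_dict(self) -> dict:
        d = dict(self.__dict__)
        if self.charged_fraction_range is not None:
            d["charged_fraction_range"] = list(self.charged_fraction_range)
        return d


def percent(x: float) -> int:
    """Round a fraction to a whole percentage, half-up."""
    value = Decimal(str(round(100 * x, 9)))
    return int(value.quantize(Decimal("1"), rounding=ROUND_HALF_UP))


def annotate_record(record: SequenceRecord, supplied_cleavage: int | None = None,
                    fuzzy_hexamer: bool = False) -> StAnnotation:
    """Annotate one protein; non-ST sequences come back rejected."""
    residues = record.residues
    ann = StAnnotation(seq_id=record.id, length=len(residues), accepted=False)

    anchors = motif_repeats.scan_motif(residues)
    if not anchors:
        ann.reject_reason = "no (D/E)FEPRP-X4-Y signature"
        return ann
    ann.accepted = True
    ann.anchors = anchors
    region = motif_repeats.segment_repeats(residues, anchors,
                                           fuzzy_leading=fuzzy_hexamer)
    ann.region = region
    ann.psim = region.psim

    mature_model = None
    if len(residues) >= 40:
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            mature_model = maturation.predict_mature_start(residues, supplied_cleavage)
    if mature_model is not None and region.start > mature_model.cleavage_after + 1:
        mature_seq = residues[mature_model.cleavage_after:]
        mature_anchor = region.start - mature_model.cleavage_after
        mature_model = maturation.nterm_features(mature_seq, mature_anchor, mature_model)
    ann.mature = mature_model

    if region.canonical_units():
        ann.type_call = typing_glyco.classify_protein(region)
    ann.glyco_sites = typing_glyco.nglyc_sites(residues, region)
    ann.completeness = maturation.classify_completeness(residues, region, mature_model)
    ann.duf_like = motif_repeats.count_duf_like_domains(region)

    mature_res = (residues[mature_model.cleavage_after:]
                  if mature_model is not None else residues)
    ann.composition = comp.composition_report(mature_res)
    return ann


def summarize(annotations: Sequence[StAnnotation]) -> DatasetSummary:
    s = DatasetSummary(n_input=len(annotations))
    accepted = [a for a in annotations if a.accepted]
    s.n_accepted = len(accepted)
    s.n_rejected = s.n_input - s.n_accepted
    if not accepted:
        return s

    s.completeness_counts = {k: 0 for k in ("full", "n_complete", "c_complete", "internal")}
    for a in accepted:
        s.completeness_counts[a.completeness.value] += 1

    full = [a for a in accepted if a.completeness.value == "full"]
    if full:
        lengths = [a.length for a in full]
        s.full_length_min = min(lengths)
        s.full_length_median = median(lengths)
        s.full_length_max = max(lengths)
        n = len(full)
        s.length_class_fractions = {
            "<150": sum(1 for L in lengths if L < 150) / n,
            "150-250": sum(1 for L in lengths if 150 <= L <= 250) / n,
            ">250": sum(1 for L in lengths if L > 250) / n,
        }
        counts = [len(a.region.units) for a in full]
        s.repeat_count_min = min(counts)
        s.repeat_count_max = max(counts)
        psims = [a.psim for a in full if a.psim is not None]
        if psims:
            s.psim_fraction_gt = {t: sum(1 for p in psims if p > t) / len(psims)
                                  for t in (0.7, 0.8, 0.9)}

    hist: dict[int, int] = {}
    for a in accepted:
        for u in a.region.canonical_units():
            hist[u.length] = hist.get(u.length, 0) + 1
    s.repeat_length_histogram = dict(sorted(hist.items()))

    typed = [a for a in accepted if a.type_call is not None]
    if typed:
        tf: dict[str, int] = {}
        for a in typed:
            tf[a.type_call.st_type] = tf.get(a.type_call.st_type, 0) + 1
        s.type_fractions = {k: v / len(typed) for k, v in sorted(tf.items())}
        s.type_percent = {k: percent(v) for k, v in s.type_fractions.items()}

    charged = [a.composition.frac_charged for a in accepted if a.composition]
    if charged:
        s.charged_fraction_range = (min(charged), max(charged))
    return s


def annotate_dataset(source, supplied_cleavages: dict | None = None,
                     fuzzy_hexamer: bool = False
                     ) -> tuple[list[StAnnotation], DatasetSummary]:
    """Annotate a FASTA path or a list of records; returns per-sequence
    annotations (accepted and rejected, exactly one entry each) plus
    the dataset summary over accepted sequences."""
    records = read_fasta(source) if isinstance(source, (str, Path)) else list(source)
    if not records:
        raise ValueError("empty input dataset")
    supplied_cleavages = supplied_cleavages or {}
    annotations = [
        annotate_record(rec, supplied_cleavages.get(rec.id), fuzzy_hexamer)
        for rec in records
    ]
    return annotations, summarize(annotations)


def to_feature_rows(ann: StAnnotation) -> list[FeatureRow]:
    """Flatten one annotation into 1-based inclusive feature rows."""
    rows: list[FeatureRow] = []
    if not ann.accepted:
        return rows
    if ann.mature is not None and ann.mature.cleavage_after > 0:
        rows.append(FeatureRow(ann.seq_id, "signal_peptide", 1,
                               ann.mature.cleavage_after))
        if ann.region.start > ann.mature.cleavage_after:
            rows.append(FeatureRow(ann.seq_id, "nterm_region",
                                   ann.mature.cleavage_after + 1, ann.region.start))
    for u in ann.region.units:
        kind = "truncated_repeat" if u.status == "truncated_terminal" else "repeat"
        rows.append(FeatureRow(ann.seq_id, kind, u.start + 1, u.end,
                               {"status": u.status, "x4": u.x4 if u.length >= 10 else ""}))
    for g in ann.glyco_sites:
        rows.append(FeatureRow(ann.seq_id, "glyco_site", g.position, g.position + 2,
                               {"sequon": g.sequon}))
    return rows


def _render_md(summary: DatasetSummary) -> str:
    lines = ["# Dataset summary", "",
             f"Sequences: {summary.n_input} "
             f"({summary.n_accepted} accepted, {summary.n_rejected} rejected)", ""]
    if summary.completeness_counts:
        lines += ["| completeness | count |", "| --- | --- |"]
        lines += [f"| {k} | {v} |" for k, v in summary.completeness_counts.items()]
        lines.append("")
    if summary.type_percent:
        lines += ["| ST type | percent |", "| --- | --- |"]
        lines += [f"| {k} | {v}% |" for k, v in summary.type_percent.items()]
        lines.append("")
    if summary.full_length_min is not None:
        lines.append(f"Full-length size range: {summary.full_length_min}"
                     f"-{summary.full_length_max} aa "
                     f"(median {summary.full_length_median})")
        lines.append(f"Repeat counts: {summary.repeat_count_min}"
                     f"-{summary.repeat_count_max}")
    return "\n".join(lines) + "\n"


def report(summary: DatasetSummary, path: str | Path, fmt: str = "json") -> None:
    """Write the summary as canonical JSON, TSV, or a markdown digest."""
    path = Path(path)
    if fmt == "json":
        path.write_text(json.dumps(summary.to_dict(), indent=2, default=str) + "\n")
    elif fmt == "tsv":
        d = summary.to_dict()
        lines = ["key\tvalue"] + [f"{k}\t{json.dumps(v, default=str)}" for k, v in d.items()]
        path.write_text("\n".join(lines) + "\n")
    elif fmt == "md":
        path.write_text(_render_md(summary))
    else:
        raise ValueError(f"unknown report format {fmt!r}")
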