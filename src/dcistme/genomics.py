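"""Copy-number genomic burden and the pathogenic germline-variant filter.

These operate on already-called tables: SEG-like segment files (chrom,
start, end, log2 ratio; 1-based inclusive coordinates) and variant tables
(gene, ClinVar significance, VAF).  Alignment, segmentation and variant
calling are upstream of this package.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .errors import ValidationError
from .io_model import SegmentRecord, VariantRecord

GAIN_THRESHOLD = 0.3
LOSS_THRESHOLD = -0.3

#: breast cancer susceptibility genes screened for pathogenic germline
#: variants.  "FANC" and "XRCC" are family stubs matched by prefix (the
#: intended members are stored verbatim; see GermlineFilterConfig).
BREAST_CANCER_GENES = (
    "ATM", "BARD1", "BLM", "BRCA1", "BRCA2", "BRIP1", "CDH1", "CHEK2",
    "EPCAM", "FAM175A", "FANC", "MLH1", "MRE11", "MSH2", "MSH6", "MUTYH",
    "NBN", "NBS1", "NF1", "PALB2", "PMS2", "PTEN", "RAD50", "RAD51C",
    "RAD51D", "RECQL", "STK11", "TP53", "XRCC", "MEN1", "PPM1D",
)

#: gene-family stubs in the list above that match by prefix
PREFIX_STUBS = frozenset({"FANC", "XRCC"})


def call_segment_states(
    segments: Sequence[SegmentRecord],
    gain_threshold: float = GAIN_THRESHOLD,
    loss_threshold: float = LOSS_THRESHOLD,
) -> list[str]:
    """State per segment: gain if log2 ratio > gain_threshold, loss if
    < loss_threshold, otherwise neutral.  Inequalities are strict, so a
    ratio exactly at a threshold is neutral."""
    states = []
    for s in segments:
        if s.log2_ratio > gain_threshold:
            states.append("gain")
        elif s.log2_ratio < loss_threshold:
            states.append("loss")
        else:
            states.append("neutral")
    return states


@dataclass(frozen=True)
class BurdenResult:
    """Fractions of total segmented length in each copy-number state."""

    sample_id: str
    gain_fraction: float
    loss_fraction: float

    @property
    def altered_fraction(self) -> float:
        return self.gain_fraction + self.loss_fraction


def cn_burden(
    segments: Sequence[SegmentRecord],
    sample_id: str = "",
    gain_threshold: float = GAIN_THRESHOLD,
    loss_threshold: float = LOSS_THRESHOLD,
) -> BurdenResult:
    """Copy-number genomic burden: summed length of gained (and lost)
    segments over the total segmented length.  Segment length is
    end − start + 1 (1-based inclusive)."""
    if not segments:
        raise ValidationError("cannot compute burden on zero segments")
    total = sum(s.length for s in segments)
    if total <= 0:
        raise ValidationError("total segment length is zero")
    states = call_segment_states(segments, gain_threshold, loss_threshold)
    gain = sum(s.length for s, st in zip(segments, states) if st == "gain")
    loss = sum(s.length for s, st in zip(segments, states) if st == "loss")
    return BurdenResult(sample_id, gain / total, loss / total)


@dataclass
class GermlineFilterConfig:
    """Filter settings for pathogenic germline variants.

    Gene symbols match case-insensitively after whitespace stripping;
    entries listed in ``prefix_stubs`` (gene-family stubs such as FANC)
    match any gene sharing the prefix.  ``min_vaf`` is inclusive
    ("at least").
    """

    gene_list: tuple[str, ...] = BREAST_CANCER_GENES
    min_vaf: float = 0.15
    allowed_significance: frozenset = frozenset({"Pathogenic", "Likely-Pathogenic"})
    prefix_stubs: frozenset = PREFIX_STUBS

    def matches_gene(self, gene: str) -> bool:
        g = gene.strip().upper()
        for entry in self.gene_list:
            e = entry.strip().upper()
            if g == e:
                return True
            if entry in self.prefix_stubs and g.startswith(e):
                return True
        return False


def filter_pathogenic_germline(
    variants: Sequence[VariantRecord],
    config: GermlineFilterConfig | None = None,
) -> list[VariantRecord]:
    """Keep variants that are (Likely-)Pathogenic in ClinVar, at VAF ≥
    min_vaf, in a susceptibility gene; input order is preserved."""
    config = config or GermlineFilterConfig()
    return [
        v
        for v in variants
        if v.clinvar in config.allowed_significance
        and v.vaf >= config.min_vaf
        and config.matches_gene(v.gene)
    ]
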