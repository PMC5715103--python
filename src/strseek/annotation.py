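"""Genomic-feature classification of STR loci against gene models.

Each locus gets exactly one class — CDS, 5'UTR, 3'UTR, intron, promoter or
intergenic — by most-specific-feature-wins: over every transcript the locus
overlaps, the highest-precedence class attained anywhere in the overlap is
kept (CDS > UTR5 > UTR3 > intron). A locus touching no transcript is a
promoter hit if it overlaps the strand-aware window upstream of a TSS
(default 2 kb), else intergenic. Exons of non-coding transcripts (lncRNAs
such as PCA3 have no CDS) are classed by a configurable label, UTR3 by
default.
"""

from __future__ import annotations

import json
import logging
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from intervaltree import IntervalTree

from .catalog import STRLocus

logger = logging.getLogger(__name__)

FEATURE_CLASSES = ("CDS", "UTR5", "UTR3", "intron", "promoter", "intergenic")
# most-specific-feature-wins ordering for genic overlap
_PRECEDENCE = {"CDS": 0, "UTR5": 1, "UTR3": 2, "intron": 3}


@dataclass(frozen=True)
class GeneModel:
    """One transcript model: transcript span, coding span (cds_start ==
    cds_end for non-coding transcripts) and sorted, non-overlapping exons,
    all 0-based half-open."""

    gene_id: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int
    cds_start: int
    cds_end: int
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError("strand must be '+' or '-'")
        if not self.tx_start <= self.cds_start <= self.cds_end <= self.tx_end:
            raise ValueError("cds span must lie within tx span")
        prev_end = self.tx_start
        for start, end in self.exons:
            if start >= end or start < prev_end or end > self.tx_end:
                raise ValueError("exons must be sorted, non-overlapping, within tx span")
            prev_end = end

    @property
    def is_coding(self) -> bool:
        return self.cds_end > self.cds_start

    @property
    def tss(self) -> int:
        """Transcription start site coordinate (strand-aware)."""
        return self.tx_start if self.strand == "+" else self.tx_end


def _overlap(a0: int, a1: int, b0: int, b1: int) -> int:
    return max(0, min(a1, b1) - max(a0, b0))


def _exon_class(model: GeneModel, seg_start: int, seg_end: int, noncoding_exon_class: str) -> set[str]:
    """Classes attained by an exonic segment [seg_start, seg_end)."""
    classes: set[str] = set()
    if not model.is_coding:
        classes.add(noncoding_exon_class)
        return classes
    if _overlap(seg_start, seg_end, model.cds_start, model.cds_end):
        classes.add("CDS")
    # exonic sequence 5'/3' of the CDS by strand
    upstream = _overlap(seg_start, seg_end, model.tx_start, model.cds_start) > 0
    downstream = _overlap(seg_start, seg_end, model.cds_end, model.tx_end) > 0
    if model.strand == "+":
        if upstream:
            classes.add("UTR5")
        if downstream:
            classes.add("UTR3")
    else:
        if upstream:
            classes.add("UTR3")
        if downstream:
            classes.add("UTR5")
    return classes


def _genic_classes(
    model: GeneModel, start: int, end: int, noncoding_exon_class: str
) -> set[str]:
    """Classes the interval [start, end) attains within one transcript."""
    classes: set[str] = set()
    exonic_bp = 0
    for ex_start, ex_end in model.exons:
        seg0, seg1 = max(start, ex_start), min(end, ex_end)
        if seg0 < seg1:
            exonic_bp += seg1 - seg0
            classes |= _exon_class(model, seg0, seg1, noncoding_exon_class)
    genic_bp = _overlap(start, end, model.tx_start, model.tx_end)
    if genic_bp > exonic_bp:  # some overlapped base is intronic
        classes.add("intron")
    return classes


def promoter_window(model: GeneModel, promoter_bp: int) -> tuple[int, int]:
    """The strand-aware [TSS - promoter_bp, TSS) window (mirrored on minus)."""
    if model.strand == "+":
        return max(0, model.tx_start - promoter_bp), model.tx_start
    return model.tx_end, model.tx_end + promoter_bp


class FeatureClassifier:
    """Chromosome-indexed classifier over a set of gene models."""

    def __init__(
        self,
        models: Iterable[GeneModel],
        promoter_bp: int = 2000,
        noncoding_exon_class: str = "UTR3",
    ) -> None:
        if noncoding_exon_class not in ("UTR5", "UTR3", "intron"):
            raise ValueError("noncoding_exon_class must be a genic class")
        self.promoter_bp = promoter_bp
        self.noncoding_exon_class = noncoding_exon_class
        self._tx_trees: dict[str, IntervalTree] = {}
        self._prom_trees: dict[str, IntervalTree] = {}
        self._warned_chroms: set[str] = set()
        for model in models:
            self._tx_trees.setdefault(model.chrom, IntervalTree()).addi(
                model.tx_start, model.tx_end, model
            )
            p0, p1 = promoter_window(model, promoter_bp)
            if p0 < p1:
                self._prom_trees.setdefault(model.chrom, IntervalTree()).addi(p0, p1, model)

    def classify(self, locus: STRLocus) -> str:
        if locus.chrom not in self._tx_trees and locus.chrom not in self._prom_trees:
            if locus.chrom not in self._warned_chroms:
                logger.warning("chromosome %s absent from gene models; intergenic", locus.chrom)
                self._warned_chroms.add(locus.chrom)
            return "intergenic"
        classes: set[str] = set()
        tx_tree = self._tx_trees.get(locus.chrom)
        if tx_tree is not None:
            for iv in tx_tree.overlap(locus.start, locus.end):
                classes |= _genic_classes(
                    iv.data, locus.start, locus.end, self.noncoding_exon_class
                )
        if classes:
            return min(classes, key=_PRECEDENCE.__getitem__)
        prom_tree = self._prom_trees.get(locus.chrom)
        if prom_tree is not None and prom_tree.overlap(locus.start, locus.end):
            return "promoter"
        return "intergenic"


def classify_locus(
    locus: STRLocus,
    models: Iterable[GeneModel] | FeatureClassifier,
    promoter_bp: int = 2000,
    noncoding_exon_class: str = "UTR3",
) -> str:
    """Classify one locus; accepts a prebuilt :class:`FeatureClassifier` or
    builds a throwaway index from the models."""
    if not isinstance(models, FeatureClassifier):
        models = FeatureClassifier(models, promoter_bp, noncoding_exon_class)
    return models.classify(locus)


def composition(classes: Iterable[str]) -> dict[str, float]:
    """Percentage composition of feature classes (sums to 100)."""
    tally = Counter(classes)
    total = sum(tally.values())
    if total == 0:
        raise ValueError("classes must be non-empty")
    return {c: 100.0 * n / total for c, n in sorted(tally.items())}


def read_bed12(source: str | Path) -> list[GeneModel]:
    """Read gene models from BED12 (thickStart/thickEnd as the coding span)."""
    models: list[GeneModel] = []
    with open(source) as handle:
        for line in handle:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            f = line.rstrip("\n").split("\t")
            chrom, start, end, name = f[0], int(f[1]), int(f[2]), f[3]
            strand = f[5]
            thick_start, thick_end = int(f[6]), int(f[7])
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            offsets = [int(x) for x in f[11].rstrip(",").split(",")]
            exons = tuple((start + o, start + o + s) for o, s in zip(offsets, sizes))
            models.append(
                GeneModel(
                    gene_id=name,
                    chrom=chrom,
                    strand=strand,
                    tx_start=start,
                    tx_end=end,
                    cds_start=thick_start,
                    cds_end=thick_end,
                    exons=exons,
                )
            )
    return models


def read_gtf(source: str | Path) -> list[GeneModel]:
    """Read gene models from a minimal GTF subset (transcript/exon/CDS rows,
    ``transcript_id`` attribute required). GTF coordinates are 1-based
    inclusive and converted here."""
    tx: dict[str, dict] = {}
    with open(source) as handle:
        for line in handle:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            feature, start, end = f[2], int(f[3]) - 1, int(f[4])
            attrs = dict(
                (kv.split(" ", 1)[0], kv.split(" ", 1)[1].strip('"'))
                for kv in (s.strip() for s in f[8].rstrip(";").split(";"))
                if " " in kv
            )
            tid = attrs.get("transcript_id")
            if tid is None:
                raise ValueError("GTF row lacks transcript_id attribute")
            entry = tx.setdefault(
                tid, {"chrom": f[0], "strand": f[6], "tx": None, "exons": [], "cds": []}
            )
            if feature == "transcript":
                entry["tx"] = (start, end)
            elif feature == "exon":
                entry["exons"].append((start, end))
            elif feature == "CDS":
                entry["cds"].append((start, end))
    models: list[GeneModel] = []
    for tid, entry in tx.items():
        exons = tuple(sorted(entry["exons"]))
        if entry["tx"] is not None:
            tx_start, tx_end = entry["tx"]
        elif exons:
            tx_start, tx_end = exons[0][0], exons[-1][1]
        else:
            raise ValueError(f"transcript {tid} has neither transcript row nor exons")
        if not exons:
            exons = ((tx_start, tx_end),)
        if entry["cds"]:
            cds_start = min(s for s, _ in entry["cds"])
            cds_end = max(e for _, e in entry["cds"])
        else:
            cds_start = cds_end = tx_start
        models.append(
            GeneModel(
                gene_id=tid,
                chrom=entry["chrom"],
                strand=entry["strand"],
                tx_start=tx_start,
                tx_end=tx_end,
                cds_start=cds_start,
                cds_end=cds_end,
                exons=exons,
            )
        )
    return models


def write_classes(rows: Sequence[tuple[str, str]], dest: str | Path) -> None:
    """Write (locus_id, class) rows as TSV."""
    with open(dest, "w") as handle:
        handle.write("#locus_id\tfeature_class\n")
        for locus_id, cls in rows:
            handle.write(f"{locus_id}\t{cls}\n")


def write_composition(comp: dict[str, float], dest: str | Path) -> None:
    Path(dest).write_text(json.dumps(comp, indent=2, sort_keys=True) + "\n")
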