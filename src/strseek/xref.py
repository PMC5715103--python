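"""Cross-reference an STR catalogue against an external polymorphic call set.

A catalogue locus is considered independently supported when an externally
called STR (e.g. a lobSTR call set from population sequencing) overlaps it on
the same chromosome and the two repeat motifs agree up to reversal and
reverse complementation — the equivalence that arises because an annotation
and a caller may report the same repeat from opposite strands or read the
unit in the opposite direction. Matched loci inherit the call's polymorphic
flag, giving the catalogue of putatively genotypable, polymorphic STRs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from intervaltree import IntervalTree

from .catalog import STRLocus

logger = logging.getLogger(__name__)

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_ACGT = frozenset("ACGT")


@dataclass(frozen=True, slots=True)
class PolymorphicCall:
    """An externally called STR locus (0-based half-open) with its motif and
    whether the caller observed it to be polymorphic."""

    chrom: str
    start: int
    end: int
    motif: str
    is_polymorphic: bool

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("end must exceed start")
        if not (1 <= len(self.motif) <= 6):
            raise ValueError("motif length must be 1-6")


@dataclass(frozen=True, slots=True)
class XrefAnnotation:
    """Cross-match outcome for one catalogue locus."""

    locus_id: str
    matched: bool
    matched_polymorphic: bool
    overlap_bp: int

    def __post_init__(self) -> None:
        if self.matched_polymorphic and not self.matched:
            raise ValueError("matched_polymorphic implies matched")
        if self.matched != (self.overlap_bp > 0):
            raise ValueError("overlap_bp > 0 iff matched")


def reverse_complement(motif: str) -> str:
    return motif.translate(_COMPLEMENT)[::-1]


def motif_equivalents(motif: str, mode: str = "basic") -> frozenset[str]:
    """Set of motifs considered the same repeat unit.

    mode ``"basic"``: the motif, its reverse, and its reverse complement.
    mode ``"extended"``: additionally closed under complementation and all
    cyclic rotations of every member (the canonical motif-family closure).
    """
    m = motif.upper()
    if not m or set(m) - _ACGT:
        raise ValueError(f"motif must be non-empty over ACGT, got {motif!r}")
    if mode == "basic":
        return frozenset({m, m[::-1], reverse_complement(m)})
    if mode != "extended":
        raise ValueError(f"mode must be 'basic' or 'extended', got {mode!r}")
    # closure under {reverse, complement} x cyclic rotation
    seen: set[str] = set()
    frontier = [m]
    while frontier:
        s = frontier.pop()
        if s in seen:
            continue
        seen.add(s)
        frontier.append(s[::-1])
        frontier.append(s.translate(_COMPLEMENT))
        frontier.extend(s[i:] + s[:i] for i in range(1, len(s)))
    return frozenset(seen)


def _motifs_equivalent(a: str, b: str, mode: str) -> bool:
    return bool(motif_equivalents(a, mode) & motif_equivalents(b, mode))


def cross_match(
    catalog: Iterable[STRLocus],
    callset: Iterable[PolymorphicCall],
    mode: str = "basic",
    min_overlap: int = 1,
) -> list[XrefAnnotation]:
    """Annotate each catalogue locus with its best-supported external call.

    A locus matches a call when they share a chromosome, overlap by at least
    ``min_overlap`` bp, and their motif-equivalence sets intersect. Among
    matching calls the one with the largest overlap wins (ties: smaller call
    start); ``matched_polymorphic`` carries that call's flag. Annotations are
    returned in catalogue order.
    """
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    trees: dict[str, IntervalTree] = {}
    for call in callset:
        trees.setdefault(call.chrom, IntervalTree()).addi(call.start, call.end, call)

    annotations: list[XrefAnnotation] = []
    n_matched = 0
    for locus in catalog:
        best: PolymorphicCall | None = None
        best_overlap = 0
        tree = trees.get(locus.chrom)
        if tree is not None:
            for iv in tree.overlap(locus.start, locus.end):
                call: PolymorphicCall = iv.data
                overlap = min(locus.end, call.end) - max(locus.start, call.start)
                if overlap < min_overlap:
                    continue
                if not _motifs_equivalent(locus.motif, call.motif, mode):
                    continue
                if overlap > best_overlap or (
                    overlap == best_overlap and best is not None and call.start < best.start
                ):
                    best, best_overlap = call, overlap
        if best is None:
            annotations.append(XrefAnnotation(locus.locus_id, False, False, 0))
        else:
            n_matched += 1
            annotations.append(
                XrefAnnotation(locus.locus_id, True, best.is_polymorphic, best_overlap)
            )
    if annotations and n_matched == 0:
        logger.warning(
            "no catalogue locus matched any call — check chromosome naming conventions"
        )
    return annotations


@dataclass(frozen=True, slots=True)
class XrefSummary:
    """The two headline proportions of a cross-match."""

    fraction_matched: float
    fraction_polymorphic_among_matched: float
    any_matched: bool
    n: int


def xref_summary(annotations: Sequence[XrefAnnotation]) -> XrefSummary:
    """Fraction of loci matched, and fraction polymorphic among the matched.

    With zero matches the second proportion is undefined; it is reported as
    0.0 with ``any_matched`` False.
    """
    if not annotations:
        raise ValueError("annotations must be non-empty")
    n = len(annotations)
    n_matched = sum(a.matched for a in annotations)
    n_poly = sum(a.matched_polymorphic for a in annotations)
    if n_matched == 0:
        return XrefSummary(0.0, 0.0, False, n)
    return XrefSummary(n_matched / n, n_poly / n_matched, True, n)


def read_callset_vcf(path: str | Path, poly_info_key: str = "POLY") -> list[PolymorphicCall]:
    """Read a call set from a VCF: POS is 1-based; the STR end and motif come
    from INFO keys ``END`` and ``MOTIF``; the polymorphic flag from
    ``poly_info_key`` (flag present => polymorphic)."""
    import pysam

    calls: list[PolymorphicCall] = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            motif = rec.info.get("MOTIF")
            if motif is None:
                raise ValueError(f"record {rec.chrom}:{rec.pos} lacks INFO/MOTIF")
            end = rec.info.get("END", rec.stop)
            calls.append(
                PolymorphicCall(
                    chrom=rec.chrom,
                    start=rec.pos - 1,
                    end=int(end),
                    motif=str(motif),
                    is_polymorphic=bool(rec.info.get(poly_info_key, False)),
                )
            )
    return calls


def read_callset_tsv(source: str | Path) -> list[PolymorphicCall]:
    """Read a BED-like call set TSV: chrom, start, end, motif, is_polymorphic."""
    calls: list[PolymorphicCall] = []
    with open(source) as handle:
        for line in handle:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            calls.append(
                PolymorphicCall(f[0], int(f[1]), int(f[2]), f[3], f[4] in ("1", "True", "true"))
            )
    return calls


def write_annotations(annotations: Iterable[XrefAnnotation], dest: str | Path) -> None:
    with open(dest, "w") as handle:
        handle.write("#locus_id\tmatched\tmatched_polymorphic\toverlap_bp\n")
        for a in annotations:
            handle.write(
                f"{a.locus_id}\t{int(a.matched)}\t{int(a.matched_polymorphic)}\t{a.overlap_bp}\n"
            )
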