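"""STR expression from RNA-seq STR-caller output, plus RT-qPCR quantities.

The RNA-seq path starts from lobSTR-style calls: each locus/sample carries an
``ALLREADS`` field listing every observed allele with its supporting read
count. Reads feeding those calls are pre-filtered on SAM flags (proper pair
required; secondary, supplementary/chimeric and duplicate alignments and
multi-mappers removed). Alleles supported by fewer than 10 reads are
discarded, and the surviving read mass is normalised against the sample's
total mapped reads (FPKM by default) to give a per-locus expression value.

The qPCR path provides the two standard relative-expression calculations:
fold change by the delta-delta-Ct method against a single housekeeping gene,
and per-sample abundance by 2^-dCt against the geometric mean of one or more
housekeeping genes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy.stats import gmean

# SAM flag bits
FLAG_PROPER_PAIR = 0x2
FLAG_SECONDARY = 0x100
FLAG_DUPLICATE = 0x400
FLAG_SUPPLEMENTARY = 0x800


@dataclass(frozen=True, slots=True)
class AlignmentRecordLite:
    """The two alignment attributes the read filter needs: the SAM flag and
    the number of reported alignments for the read (HI/NH-style tag)."""

    flag: int
    alignment_hits: int = 1

    def __post_init__(self) -> None:
        if self.flag < 0:
            raise ValueError("flag must be >= 0")
        if self.alignment_hits < 1:
            raise ValueError("alignment_hits must be >= 1")


def keep_alignment(rec: AlignmentRecordLite) -> bool:
    """True iff the read passes the expression read filter: properly paired,
    not secondary/supplementary/duplicate, and uniquely mapped."""
    return (
        bool(rec.flag & FLAG_PROPER_PAIR)
        and not rec.flag & (FLAG_SECONDARY | FLAG_DUPLICATE | FLAG_SUPPLEMENTARY)
        and rec.alignment_hits == 1
    )


def keep_aligned_segment(seg) -> bool:
    """:func:`keep_alignment` applied to a ``pysam.AlignedSegment``; the hit
    count is read from the NH tag, falling back to HI+1-style uniqueness via
    NH's absence meaning a single reported alignment."""
    hits = 1
    if seg.has_tag("NH"):
        hits = int(seg.get_tag("NH"))
    elif seg.has_tag("HI"):
        # HI indexes the alignment; any index beyond the first marks a multi-mapper
        hits = 2 if int(seg.get_tag("HI")) > 1 else 1
    return keep_alignment(AlignmentRecordLite(flag=seg.flag, alignment_hits=hits))


@dataclass(frozen=True)
class AlleleReadProfile:
    """Per (sample, condition, locus) allele read counts.

    Allele labels are integers — repeat counts or bp offsets from the
    reference allele, carried through unchanged — mapping to supporting read
    counts. ``total_mapped_reads`` is the sample's library size.
    """

    sample_id: str
    condition: str
    locus_id: str
    allele_reads: Mapping[int, int] = field(default_factory=dict)
    total_mapped_reads: int = 0

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.allele_reads.values()):
            raise ValueError("read counts must be >= 0")
        if self.total_mapped_reads < sum(self.allele_reads.values()):
            raise ValueError("total_mapped_reads must cover the allele reads")

    @property
    def is_expressed(self) -> bool:
        return bool(self.allele_reads)

    @property
    def str_reads(self) -> int:
        return sum(self.allele_reads.values())


def parse_allreads(text: str) -> dict[int, int]:
    """Parse a lobSTR ``ALLREADS`` field: ``allele|count`` pairs separated by
    semicolons; ``"."`` or an empty string is an empty mapping."""
    if text in (".", ""):
        return {}
    mapping: dict[int, int] = {}
    for token in text.split(";"):
        parts = token.split("|")
        if len(parts) != 2:
            raise ValueError(f"malformed ALLREADS token {token!r}")
        try:
            allele, count = int(parts[0]), int(parts[1])
        except ValueError as exc:
            raise ValueError(f"malformed ALLREADS token {token!r}") from exc
        mapping[allele] = count
    return mapping


def format_allreads(mapping: Mapping[int, int]) -> str:
    """Inverse of :func:`parse_allreads` (alleles in ascending order)."""
    if not mapping:
        return "."
    return ";".join(f"{a}|{mapping[a]}" for a in sorted(mapping))


def filter_alleles(profile: AlleleReadProfile, min_reads: int = 10) -> AlleleReadProfile:
    """Drop alleles supported by fewer than ``min_reads`` reads (boundary
    value kept). Idempotent; a profile with no surviving allele is
    not expressed."""
    if min_reads < 1:
        raise ValueError("min_reads must be >= 1")
    kept = {a: c for a, c in profile.allele_reads.items() if c >= min_reads}
    return replace(profile, allele_reads=kept)


def normalize_expression(
    profile: AlleleReadProfile, locus_length_bp: int | None = None, scheme: str = "fpkm"
) -> float:
    """Normalise surviving STR reads against library size.

    ``"fpkm"``: reads * 1e9 / (locus_length_bp * total_mapped_reads);
    ``"rpm"``: reads * 1e6 / total_mapped_reads.
    """
    if profile.total_mapped_reads <= 0:
        raise ValueError("total_mapped_reads must be positive")
    reads = profile.str_reads
    if scheme == "rpm":
        return reads * 1e6 / profile.total_mapped_reads
    if scheme != "fpkm":
        raise ValueError(f"scheme must be 'fpkm' or 'rpm', got {scheme!r}")
    if locus_length_bp is None or locus_length_bp <= 0:
        raise ValueError("fpkm requires a positive locus_length_bp")
    return reads * 1e9 / (locus_length_bp * profile.total_mapped_reads)


def observed_alleles(profiles: Iterable[AlleleReadProfile]) -> list[int]:
    """Ascending union of surviving allele labels across profiles of one locus."""
    alleles: set[int] = set()
    for p in profiles:
        alleles.update(p.allele_reads)
    return sorted(alleles)


def offsets_to_repeat_counts(mapping: Mapping[int, int], ref_repeats: int, period: int) -> dict[int, int]:
    """Convert bp-offset allele labels to repeat counts given the reference
    allele's repeat count and the motif period. Offsets must be multiples of
    the period."""
    out: dict[int, int] = {}
    for offset, count in mapping.items():
        if offset % period:
            raise ValueError(f"offset {offset} is not a multiple of period {period}")
        out[ref_repeats + offset // period] = count
    return out


@dataclass(frozen=True)
class CtMeasurement:
    """One qPCR measurement: the target gene Ct and its housekeeping Ct(s)."""

    target_ct: float
    housekeeping_cts: Sequence[float]

    def __post_init__(self) -> None:
        cts = [self.target_ct, *self.housekeeping_cts]
        if not self.housekeeping_cts:
            raise ValueError("at least one housekeeping Ct is required")
        if not all(np.isfinite(c) and c > 0 for c in cts):
            raise ValueError("Ct values must be finite and positive")

    @property
    def delta_ct(self) -> float:
        return self.target_ct - float(gmean(np.asarray(self.housekeeping_cts, dtype=float)))


def rel_expr_ddct(treated: CtMeasurement, control: CtMeasurement) -> float:
    """Fold change by the delta-delta-Ct method, 2^-((dCt_treated)-(dCt_control)),
    each dCt against a single housekeeping gene."""
    for m, name in ((treated, "treated"), (control, "control")):
        if len(m.housekeeping_cts) != 1:
            raise ValueError(
                f"{name}: delta-delta-Ct uses exactly one housekeeping gene; "
                "use rel_expr_dct for geometric-mean normalisation"
            )
    d_treated = treated.target_ct - treated.housekeeping_cts[0]
    d_control = control.target_ct - control.housekeeping_cts[0]
    return float(2.0 ** -(d_treated - d_control))


def rel_expr_dct(m: CtMeasurement) -> float:
    """Relative abundance 2^-dCt with dCt against the geometric mean of the
    housekeeping Cts (reduces to plain dCt for a single housekeeper)."""
    return float(2.0 ** -m.delta_ct)


def read_lobstr_vcf(
    path: str | Path,
    total_mapped_reads: Mapping[str, int],
    condition_of: Mapping[str, str] | None = None,
) -> list[AlleleReadProfile]:
    """Read per-sample ALLREADS profiles from a lobSTR-style VCF.

    ``total_mapped_reads`` maps sample name to library size; ``condition_of``
    optionally maps sample name to its condition label (default
    ``"unknown"``).
    """
    import pysam

    profiles: list[AlleleReadProfile] = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            locus_id = rec.id or f"{rec.chrom}:{rec.pos - 1}"
            for sample_name, sample in rec.samples.items():
                allreads = sample.get("ALLREADS")
                mapping = parse_allreads(allreads if allreads not in (None,) else ".")
                profiles.append(
                    AlleleReadProfile(
                        sample_id=sample_name,
                        condition=(condition_of or {}).get(sample_name, "unknown"),
                        locus_id=locus_id,
                        allele_reads=mapping,
                        total_mapped_reads=total_mapped_reads[sample_name],
                    )
                )
    return profiles


def expression_matrix(
    profiles: Iterable[AlleleReadProfile],
    locus_lengths: Mapping[str, int] | None = None,
    min_reads: int = 10,
    scheme: str = "fpkm",
):
    """Filtered, normalised expression as a DataFrame (rows = loci, columns =
    ``sample:condition``)."""
    import pandas as pd

    cells: dict[str, dict[str, float]] = {}
    for p in profiles:
        fp = filter_alleles(p, min_reads=min_reads)
        length = None if locus_lengths is None else locus_lengths.get(p.locus_id)
        value = normalize_expression(fp, locus_length_bp=length, scheme=scheme)
        cells.setdefault(fp.locus_id, {})[f"{fp.sample_id}:{fp.condition}"] = value
    frame = pd.DataFrame.from_dict(cells, orient="index").fillna(0.0)
    return frame.sort_index()[sorted(frame.columns)]
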