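"""Short tandem repeat (STR) catalogue: RepeatMasker parsing, summary, filtering.

An STR here is a ``Simple_repeat`` record from a RepeatMasker ``.out``
annotation file: a 1-6 nt motif repeated in tandem, with per-locus divergence
percentages (substitutions, deletions, insertions relative to the consensus).
The catalogue stage parses those records, characterises the genome-wide
distribution (repeat class, period, motif GC content), and applies the two
exclusion filters used to nominate genotypable loci:

* mono-nucleotide repeats are dropped (capillary fragment analysis cannot
  resolve single-base allele differences), and
* loci with more than 5% substitutions, deletions or insertions are dropped
  (sequence-degenerate repeats are poor expansion/contraction candidates).

All internal coordinates are 0-based half-open; the RepeatMasker ``.out``
1-based inclusive begin/end are converted at the parsing boundary.
"""

from __future__ import annotations

import gzip
import logging
import math
import re
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, TextIO

logger = logging.getLogger(__name__)

_MOTIF_RE = re.compile(r"^\(([A-Za-z]+)\)n$")
_ACGT = frozenset("ACGT")

#: class label RepeatMasker gives to microsatellites
SIMPLE_REPEAT = "Simple_repeat"


class RepeatMaskerParseError(ValueError):
    """A structurally malformed ``.out`` data row."""


@dataclass(frozen=True, slots=True)
class STRLocus:
    """One simple-repeat annotation record.

    ``start``/``end`` are 0-based half-open genomic coordinates, ``motif`` the
    uppercase repeat unit (period = ``len(motif)``), and ``pct_div``,
    ``pct_del``, ``pct_ins`` the RepeatMasker divergence percentages.
    """

    chrom: str
    start: int
    end: int
    motif: str
    period: int
    strand: str
    pct_div: float
    pct_del: float
    pct_ins: float
    repeat_class: str = SIMPLE_REPEAT

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"end ({self.end}) must exceed start ({self.start})")
        if not (1 <= len(self.motif) <= 6) or set(self.motif) - _ACGT:
            raise ValueError(f"motif must be 1-6 bases over ACGT, got {self.motif!r}")
        if self.period != len(self.motif):
            raise ValueError("period must equal motif length")
        for name in ("pct_div", "pct_del", "pct_ins"):
            v = getattr(self, name)
            if not (0.0 <= v <= 100.0):
                raise ValueError(f"{name} out of [0, 100]: {v}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    @property
    def locus_id(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}:{self.motif}"

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True, slots=True)
class CatalogSummary:
    """Tallies of a catalogue by repeat class, period and motif GC bin."""

    class_counts: dict[str, int]
    period_counts: dict[int, int]
    gc_histogram: dict[float, int]
    n_total: int


@dataclass(frozen=True, slots=True)
class FilterReport:
    """Accounting for :func:`filter_catalog`: every input locus is either
    excluded as mono-repeat, excluded as divergent, or kept."""

    n_input: int
    n_excluded_mono: int
    n_excluded_divergent: int
    n_kept: int

    def __post_init__(self) -> None:
        if self.n_input != self.n_excluded_mono + self.n_excluded_divergent + self.n_kept:
            raise ValueError("filter report does not partition the input")


def _open_text(source: str | Path | TextIO) -> TextIO:
    if hasattr(source, "read"):
        return source  # type: ignore[return-value]
    path = Path(source)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def parse_repeatmasker(
    source: str | Path | TextIO | Iterable[str],
    keep_classes: set[str] | frozenset[str] | None = frozenset({SIMPLE_REPEAT}),
) -> list[STRLocus]:
    """Parse a RepeatMasker ``.out`` annotation into :class:`STRLocus` records.

    ``source`` may be a path (optionally ``.gz``), an open text handle, or an
    iterable of lines. The ``.out`` dialect is: two header lines and a blank
    line, then whitespace-delimited columns
    ``SW-score %div %del %ins query begin end (left) strand name class/family …``.
    Rows whose class/family is not in ``keep_classes`` are skipped
    (``keep_classes=None`` keeps everything). The repeat name for simple
    repeats has the form ``(MOTIF)n``; rows whose motif contains non-ACGT
    characters (RepeatMasker occasionally emits ambiguity codes) are skipped
    with a warning. Begin/end are 1-based inclusive and converted to 0-based
    half-open; strand ``C`` (complement) maps to ``-``.

    Raises :class:`RepeatMaskerParseError` naming the line number for rows with
    too few columns or non-numeric coordinates.
    """
    if isinstance(source, (str, Path)) or hasattr(source, "read"):
        handle = _open_text(source)  # type: ignore[arg-type]
        lines: Iterable[str] = handle
    else:
        lines = source

    loci: list[STRLocus] = []
    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line:
            continue
        fields = line.split()
        # header lines start with column titles, not an integer SW score
        if not fields[0].lstrip("-").isdigit():
            continue
        if len(fields) < 11:
            raise RepeatMaskerParseError(
                f"line {lineno}: expected >=11 columns, got {len(fields)}"
            )
        repeat_class = fields[10]
        if keep_classes is not None and repeat_class not in keep_classes:
            continue
        try:
            pct_div, pct_del, pct_ins = (float(fields[i]) for i in (1, 2, 3))
            begin, end = int(fields[5]), int(fields[6])
        except ValueError as exc:
            raise RepeatMaskerParseError(f"line {lineno}: {exc}") from exc
        chrom = fields[4]
        strand = "-" if fields[8] == "C" else fields[8]
        name = fields[9]
        m = _MOTIF_RE.match(name)
        if m is None:
            logger.warning("line %d: repeat name %r is not (MOTIF)n; skipped", lineno, name)
            continue
        motif = m.group(1).upper()
        if set(motif) - _ACGT or not (1 <= len(motif) <= 6):
            logger.warning("line %d: motif %r not 1-6 bases over ACGT; skipped", lineno, motif)
            continue
        loci.append(
            STRLocus(
                chrom=chrom,
                start=begin - 1,  # 1-based inclusive -> 0-based half-open
                end=end,
                motif=motif,
                period=len(motif),
                strand=strand,
                pct_div=pct_div,
                pct_del=pct_del,
                pct_ins=pct_ins,
                repeat_class=repeat_class,
            )
        )
    return loci


def gc_percent(motif: str) -> float:
    """GC content of a repeat unit, in percent."""
    if not motif:
        raise ValueError("motif must be non-empty")
    if set(motif.upper()) - _ACGT:
        raise ValueError(f"motif must be over ACGT, got {motif!r}")
    m = motif.upper()
    return 100.0 * (m.count("G") + m.count("C")) / len(m)


def summarize_catalog(catalog: Iterable[STRLocus], gc_bin_width: float = 10.0) -> CatalogSummary:
    """Tally a catalogue by repeat class, period, and motif GC percent.

    GC bins are half-open ``[k*w, (k+1)*w)`` keyed by bin start; a motif at
    exactly 100% GC falls in the last bin that contains 100.
    """
    loci = list(catalog)
    if not loci:
        raise ValueError("catalog must be non-empty")
    if gc_bin_width <= 0:
        raise ValueError("gc_bin_width must be positive")
    class_counts: Counter[str] = Counter()
    period_counts: Counter[int] = Counter()
    gc_histogram: Counter[float] = Counter()
    for locus in loci:
        class_counts[locus.repeat_class] += 1
        period_counts[locus.period] += 1
        gc = gc_percent(locus.motif)
        gc_histogram[math.floor(gc / gc_bin_width) * gc_bin_width] += 1
    return CatalogSummary(
        class_counts=dict(class_counts),
        period_counts=dict(sorted(period_counts.items())),
        gc_histogram=dict(sorted(gc_histogram.items())),
        n_total=len(loci),
    )


def filter_catalog(
    catalog: Iterable[STRLocus],
    exclude_mono: bool = True,
    max_pct: float = 5.0,
    combine: str = "any",
) -> tuple[list[STRLocus], FilterReport]:
    """Apply the mono-repeat and divergence exclusion filters.

    Mono-nucleotide repeats (period 1) are dropped first when
    ``exclude_mono``. Then the divergence rule: in mode ``"any"`` a locus is
    excluded when any of pct_div/pct_del/pct_ins is strictly greater than
    ``max_pct``; in mode ``"sum"`` when their sum exceeds ``max_pct``. The
    boundary value (exactly ``max_pct``) is kept.
    """
    if combine not in ("any", "sum"):
        raise ValueError(f"combine must be 'any' or 'sum', got {combine!r}")
    kept: list[STRLocus] = []
    n_input = n_mono = n_div = 0
    for locus in catalog:
        n_input += 1
        if exclude_mono and locus.period == 1:
            n_mono += 1
            continue
        if combine == "any":
            divergent = max(locus.pct_div, locus.pct_del, locus.pct_ins) > max_pct
        else:
            divergent = (locus.pct_div + locus.pct_del + locus.pct_ins) > max_pct
        if divergent:
            n_div += 1
            continue
        kept.append(locus)
    report = FilterReport(
        n_input=n_input,
        n_excluded_mono=n_mono,
        n_excluded_divergent=n_div,
        n_kept=len(kept),
    )
    return kept, report


_TSV_COLUMNS = ("chrom", "start", "end", "motif", "period", "pct_div", "pct_del", "pct_ins", "strand")


def write_catalog(catalog: Iterable[STRLocus], dest: str | Path | TextIO) -> None:
    """Write a catalogue as BED-like TSV (0-based half-open coordinates)."""
    own = isinstance(dest, (str, Path))
    handle = open(dest, "w") if own else dest  # type: ignore[arg-type]
    try:
        handle.write("#" + "\t".join(_TSV_COLUMNS) + "\n")
        for loc in catalog:
            handle.write(
                f"{loc.chrom}\t{loc.start}\t{loc.end}\t{loc.motif}\t{loc.period}\t"
                f"{loc.pct_div!r}\t{loc.pct_del!r}\t{loc.pct_ins!r}\t{loc.strand}\n"
            )
    finally:
        if own:
            handle.close()


def read_catalog(source: str | Path | TextIO) -> list[STRLocus]:
    """Read a BED-like TSV written by :func:`write_catalog`."""
    own = isinstance(source, (str, Path))
    handle = _open_text(source) if own else source  # type: ignore[arg-type]
    loci: list[STRLocus] = []
    try:
        for line in handle:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            loci.append(
                STRLocus(
                    chrom=f[0],
                    start=int(f[1]),
                    end=int(f[2]),
                    motif=f[3],
                    period=int(f[4]),
                    strand=f[8],
                    pct_div=float(f[5]),
                    pct_del=float(f[6]),
                    pct_ins=float(f[7]),
                )
            )
    finally:
        if own:
            handle.close()
    return loci
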