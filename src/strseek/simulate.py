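"""Synthetic inputs with known ground truth for every pipeline stage.

Each generator is a pure function of its configuration and a seed, so any
run is byte-reproducible. Defaults mirror the study conditions the pipeline
is designed for: a catalogue dominated by low-divergence dinucleotide simple
repeats, an external call set detecting 75% of loci with 99% of detections
polymorphic, an eight-pair tumor/adjacent expression study with planted
up/down-regulated STRs, and a case-control cohort (1,153 cases / 1,210
controls) whose arms draw genotypes under Hardy-Weinberg from the TG-PCA3
allele frequencies (11-repeat allele at 76% in cases vs 71% in controls).

The generated cohort is an idealisation: each arm is exactly HWE at its own
allele frequencies (a case arm ascertained on genotype is not strictly HWE),
ages are normal, survival is exponential with genotype-dependent hazards,
and there is no linkage structure around the STR.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from .assoc import Genotype, SubjectRecord
from .catalog import SIMPLE_REPEAT, STRLocus
from .prioritize import PairedExpression
from .xref import PolymorphicCall, motif_equivalents

_MOTIF_POOL = {
    1: ["A", "T", "C"],
    2: ["TG", "CA", "AT", "TA", "AC"],
    3: ["CAG", "AAT", "ATG"],
    4: ["TAAA", "GAAA", "TTTA", "TAGA"],
    5: ["TTTTG", "CAAAA", "GAAAA"],
    6: ["TTTTTG", "CAAAAA"],
}


@dataclass(frozen=True)
class CatalogConfig:
    n_loci: int = 500
    class_mix: Mapping[str, float] = field(
        default_factory=lambda: {
            SIMPLE_REPEAT: 0.60,
            "LINE/L1": 0.15,
            "SINE/Alu": 0.15,
            "LTR/ERVL": 0.10,
        }
    )
    # mostly dinucleotides, few hexamers; ~6.5% mononucleotide
    period_mix: Mapping[int, float] = field(
        default_factory=lambda: {1: 0.065, 2: 0.50, 3: 0.12, 4: 0.17, 5: 0.09, 6: 0.055}
    )
    # per-field exponential divergence; scale 2.8 puts ~58% of loci under 5%
    # on all three fields jointly
    divergence_scale: float = 2.8
    n_chroms: int = 4

    def __post_init__(self) -> None:
        for mix in (self.class_mix, self.period_mix):
            if abs(sum(mix.values()) - 1.0) > 1e-9:
                raise ValueError("mix proportions must sum to 1")


@dataclass(frozen=True)
class CallsetConfig:
    detection_prob: float = 0.75
    polymorphic_prob: float = 0.99
    motif_swap_prob: float = 0.5  # replace motif with a reverse/revcomp equivalent
    max_jitter: int = 5

    def __post_init__(self) -> None:
        for p in (self.detection_prob, self.polymorphic_prob, self.motif_swap_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")


@dataclass(frozen=True)
class ExpressionConfig:
    n_null: int = 200
    n_planted_up: int = 4
    n_planted_down: int = 4
    n_pairs: int = 8
    effect_fold: float = 8.0
    baseline_fpkm: float = 5.0
    noise_sigma: float = 0.5  # log-normal sigma (natural log), ~1.6-fold 1-sd spread
    sparsity: float = 0.0  # probability a value is zeroed


@dataclass(frozen=True)
class CohortConfig:
    n_cases: int = 1153
    n_controls: int = 1210
    # allele frequencies from the printed TG-PCA3 allele blocks
    case_allele_freqs: Mapping[int, float] = field(
        default_factory=lambda: {9: 1 / 2312, 10: 9 / 2312, 11: 1757 / 2312, 12: 542 / 2312, 13: 3 / 2312}
    )
    control_allele_freqs: Mapping[int, float] = field(
        default_factory=lambda: {10: 7 / 2426, 11: 1730 / 2426, 12: 688 / 2426, 13: 1 / 2426}
    )
    age_mean_case: float = 63.1
    age_mean_control: float = 61.8
    age_sd: float = 8.0
    family_history_prob_case: float = 0.34
    family_history_prob_control: float = 0.10
    # aggressiveness: odds of Gleason >= 8 multiplied per 11-repeat copy
    baseline_aggressive_odds: float = 0.08
    gleason_or: float = 2.0
    # survival: exponential event hazard per month, by genotype (fallback 1.0x)
    base_hazard: float = 0.0008
    hazard_multipliers: Mapping[str, float] = field(
        default_factory=lambda: {"11/11": 1.0, "11/12": 1.0, "12/12": 0.33}
    )
    followup_months: float = 120.0
    pca_specific_frac: float = 24 / 68  # fraction of deaths that are disease-specific
    # optional genotype-level odds-ratio tilt applied to the case arm
    # (overrides case_allele_freqs when set): genotype string -> OR vs HWE
    genotype_or: Mapping[str, float] | None = None

    def __post_init__(self) -> None:
        for freqs in (self.case_allele_freqs, self.control_allele_freqs):
            if abs(sum(freqs.values()) - 1.0) > 1e-9:
                raise ValueError("allele frequencies must sum to 1 per arm")


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0
    catalog: CatalogConfig = field(default_factory=CatalogConfig)
    callset: CallsetConfig = field(default_factory=CallsetConfig)
    expression: ExpressionConfig = field(default_factory=ExpressionConfig)
    cohort: CohortConfig = field(default_factory=CohortConfig)

    @classmethod
    def from_yaml(cls, source: str | Path) -> "SimulationConfig":
        raw = yaml.safe_load(Path(source).read_text()) or {}
        return cls(
            seed=raw.get("seed", 0),
            catalog=CatalogConfig(**raw.get("catalog", {})),
            callset=CallsetConfig(**raw.get("callset", {})),
            expression=ExpressionConfig(**raw.get("expression", {})),
            cohort=CohortConfig(**raw.get("cohort", {})),
        )


# --------------------------------------------------------------------------- #
# catalogue

_OUT_HEADER = (
    "   SW  perc perc perc  query      position in query           matching"
    "       repeat              position in  repeat\n"
    "score  div. del. ins.  sequence    begin     end    (left)    repeat"
    "         class/family         begin  end (left)   ID\n"
    "\n"
)


def gen_catalog(cfg: CatalogConfig, seed: int = 0) -> tuple[str, list[STRLocus]]:
    """Generate a RepeatMasker ``.out`` text plus the truth: the STRLocus
    records a parser restricted to Simple_repeat should recover, exactly."""
    rng = np.random.default_rng(seed)
    classes = list(cfg.class_mix)
    class_p = np.array([cfg.class_mix[c] for c in classes])
    periods = list(cfg.period_mix)
    period_p = np.array([cfg.period_mix[p] for p in periods])

    lines = [_OUT_HEADER]
    truth: list[STRLocus] = []
    positions = {f"chr{i + 1}": 10_000 for i in range(cfg.n_chroms)}
    rm_id = 0
    for _ in range(cfg.n_loci):
        rm_id += 1
        chrom = f"chr{rng.integers(1, cfg.n_chroms + 1)}"
        repeat_class = classes[rng.choice(len(classes), p=class_p)]
        start0 = positions[chrom] + int(rng.integers(50, 5000))
        strand = "+" if rng.random() < 0.5 else "C"
        if repeat_class == SIMPLE_REPEAT:
            period = int(periods[rng.choice(len(periods), p=period_p)])
            motif = _MOTIF_POOL[period][rng.integers(0, len(_MOTIF_POOL[period]))]
            units = int(rng.integers(5, 31))
            length = period * units
            name = f"({motif})n"
        else:
            length = int(rng.integers(150, 3000))
            name = {"LINE/L1": "L1MA4", "SINE/Alu": "AluSx", "LTR/ERVL": "MLT1B"}.get(
                repeat_class, "REP1"
            )
        end0 = start0 + length
        positions[chrom] = end0
        # one decimal place, as RepeatMasker prints: keeps round-trip exact
        div, dele, ins = (
            round(min(float(rng.exponential(cfg.divergence_scale)), 99.9), 1) for _ in range(3)
        )
        score = int(rng.integers(200, 5000))
        lines.append(
            f"{score:>5} {div:5.1f} {dele:5.1f} {ins:5.1f}  {chrom:<10} "
            f"{start0 + 1:>9} {end0:>9} (0)  {strand} {name:<16} "
            f"{repeat_class:<18} 1 {length} (0) {rm_id}\n"
        )
        if repeat_class == SIMPLE_REPEAT:
            truth.append(
                STRLocus(
                    chrom=chrom,
                    start=start0,
                    end=end0,
                    motif=motif,
                    period=len(motif),
                    strand="-" if strand == "C" else "+",
                    pct_div=div,
                    pct_del=dele,
                    pct_ins=ins,
                )
            )
    return "".join(lines), truth


# --------------------------------------------------------------------------- #
# polymorphic call set


def gen_callset(
    catalog: Sequence[STRLocus], cfg: CallsetConfig, seed: int = 0
) -> tuple[list[PolymorphicCall], dict[str, bool]]:
    """Emit each locus with probability ``detection_prob``, jittered within
    overlap and with its motif replaced by a reverse/reverse-complement
    equivalent half the time. Returns the calls and the truth mapping
    locus_id -> is_polymorphic for every detected locus."""
    rng = np.random.default_rng(seed)
    calls: list[PolymorphicCall] = []
    truth: dict[str, bool] = {}
    for locus in catalog:
        if rng.random() >= cfg.detection_prob:
            continue
        jitter = min(cfg.max_jitter, locus.length - 1)
        shift = int(rng.integers(-jitter, jitter + 1)) if jitter > 0 else 0
        motif = locus.motif
        if rng.random() < cfg.motif_swap_prob:
            equivalents = sorted(motif_equivalents(motif, mode="basic"))
            motif = equivalents[rng.integers(0, len(equivalents))]
        poly = bool(rng.random() < cfg.polymorphic_prob)
        calls.append(
            PolymorphicCall(
                chrom=locus.chrom,
                start=max(0, locus.start + shift),
                end=locus.end + shift,
                motif=motif,
                is_polymorphic=poly,
            )
        )
        truth[locus.locus_id] = poly
    return calls, truth


def write_callset_vcf(
    calls: Sequence[PolymorphicCall], dest: str | Path, poly_info_key: str = "POLY"
) -> None:
    """Write calls as a minimal VCF: POS 1-based, INFO END/MOTIF and a
    polymorphic flag."""
    contigs = sorted({c.chrom for c in calls})
    with open(dest, "w") as handle:
        handle.write("##fileformat=VCFv4.2\n")
        for contig in contigs:
            handle.write(f"##contig=<ID={contig}>\n")
        handle.write('##INFO=<ID=END,Number=1,Type=Integer,Description="STR end">\n')
        handle.write('##INFO=<ID=MOTIF,Number=1,Type=String,Description="Repeat unit">\n')
        handle.write(
            f'##INFO=<ID={poly_info_key},Number=0,Type=Flag,Description="Polymorphic">\n'
        )
        handle.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for call in sorted(calls, key=lambda c: (c.chrom, c.start)):
            info = f"END={call.end};MOTIF={call.motif}"
            if call.is_polymorphic:
                info += f";{poly_info_key}"
            handle.write(f"{call.chrom}\t{call.start + 1}\t.\tN\t.\t.\tPASS\t{info}\n")


# --------------------------------------------------------------------------- #
# paired expression study


def gen_expression_study(
    cfg: ExpressionConfig, seed: int = 0
) -> tuple[list[PairedExpression], dict[str, list[str]]]:
    """Paired tumor/adjacent expression with planted differential STRs.

    Null STRs draw tumor and adjacent values i.i.d. log-normal around
    ``baseline_fpkm``; planted-up STRs have tumor multiplied by
    ``effect_fold``, planted-down the adjacent side. ``sparsity`` zeroes
    values at random. Truth lists the planted ids.
    """
    rng = np.random.default_rng(seed)
    samples = [f"P{i + 1}" for i in range(cfg.n_pairs)]
    mu = math.log(cfg.baseline_fpkm)

    def draw_pairs(tumor_scale: float, adjacent_scale: float) -> tuple:
        pairs = []
        for sample in samples:
            t = float(rng.lognormal(mu, cfg.noise_sigma)) * tumor_scale
            a = float(rng.lognormal(mu, cfg.noise_sigma)) * adjacent_scale
            if cfg.sparsity > 0:
                if rng.random() < cfg.sparsity:
                    t = 0.0
                if rng.random() < cfg.sparsity:
                    a = 0.0
            pairs.append((sample, t, a))
        return tuple(pairs)

    studies: list[PairedExpression] = []
    truth: dict[str, list[str]] = {"up": [], "down": []}
    for i in range(cfg.n_planted_up):
        str_id = f"UP{i + 1:03d}"
        truth["up"].append(str_id)
        studies.append(PairedExpression(str_id, draw_pairs(cfg.effect_fold, 1.0)))
    for i in range(cfg.n_planted_down):
        str_id = f"DOWN{i + 1:03d}"
        truth["down"].append(str_id)
        studies.append(PairedExpression(str_id, draw_pairs(1.0, cfg.effect_fold)))
    for i in range(cfg.n_null):
        studies.append(PairedExpression(f"NULL{i + 1:04d}", draw_pairs(1.0, 1.0)))
    return studies, truth


# --------------------------------------------------------------------------- #
# cohort


def _hwe_genotype_probs(freqs: Mapping[int, float]) -> tuple[list[Genotype], np.ndarray]:
    alleles = sorted(freqs)
    genotypes: list[Genotype] = []
    probs: list[float] = []
    for i, a in enumerate(alleles):
        for b in alleles[i:]:
            genotypes.append(Genotype(a, b))
            p = freqs[a] ** 2 if a == b else 2 * freqs[a] * freqs[b]
            probs.append(p)
    arr = np.array(probs)
    return genotypes, arr / arr.sum()


def _case_genotype_probs(cfg: CohortConfig) -> tuple[list[Genotype], np.ndarray]:
    if cfg.genotype_or is None:
        return _hwe_genotype_probs(cfg.case_allele_freqs)
    # tilt the control HWE distribution by per-genotype odds ratios
    genotypes, probs = _hwe_genotype_probs(cfg.control_allele_freqs)
    tilts = np.array([cfg.genotype_or.get(str(g), 1.0) for g in genotypes])
    tilted = probs * tilts
    return genotypes, tilted / tilted.sum()


def gen_cohort(cfg: CohortConfig, seed: int = 0) -> list[SubjectRecord]:
    """Simulate a case-control cohort.

    Genotypes are drawn under Hardy-Weinberg within each arm from the
    arm-specific allele frequencies (or, when ``genotype_or`` is set, from
    the control HWE distribution tilted genotype-wise in the case arm).
    Cases receive a Gleason score whose odds of being >= 8 scale with the
    number of 11-repeat copies; survival times are exponential with
    genotype-dependent hazards, censored at ``followup_months``.
    """
    rng = np.random.default_rng(seed)
    subjects: list[SubjectRecord] = []

    control_gts, control_p = _hwe_genotype_probs(cfg.control_allele_freqs)
    case_gts, case_p = _case_genotype_probs(cfg)

    for arm, n, gts, probs, age_mean, fh_prob in (
        ("case", cfg.n_cases, case_gts, case_p, cfg.age_mean_case, cfg.family_history_prob_case),
        ("control", cfg.n_controls, control_gts, control_p, cfg.age_mean_control,
         cfg.family_history_prob_control),
    ):
        gt_idx = rng.choice(len(gts), size=n, p=probs)
        ages = rng.normal(age_mean, cfg.age_sd, size=n)
        fh = rng.random(n) < fh_prob
        for i in range(n):
            genotype = gts[gt_idx[i]]
            gleason = None
            time = cfg.followup_months
            event = False
            event_pca = False
            if arm == "case":
                n11 = (genotype.a1 == 11) + (genotype.a2 == 11)
                odds = cfg.baseline_aggressive_odds * cfg.gleason_or**n11
                aggressive = rng.random() < odds / (1 + odds)
                gleason = int(rng.integers(8, 11)) if aggressive else int(rng.integers(6, 8))
                hazard = cfg.base_hazard * cfg.hazard_multipliers.get(str(genotype), 1.0)
                t = float(rng.exponential(1.0 / hazard)) if hazard > 0 else math.inf
                if t < cfg.followup_months:
                    time, event = t, True
                    event_pca = bool(rng.random() < cfg.pca_specific_frac)
            subjects.append(
                SubjectRecord(
                    id=f"{arm[:2].upper()}{i + 1:05d}",
                    status=arm,
                    genotype=genotype,
                    age=float(round(ages[i], 1)),
                    family_history=bool(fh[i]),
                    gleason=gleason,
                    time=float(round(time, 2)),
                    event_all_cause=event,
                    event_pca_specific=event_pca,
                )
            )
    return subjects
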