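"""Case-control genetics for a multi-allelic STR: tabulation, odds ratios,
logistic models, Hardy-Weinberg, bootstrap, aggressiveness and survival.

The unit of analysis is an unordered allele pair (genotype) per subject,
e.g. 11/12 for a TG dinucleotide repeat with 11 and 12 repeat units.
Association is tested genotype-wise against the most common homozygous
genotype as reference, with crude cross-product odds ratios, unadjusted and
covariate-adjusted logistic regression (the two agree exactly in the
single-predictor case), and a stratified bootstrap for resampling-based
confidence intervals and p-values. Disease aggressiveness dichotomises the
Gleason score at 8; survival uses Kaplan-Meier curves with the log-rank
(Mantel-Cox) test and an observed/expected hazard ratio.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats


# --------------------------------------------------------------------------- #
# genotype tabulation


@dataclass(frozen=True, slots=True, order=True)
class Genotype:
    """An unordered allele pair, normalised so a1 <= a2."""

    a1: int
    a2: int

    # custom __init__ so the pair is normalised ascending on construction
    def __init__(self, a1: int, a2: int) -> None:
        lo, hi = (a1, a2) if a1 <= a2 else (a2, a1)
        object.__setattr__(self, "a1", lo)
        object.__setattr__(self, "a2", hi)

    @classmethod
    def parse(cls, text: str) -> "Genotype":
        """Parse ``"11/12"``-style notation."""
        a, b = text.split("/")
        return cls(int(a), int(b))

    @property
    def is_heterozygous(self) -> bool:
        return self.a1 != self.a2

    def __str__(self) -> str:
        return f"{self.a1}/{self.a2}"


#: group label -> genotype -> subject count (the published-table shape)
GenotypeCountTable = Mapping[str, Mapping[Genotype, int]]


@dataclass(frozen=True)
class SubjectRecord:
    """One cohort member."""

    id: str
    status: str  # "case" | "control"
    genotype: Genotype
    age: float
    family_history: bool | None = None
    gleason: int | None = None
    time: float = 0.0  # follow-up, months
    event_all_cause: bool = False
    event_pca_specific: bool = False

    def __post_init__(self) -> None:
        if self.status not in ("case", "control"):
            raise ValueError("status must be 'case' or 'control'")
        if self.gleason is not None and self.status != "case":
            raise ValueError("gleason is defined only for cases")
        if self.time < 0:
            raise ValueError("follow-up time must be >= 0")


def genotype_counts(subjects: Iterable[SubjectRecord]) -> dict[str, dict[Genotype, int]]:
    """Tabulate subjects into the group -> genotype -> count table shape."""
    table: dict[str, Counter] = {}
    for s in subjects:
        table.setdefault(s.status, Counter())[s.genotype] += 1
    return {g: dict(c) for g, c in table.items()}


def allele_counts_from_genotypes(table: GenotypeCountTable, group: str) -> dict[int, int]:
    """Per-allele counts for one group: homozygotes contribute 2 copies,
    heterozygotes 1 per constituent allele. Total = 2 x subjects."""
    if group not in table:
        raise KeyError(f"unknown group {group!r}; have {sorted(table)}")
    counts: Counter[int] = Counter()
    for gt, n in table[group].items():
        counts[gt.a1] += n
        counts[gt.a2] += n
    return dict(sorted(counts.items()))


def allele_frequencies(counts: Mapping[int, int]) -> dict[int, float]:
    """Allele frequencies in percent (of 2N chromosomes)."""
    total = sum(counts.values())
    if total <= 0:
        raise ValueError("total allele count must be positive")
    return {a: 100.0 * c / total for a, c in sorted(counts.items())}


def round_half_up(x: float, ndigits: int = 0) -> float:
    """Display rounding: half-up, as in the published tables."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def observed_alleles_in_table(table: GenotypeCountTable) -> list[int]:
    """Ascending union of alleles over all groups (rows with count > 0)."""
    alleles: set[int] = set()
    for group_counts in table.values():
        for gt, n in group_counts.items():
            if n > 0:
                alleles.update((gt.a1, gt.a2))
    return sorted(alleles)


def restrict_genotypes(
    subjects: Iterable[SubjectRecord],
    kept: frozenset[Genotype] = frozenset({Genotype(11, 11), Genotype(11, 12), Genotype(12, 12)}),
) -> tuple[list[SubjectRecord], int]:
    """Drop subjects whose genotype is outside ``kept`` (rare genotypes are
    excluded before regression); returns (kept subjects, number removed)."""
    kept_subjects = []
    removed = 0
    for s in subjects:
        if s.genotype in kept:
            kept_subjects.append(s)
        else:
            removed += 1
    return kept_subjects, removed


def heterozygosity(counts: Mapping[Genotype, int]) -> float:
    """Observed heterozygosity: fraction of subjects with two distinct alleles."""
    total = sum(counts.values())
    if total <= 0:
        raise ValueError("no subjects")
    return sum(n for gt, n in counts.items() if gt.is_heterozygous) / total


# --------------------------------------------------------------------------- #
# odds ratios and logistic regression


@dataclass(frozen=True)
class AssociationResult:
    term: str
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    method: str

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.odds_ratio <= self.ci_high):
            raise ValueError("Wald interval must bracket the odds ratio")


def crude_or(a: int, b: int, c: int, d: int, term: str = "exposure") -> AssociationResult:
    """Cross-product odds ratio of a 2x2 table with Wald 95% CI and p.

    Cells: a = exposed cases, b = reference cases, c = exposed controls,
    d = reference controls. Any zero cell triggers the Haldane-Anscombe +0.5
    correction to all cells (flagged in ``method``); two zero cells on one
    margin make the OR undefined and raise.
    """
    cells = (a, b, c, d)
    if any(x < 0 for x in cells):
        raise ValueError("cell counts must be >= 0")
    for m1, m2 in ((a, b), (c, d), (a, c), (b, d)):
        if m1 == 0 and m2 == 0:
            raise ValueError("a 2x2 margin is entirely zero; OR undefined")
    method = "crude cross-product (Wald)"
    if 0 in cells:
        a, b, c, d = (x + 0.5 for x in cells)  # type: ignore[assignment]
        method += " +0.5 Haldane-Anscombe"
    or_ = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = math.log(or_) / se
    p = 2 * stats.norm.sf(abs(z))
    return AssociationResult(
        term=term,
        odds_ratio=or_,
        ci_low=math.exp(math.log(or_) - 1.959963984540054 * se),
        ci_high=math.exp(math.log(or_) + 1.959963984540054 * se),
        p_value=float(p),
        method=method,
    )


class LogisticFitError(RuntimeError):
    """Non-convergence or separation in a logistic fit."""


def fit_logistic(
    design: pd.DataFrame, response: Sequence[int] | np.ndarray
) -> list[AssociationResult]:
    """Maximum-likelihood binary logistic regression (Newton/IRLS via
    statsmodels; tolerance 1e-8, max 50 iterations). ``design`` holds the
    predictor columns (no intercept — one is added); results are per
    predictor term: OR = exp(coef), Wald 95% CI and p."""
    import statsmodels.api as sm

    X = sm.add_constant(pd.DataFrame(design), has_constant="add")
    y = np.asarray(response, dtype=float)
    try:
        fit = sm.Logit(y, X).fit(disp=0, maxiter=50, tol=1e-8)
    except Exception as exc:  # statsmodels raises several separation/LinAlg types
        raise LogisticFitError(
            f"logistic fit failed for terms {list(design.columns)}: {exc}"
        ) from exc
    if not fit.mle_retvals.get("converged", True):
        raise LogisticFitError(f"no convergence for terms {list(design.columns)}")
    conf = fit.conf_int(alpha=0.05)
    results = []
    for term in [*design.columns, "const"]:  # intercept reported last
        coef = fit.params[term]
        results.append(
            AssociationResult(
                term=str(term),
                odds_ratio=math.exp(coef),
                ci_low=math.exp(conf.loc[term, 0]),
                ci_high=math.exp(conf.loc[term, 1]),
                p_value=float(fit.pvalues[term]),
                method="binary logistic regression (Wald)",
            )
        )
    return results


def genotype_design(
    subjects: Sequence[SubjectRecord],
    exposed: Genotype,
    ref: Genotype,
    adjust: Sequence[str] = (),
) -> tuple[pd.DataFrame, np.ndarray]:
    """Indicator design (exposed genotype vs reference) with optional
    age / family-history covariates; subjects with other genotypes, or with a
    missing covariate, are dropped."""
    rows = []
    for s in subjects:
        if s.genotype not in (exposed, ref):
            continue
        row = {f"genotype[{exposed}]": 1.0 if s.genotype == exposed else 0.0}
        if "age" in adjust:
            row["age"] = s.age
        if "family_history" in adjust:
            if s.family_history is None:
                continue
            row["family_history"] = 1.0 if s.family_history else 0.0
        row["_y"] = 1.0 if s.status == "case" else 0.0
        rows.append(row)
    frame = pd.DataFrame(rows)
    y = frame.pop("_y").to_numpy()
    return frame, y


def genotype_or(
    subjects: Sequence[SubjectRecord],
    exposed: Genotype,
    ref: Genotype,
    adjust: Sequence[str] = (),
) -> AssociationResult:
    """Odds ratio for carrying ``exposed`` vs ``ref`` genotype, by logistic
    regression (optionally covariate-adjusted)."""
    X, y = genotype_design(subjects, exposed, ref, adjust)
    return fit_logistic(X, y)[0]


def allele_observations(subjects: Iterable[SubjectRecord]) -> list[tuple[int, str]]:
    """Per-allele coding: each subject contributes two (allele, status)
    observations."""
    obs = []
    for s in subjects:
        obs.append((s.genotype.a1, s.status))
        obs.append((s.genotype.a2, s.status))
    return obs


def allelic_or(subjects: Sequence[SubjectRecord], allele: int, coding: str = "per-allele") -> AssociationResult:
    """Allele-level odds ratio under ``"per-allele"`` (2 observations per
    subject) or ``"carrier"`` (dominant, >=1 copy) coding."""
    if coding == "per-allele":
        obs = allele_observations(subjects)
        a = sum(1 for al, st in obs if al == allele and st == "case")
        b = sum(1 for al, st in obs if al != allele and st == "case")
        c = sum(1 for al, st in obs if al == allele and st == "control")
        d = sum(1 for al, st in obs if al != allele and st == "control")
    elif coding == "carrier":
        def carries(s: SubjectRecord) -> bool:
            return allele in (s.genotype.a1, s.genotype.a2)

        a = sum(1 for s in subjects if s.status == "case" and carries(s))
        b = sum(1 for s in subjects if s.status == "case" and not carries(s))
        c = sum(1 for s in subjects if s.status == "control" and carries(s))
        d = sum(1 for s in subjects if s.status == "control" and not carries(s))
    else:
        raise ValueError("coding must be 'per-allele' or 'carrier'")
    result = crude_or(a, b, c, d, term=f"allele[{allele}] ({coding})")
    return result


# --------------------------------------------------------------------------- #
# Hardy-Weinberg


@dataclass(frozen=True)
class HweResult:
    chi2: float
    df: int
    p_value: float
    pooled: bool  # classes with expected < 5 were pooled


def hwe_test(counts: Mapping[Genotype, int], pool_threshold: float = 5.0) -> HweResult:
    """Chi-square goodness-of-fit of observed genotype counts against
    Hardy-Weinberg proportions from the observed allele frequencies.

    Expected counts: n p_i^2 for homozygotes, 2 n p_i p_j for heterozygotes,
    over every genotype constructible from the observed alleles. Classes with
    expected count below ``pool_threshold`` are pooled into one class (flagged).
    df = (#genotype classes - #alleles), clamped to >= 1 after pooling.
    """
    n = sum(counts.values())
    if n <= 0:
        raise ValueError("no subjects")
    allele_counts: Counter[int] = Counter()
    for gt, c in counts.items():
        allele_counts[gt.a1] += c
        allele_counts[gt.a2] += c
    alleles = sorted(allele_counts)
    if len(alleles) < 2:
        raise ValueError("not polymorphic: fewer than two alleles observed")
    freqs = {a: allele_counts[a] / (2 * n) for a in alleles}

    observed: list[float] = []
    expected: list[float] = []
    for i, ai in enumerate(alleles):
        for aj in alleles[i:]:
            gt = Genotype(ai, aj)
            exp = n * (freqs[ai] ** 2 if ai == aj else 2 * freqs[ai] * freqs[aj])
            observed.append(counts.get(gt, 0))
            expected.append(exp)

    obs_arr, exp_arr = np.array(observed, float), np.array(expected, float)
    small = exp_arr < pool_threshold
    pooled = bool(small.sum() > 1)
    if pooled:
        obs_arr = np.append(obs_arr[~small], obs_arr[small].sum())
        exp_arr = np.append(exp_arr[~small], exp_arr[small].sum())
    chi2 = float(((obs_arr - exp_arr) ** 2 / exp_arr).sum())
    df = max(1, len(obs_arr) - len(alleles))
    return HweResult(chi2=chi2, df=df, p_value=float(stats.chi2.sf(chi2, df)), pooled=pooled)


# --------------------------------------------------------------------------- #
# bootstrap


@dataclass(frozen=True)
class BootstrapResult:
    """Percentile CI and two-tailed p for a resampled statistic (log-OR scale
    for the default statistic)."""

    estimate: float
    ci_low: float
    ci_high: float
    p_value: float
    n_resamples: int
    n_redrawn: int


def _log_or_from_counts(a: float, b: float, c: float, d: float) -> float:
    return math.log((a * d) / (b * c))


def bootstrap_or(
    subjects: Sequence[SubjectRecord],
    exposed: Genotype,
    ref: Genotype,
    statistic: Callable[[Sequence[SubjectRecord]], float] | None = None,
    n_resamples: int = 1000,
    seed: int = 0,
) -> BootstrapResult:
    """Stratified bootstrap of an association statistic.

    Subjects are resampled with replacement within the case and control
    strata. The default statistic is the log odds ratio of carrying the
    ``exposed`` vs the ``ref`` genotype; any subjects->real callable may be
    supplied instead. Resamples on which the statistic is undefined (empty
    2x2 cell, exception, non-finite value) are redrawn and counted. The
    two-tailed p is 2 x min(frac(stat <= 0), frac(stat >= 0)), floored at
    2 / n_resamples. Fully reproducible for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    cases = [s for s in subjects if s.status == "case"]
    controls = [s for s in subjects if s.status == "control"]
    if not cases or not controls:
        raise ValueError("both case and control strata must be non-empty")

    if statistic is None:
        stats_arr, n_redrawn = _bootstrap_default_log_or(
            cases, controls, exposed, ref, n_resamples, rng
        )
        point = _default_log_or(subjects, exposed, ref)
    else:
        values: list[float] = []
        n_redrawn = 0
        max_draws = 50 * n_resamples
        draws = 0
        while len(values) < n_resamples:
            draws += 1
            if draws > max_draws:
                raise RuntimeError("bootstrap: too many undefined resamples")
            resample = [cases[i] for i in rng.integers(0, len(cases), len(cases))]
            resample += [controls[i] for i in rng.integers(0, len(controls), len(controls))]
            try:
                v = statistic(resample)
            except (ValueError, ZeroDivisionError, KeyError):
                n_redrawn += 1
                continue
            if not math.isfinite(v):
                n_redrawn += 1
                continue
            values.append(v)
        stats_arr = np.array(values)
        point = statistic(subjects)

    ci_low, ci_high = np.percentile(stats_arr, [2.5, 97.5])
    frac_le = float((stats_arr <= 0).mean())
    frac_ge = float((stats_arr >= 0).mean())
    p = max(2 * min(frac_le, frac_ge), 2 / n_resamples)
    return BootstrapResult(
        estimate=float(point),
        ci_low=float(ci_low),
        ci_high=float(ci_high),
        p_value=min(1.0, p),
        n_resamples=n_resamples,
        n_redrawn=n_redrawn,
    )


def _default_log_or(
    subjects: Sequence[SubjectRecord], exposed: Genotype, ref: Genotype
) -> float:
    a = sum(1 for s in subjects if s.status == "case" and s.genotype == exposed)
    b = sum(1 for s in subjects if s.status == "case" and s.genotype == ref)
    c = sum(1 for s in subjects if s.status == "control" and s.genotype == exposed)
    d = sum(1 for s in subjects if s.status == "control" and s.genotype == ref)
    return _log_or_from_counts(a, b, c, d)


def _bootstrap_default_log_or(
    cases: Sequence[SubjectRecord],
    controls: Sequence[SubjectRecord],
    exposed: Genotype,
    ref: Genotype,
    n_resamples: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, int]:
    """Vectorised stratified resampling for the default genotype log-OR:
    resampling subjects within a stratum and counting genotype categories is
    a multinomial draw over (exposed, ref, other)."""

    def category_probs(stratum: Sequence[SubjectRecord]) -> tuple[np.ndarray, int]:
        n_exp = sum(1 for s in stratum if s.genotype == exposed)
        n_ref = sum(1 for s in stratum if s.genotype == ref)
        n = len(stratum)
        return np.array([n_exp, n_ref, n - n_exp - n_ref]) / n, n

    p_case, n_case = category_probs(cases)
    p_ctrl, n_ctrl = category_probs(controls)

    out = np.empty(n_resamples)
    filled = 0
    n_redrawn = 0
    for _ in range(200):  # redraw rounds; virtually always 1-2
        need = n_resamples - filled
        if need == 0:
            break
        case_draw = rng.multinomial(n_case, p_case, size=need)
        ctrl_draw = rng.multinomial(n_ctrl, p_ctrl, size=need)
        a, b = case_draw[:, 0].astype(float), case_draw[:, 1].astype(float)
        c, d = ctrl_draw[:, 0].astype(float), ctrl_draw[:, 1].astype(float)
        ok = (a > 0) & (b > 0) & (c > 0) & (d > 0)
        n_redrawn += int((~ok).sum())
        vals = np.log((a[ok] * d[ok]) / (b[ok] * c[ok]))
        out[filled : filled + vals.size] = vals
        filled += vals.size
    else:
        raise RuntimeError("bootstrap: too many undefined resamples")
    return out, n_redrawn


# --------------------------------------------------------------------------- #
# aggressiveness, survival, genotype-expression


def dichotomize_gleason(gs: int) -> str:
    """Gleason score grouping: < 8 less aggressive, >= 8 aggressive."""
    if not 2 <= gs <= 10:
        raise ValueError(f"Gleason score out of range 2..10: {gs}")
    return "aggressive" if gs >= 8 else "less aggressive"


@dataclass(frozen=True)
class KMResult:
    """Kaplan-Meier curves with the log-rank test and, for two groups, the
    observed/expected hazard ratio."""

    curves: dict[str, pd.DataFrame]  # columns: time, survival
    chi2: float
    p_value: float
    hazard_ratio: float | None
    observed: dict[str, float] = field(default_factory=dict)
    expected: dict[str, float] = field(default_factory=dict)


def _logrank_oe(groups: Mapping[str, Sequence[tuple[float, bool]]]) -> tuple[dict, dict]:
    """Observed and expected event counts per group over distinct event times
    (expected from the at-risk proportions, the Mantel-Cox tie handling)."""
    labels = sorted(groups)
    times = {}
    for label in labels:
        for t, e in groups[label]:
            if e:
                times[t] = None
    observed = {lb: 0.0 for lb in labels}
    expected = {lb: 0.0 for lb in labels}
    for t in sorted(times):
        at_risk = {lb: sum(1 for ti, _ in groups[lb] if ti >= t) for lb in labels}
        events = {lb: sum(1 for ti, ei in groups[lb] if ti == t and ei) for lb in labels}
        n_t = sum(at_risk.values())
        d_t = sum(events.values())
        for lb in labels:
            observed[lb] += events[lb]
            expected[lb] += d_t * at_risk[lb] / n_t
    return observed, expected


def km_logrank(groups: Mapping[str, Sequence[tuple[float, bool]]]) -> KMResult:
    """Kaplan-Meier estimates per group and the log-rank (Mantel-Cox) test.

    ``groups`` maps a label to (time, event) pairs. For exactly two groups the
    hazard ratio (O1/E1)/(O2/E2) is reported with groups in sorted-label
    order. Raises on an empty group or when no events occur at all.
    """
    from lifelines import KaplanMeierFitter
    from lifelines.statistics import multivariate_logrank_test

    if len(groups) < 2:
        raise ValueError("at least two groups are required")
    durations, events, labels = [], [], []
    curves: dict[str, pd.DataFrame] = {}
    for label in sorted(groups):
        data = list(groups[label])
        if not data:
            raise ValueError(f"group {label!r} has no subjects")
        t = [x for x, _ in data]
        e = [bool(x) for _, x in data]
        durations += t
        events += e
        labels += [label] * len(data)
        kmf = KaplanMeierFitter()
        kmf.fit(t, e, label=str(label))
        sf = kmf.survival_function_
        curves[label] = pd.DataFrame(
            {"time": sf.index.to_numpy(), "survival": sf.iloc[:, 0].to_numpy()}
        )
    if not any(events):
        raise ValueError("no events in any group; log-rank test undefined")
    test = multivariate_logrank_test(durations, labels, events)
    hr = None
    observed, expected = _logrank_oe(groups)
    if len(groups) == 2:
        lb1, lb2 = sorted(groups)
        if observed[lb2] > 0 and expected[lb1] > 0 and expected[lb2] > 0:
            hr = (observed[lb1] / expected[lb1]) / (observed[lb2] / expected[lb2])
    return KMResult(
        curves=curves,
        chi2=float(test.test_statistic),
        p_value=float(test.p_value),
        hazard_ratio=hr,
        observed=observed,
        expected=expected,
    )


def ks_two_sample(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov test (asymptotic p): D is the supremum
    distance between the two empirical CDFs."""
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    res = stats.ks_2samp(x, y, method="asymp")
    return float(res.statistic), float(res.pvalue)


# --------------------------------------------------------------------------- #
# cohort I/O


_COHORT_COLUMNS = [
    "id", "status", "genotype", "age", "family_history", "gleason",
    "time", "event_all_cause", "event_pca_specific",
]


def write_cohort(subjects: Iterable[SubjectRecord], dest: str | Path) -> None:
    rows = []
    for s in subjects:
        rows.append(
            {
                "id": s.id,
                "status": s.status,
                "genotype": str(s.genotype),
                "age": s.age,
                "family_history": "" if s.family_history is None else int(s.family_history),
                "gleason": "" if s.gleason is None else s.gleason,
                "time": s.time,
                "event_all_cause": int(s.event_all_cause),
                "event_pca_specific": int(s.event_pca_specific),
            }
        )
    pd.DataFrame(rows, columns=_COHORT_COLUMNS).to_csv(dest, index=False)


def read_cohort(source: str | Path) -> list[SubjectRecord]:
    frame = pd.read_csv(source, dtype={"genotype": str})
    subjects = []
    for row in frame.itertuples(index=False):
        fh = row.family_history
        gl = row.gleason
        subjects.append(
            SubjectRecord(
                id=str(row.id),
                status=row.status,
                genotype=Genotype.parse(row.genotype),
                age=float(row.age),
                family_history=None if pd.isna(fh) else bool(int(fh)),
                gleason=None if pd.isna(gl) else int(gl),
                time=float(row.time),
                event_all_cause=bool(row.event_all_cause),
                event_pca_specific=bool(row.event_pca_specific),
            )
        )
    return subjects
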