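"""Candidate prioritisation over paired tumor / adjacent-normal STR expression.

The ranking metric favours STRs that are both consistently differentially
expressed and widely expressed: for each STR, sum the per-sample fold change
(tumor / adjacent) over the pairs that express it, and multiply by the number
of expressing pairs. The top-k scores nominate over-expressed candidates and
the bottom-k under-expressed ones.

Zero handling: a pair where both members are zero does not contribute and
does not count as expressing; a zero in exactly one member gets a small
pseudocount (default 0.01, FPKM scale) so the ratio stays finite. A log2
mode is offered because raw ratios compress under-expression toward zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence


@dataclass(frozen=True)
class PairedExpression:
    """Per-STR paired expression values, one (tumor, adjacent) pair per sample."""

    str_id: str
    pairs: tuple[tuple[str, float, float], ...]  # (sample_id, tumor, adjacent)

    def __post_init__(self) -> None:
        sample_ids = [s for s, _, _ in self.pairs]
        if len(set(sample_ids)) != len(sample_ids):
            raise ValueError("sample_ids must be unique within one STR")
        if any(t < 0 or a < 0 for _, t, a in self.pairs):
            raise ValueError("expression values must be non-negative")


@dataclass(frozen=True)
class PriorityScore:
    str_id: str
    n_expressed: int
    sum_fold_change: float
    score: float


def sample_fold_change(
    tumor: float, adjacent: float, eps: float = 0.01, log2_mode: bool = False
) -> float | None:
    """Tumor/adjacent fold change for one pair; None when neither member is
    expressed. ``eps`` is added only to zero terms."""
    if tumor < 0 or adjacent < 0:
        raise ValueError("expression values must be non-negative")
    if eps <= 0:
        raise ValueError("eps must be positive")
    if tumor == 0 and adjacent == 0:
        return None
    ratio = (tumor if tumor > 0 else eps) / (adjacent if adjacent > 0 else eps)
    return math.log2(ratio) if log2_mode else ratio


def priority_score(
    pe: PairedExpression, eps: float = 0.01, log2_mode: bool = False
) -> PriorityScore:
    """Sum of per-pair fold changes times the number of expressing pairs."""
    if not pe.pairs:
        raise ValueError("at least one pair is required")
    total = 0.0
    n_expressed = 0
    for _, tumor, adjacent in pe.pairs:
        fc = sample_fold_change(tumor, adjacent, eps=eps, log2_mode=log2_mode)
        if fc is None:
            continue
        n_expressed += 1
        total += fc
    return PriorityScore(
        str_id=pe.str_id,
        n_expressed=n_expressed,
        sum_fold_change=total,
        score=total * n_expressed,
    )


def select_candidates(
    scores: Iterable[PriorityScore], k: int = 4
) -> tuple[list[str], list[str]]:
    """Ids of the k highest- and k lowest-scoring STRs (ties broken by
    lexicographic str_id, deterministically)."""
    ranked = sorted(scores, key=lambda s: (s.score, s.str_id))
    if len(ranked) < 2 * k:
        raise ValueError(f"need at least {2 * k} scores, got {len(ranked)}")
    bottom = [s.str_id for s in ranked[:k]]
    top = sorted(ranked[-k:], key=lambda s: (-s.score, s.str_id))
    return [s.str_id for s in top], bottom


def rank_table(scores: Sequence[PriorityScore]):
    """Ranked DataFrame (descending score; rank 1 = highest)."""
    import pandas as pd

    frame = pd.DataFrame(
        [(s.str_id, s.n_expressed, s.sum_fold_change, s.score) for s in scores],
        columns=["str_id", "n_expressed", "sum_fc", "score"],
    ).sort_values(["score", "str_id"], ascending=[False, True], ignore_index=True)
    frame["rank"] = frame.index + 1
    return frame


def paired_expression_from_frame(frame, tumor_suffix=":tumor", adjacent_suffix=":adjacent"):
    """Build :class:`PairedExpression` objects from an expression matrix whose
    columns are ``sample:condition`` (as written by
    :func:`strseek.expression.expression_matrix`)."""
    samples = sorted(
        c[: -len(tumor_suffix)] for c in frame.columns if c.endswith(tumor_suffix)
    )
    out: list[PairedExpression] = []
    for str_id, row in frame.iterrows():
        pairs = tuple(
            (s, float(row[s + tumor_suffix]), float(row[s + adjacent_suffix]))
            for s in samples
        )
        out.append(PairedExpression(str_id=str(str_id), pairs=pairs))
    return out


def write_ranked(scores: Sequence[PriorityScore], dest: str | Path) -> None:
    rank_table(scores).to_csv(dest, sep="\t", index=False)
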