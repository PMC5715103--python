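"""Published genotype-count tables for the TG-PCA3 dinucleotide repeat.

These are the printed cohort tabulations used as desk-scale inputs to the
association stage: case/control genotype counts for prostate-cancer risk, and
the case-only split by Gleason score (< 8 less aggressive vs >= 8
aggressive). Counts are transcribed as printed; the genotype rows sum to
1,156 cases / 1,213 controls while the cohort description reports 1,153 /
1,210 — the three-subject discrepancy is in the source and is carried
through unchanged.
"""

from __future__ import annotations

from .assoc import Genotype


def _table(rows: dict[str, int]) -> dict[Genotype, int]:
    return {Genotype.parse(k): v for k, v in rows.items()}


def tg_pca3_case_control() -> dict[str, dict[Genotype, int]]:
    """Case/control genotype counts for the TG-PCA3 STR (repeat-count alleles)."""
    return {
        "case": _table(
            {
                "10/10": 2,
                "10/11": 2,
                "10/12": 3,
                "9/11": 1,
                "11/11": 680,
                "11/12": 392,
                "11/13": 2,
                "12/12": 73,
                "12/13": 1,
            }
        ),
        "control": _table(
            {
                "10/10": 3,
                "10/11": 1,
                "10/12": 0,
                "9/11": 0,
                "11/11": 634,
                "11/12": 461,
                "11/13": 0,
                "12/12": 113,
                "12/13": 1,
            }
        ),
    }


def tg_pca3_by_gleason() -> dict[str, dict[Genotype, int]]:
    """Case-only genotype counts split at Gleason score 8 (< 8 vs >= 8)."""
    return {
        "gs_lt8": _table(
            {
                "10/10": 2,
                "10/11": 2,
                "10/12": 2,
                "9/11": 0,
                "11/11": 534,
                "11/12": 309,
                "11/13": 2,
                "12/12": 64,
                "12/13": 1,
            }
        ),
        "gs_ge8": _table(
            {
                "10/10": 0,
                "10/11": 0,
                "10/12": 1,
                "9/11": 1,
                "11/11": 86,
                "11/12": 52,
                "11/13": 0,
                "12/12": 5,
                "12/13": 0,
            }
        ),
    }
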