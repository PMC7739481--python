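"""Questionnaire scoring and summary statistics for the breast-cancer survey.

Implements the scoring rules of two instruments and the two summary
statistics recomputable from published aggregates:

* **SADS** (Social Avoidance and Distress Scale): 28 yes/no items, 14 per
  subscale; a total above 9 flags clinically relevant avoidance/distress.
* **SES** (Rosenberg Self-Esteem Scale): 10 four-point items, total 10-40;
  cut points <= 25 low, 26-32 moderate, >= 33 high.  The published cuts
  leave a total of exactly 25 unassigned ("lower than 25" vs "26-32"); it
  is assigned to *low* here so the categories partition the range.  The
  standard instrument reverse-scores half the items; the source survey does
  not mention reverse coding, so none is applied by default and a
  ``reverse_coded`` flag restores standard scoring.
* a one-sample t statistic from printed mean/SD/n against a population
  reference, and
* a Pearson chi-square test on an r x c contingency table (no continuity
  correction).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Tuple

import numpy as np
from scipy.stats import chi2_contingency

SADS_ITEMS_PER_SUBSCALE = 14
SES_N_ITEMS = 10
SADS_FLAG_THRESHOLD = 9  # flagged iff total strictly above
SES_LOW_MAX = 25
SES_MODERATE_MAX = 32
# standard Rosenberg reverse-keyed items (0-based positions)
SES_REVERSE_ITEMS = (2, 4, 5, 7, 8)


@dataclass(frozen=True)
class QuestionnaireRecord:
    """One respondent: 28 binary SADS answers then 10 four-point SES answers.

    ``sads_items`` holds the 14 avoidance items followed by the 14 distress
    items, each 0 (no) or 1 (yes); ``ses_items`` are in {1, 2, 3, 4}.
    """

    sads_items: Tuple[int, ...]
    ses_items: Tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.sads_items) != 2 * SADS_ITEMS_PER_SUBSCALE:
            raise ValueError(
                f"SADS needs {2 * SADS_ITEMS_PER_SUBSCALE} items, got {len(self.sads_items)}"
            )
        if any(v not in (0, 1) for v in self.sads_items):
            raise ValueError("SADS items must be binary (0 = no, 1 = yes)")
        if len(self.ses_items) != SES_N_ITEMS:
            raise ValueError(f"SES needs {SES_N_ITEMS} items, got {len(self.ses_items)}")
        if any(v not in (1, 2, 3, 4) for v in self.ses_items):
            raise ValueError("SES items must be integers in 1..4")


def score_sads(record: QuestionnaireRecord) -> Tuple[int, int, int, bool]:
    """Subscale sums, total, and the above-9 flag.

    Returns ``(avoidance, distress, total, flagged)`` where ``flagged`` is
    True iff the total exceeds 9.
    """
    avoidance = sum(record.sads_items[:SADS_ITEMS_PER_SUBSCALE])
    distress = sum(record.sads_items[SADS_ITEMS_PER_SUBSCALE:])
    total = avoidance + distress
    return avoidance, distress, total, total > SADS_FLAG_THRESHOLD


def classify_ses(record: QuestionnaireRecord, reverse_coded: bool = False) -> Tuple[int, str]:
    """SES total and self-esteem category (low / moderate / high).

    ``reverse_coded`` applies the standard instrument's reverse keying of
    items 3, 5, 6, 8 and 9 (1-based) before summing.
    """
    items = list(record.ses_items)
    if reverse_coded:
        for i in SES_REVERSE_ITEMS:
            items[i] = 5 - items[i]
    total = sum(items)
    if total <= SES_LOW_MAX:
        category = "low"
    elif total <= SES_MODERATE_MAX:
        category = "moderate"
    else:
        category = "high"
    return total, category


@dataclass(frozen=True)
class SummaryStats:
    """Printed aggregates of a sample plus the population reference mean."""

    mean: float
    sd: float
    n: int
    reference_mean: float

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise ValueError("sd must be positive")
        if self.n < 2:
            raise ValueError("n must be >= 2")


def one_sample_t_from_summary(stats: SummaryStats) -> Tuple[float, int]:
    """One-sample t statistic (mean - mu0) / (sd / sqrt(n)) and df = n - 1."""
    t = (stats.mean - stats.reference_mean) / (stats.sd / np.sqrt(stats.n))
    return float(t), stats.n - 1


def chi_square_contingency(table: Sequence[Sequence[float]]) -> Tuple[float, int]:
    """Pearson chi-square statistic and df of an r x c contingency table.

    Expected counts come from the margins; no Yates continuity correction
    is applied (the published statistics use the uncorrected form).
    """
    counts = np.asarray(table, dtype=float)
    if counts.ndim != 2 or counts.shape[0] < 2 or counts.shape[1] < 2:
        raise ValueError("contingency table must be at least 2 x 2")
    if (counts < 0).any():
        raise ValueError("counts must be non-negative")
    if (counts.sum(axis=1) == 0).any() or (counts.sum(axis=0) == 0).any():
        raise ValueError("every row and column margin must be positive")
    chi2, _, df, _ = chi2_contingency(counts, correction=False)
    return float(chi2), int(df)
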