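"""Descriptive layer: rank correlation, repeat-lavage comparison, summary
tables, the all-score overlap interval, and 2x2 cross-tabulation.

These operations reproduce the descriptive analyses that surround the
latent-class model: how strongly the ordinal endoscopy score tracks the
continuous lavage red-cell count, whether performing a lavage itself raises
the count 24 h later, and the agreement table between the two binary calls
(TBE score >= 1 vs BALFRBC >= threshold).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.anova import AnovaRM

from .cohort import ExamRecord

__all__ = [
    "SpearmanResult",
    "PairedComparison",
    "ScoreSummaryRow",
    "OverlapInterval",
    "CrossTab",
    "spearman_tied",
    "repeated_measures_anova",
    "pooled_summary",
    "score_summary_table",
    "overlap_interval",
    "cross_tabulate",
]


class SpearmanResult(NamedTuple):
    correlation: float
    p_value: float


def spearman_tied(scores: Sequence[float], counts: Sequence[float]) -> SpearmanResult:
    """Spearman rank correlation with average ranks for ties.

    Equivalent to the Pearson correlation of the average-ranked inputs, with
    a two-sided p-value from the t-approximation on n-2 degrees of freedom
    (adequate at the study's n; exact permutation is only worthwhile for
    tiny n and is exercised in the test suite's oracle).
    """
    x = np.asarray(scores, dtype=float)
    y = np.asarray(counts, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"length mismatch: scores has {x.size}, counts has {y.size}")
    if x.size < 3:
        raise ValueError(f"need at least 3 paired observations, got {x.size}")
    if np.ptp(x) == 0:
        raise ValueError("scores input is constant; correlation undefined")
    if np.ptp(y) == 0:
        raise ValueError("counts input is constant; correlation undefined")
    res = stats.spearmanr(x, y)
    return SpearmanResult(float(res.statistic), float(res.pvalue))


@dataclass(frozen=True)
class PairedComparison:
    """One-way repeated-measures ANOVA result plus per-occasion summaries."""

    f_stat: float
    p_value: float
    df_num: float
    df_den: float
    group_means: tuple[float, ...]
    group_sds: tuple[float, ...]


def repeated_measures_anova(
    values_by_occasion: Sequence[Sequence[float]],
    subjects: Optional[Sequence] = None,
) -> PairedComparison:
    """One-way repeated-measures ANOVA across lavage occasions.

    ``values_by_occasion[k][i]`` is subject i's value on occasion k; every
    subject must appear once per occasion.  With two occasions the F
    statistic equals the square of the paired t statistic on (1, n-1)
    degrees of freedom and the p-values coincide.
    """
    arrays = [np.asarray(v, dtype=float) for v in values_by_occasion]
    if len(arrays) < 2:
        raise ValueError("need at least 2 occasions")
    n = arrays[0].size
    bad = [k + 1 for k, a in enumerate(arrays) if a.size != n]
    if bad:
        raise ValueError(
            f"unbalanced design: occasions {bad} have a different number of "
            f"subjects than occasion 1 (n={n})"
        )
    if n < 2:
        raise ValueError("need at least 2 subjects")
    if subjects is None:
        subjects = [f"s{i + 1}" for i in range(n)]
    elif len(subjects) != n:
        raise ValueError(f"subjects has length {len(subjects)}, expected {n}")

    means = tuple(float(a.mean()) for a in arrays)
    sds = tuple(float(a.std(ddof=1)) for a in arrays)
    df_num = float(len(arrays) - 1)
    df_den = float((len(arrays) - 1) * (n - 1))

    wide = np.column_stack(arrays)
    # Occasion effect with zero between-occasion variation: F = 0, p = 1
    # (AnovaRM returns NaN on the 0/0 case).
    if np.allclose(wide - wide[:, :1], 0.0):
        return PairedComparison(0.0, 1.0, df_num, df_den, means, sds)

    long = pd.DataFrame(
        {
            "subject": np.repeat(list(subjects), len(arrays)),
            "occasion": np.tile(np.arange(1, len(arrays) + 1), n),
            "value": wide.reshape(-1),
        }
    )
    table = AnovaRM(long, depvar="value", subject="subject", within=["occasion"]).fit().anova_table
    f = float(table["F Value"].iloc[0])
    p = float(table["Pr > F"].iloc[0])
    if not np.isfinite(f):  # zero residual variance with a real occasion effect
        f, p = np.inf, 0.0
    return PairedComparison(f, p, df_num, df_den, means, sds)


class GroupSummary(NamedTuple):
    n: int
    mean: float
    sd: float


def pooled_summary(group_summaries: Sequence[tuple[int, float, float]]) -> GroupSummary:
    """Pool per-group (n, mean, sd) summaries into one.

    Pooled mean is the n-weighted mean; the pooled SD reconstructs the total
    sum of squares (within-group + between-group) and divides by N-1, so it
    equals the SD that would be computed from the concatenated raw data.
    """
    if not group_summaries:
        raise ValueError("no group summaries given")
    groups = [GroupSummary(int(n), float(m), float(s)) for n, m, s in group_summaries]
    for g in groups:
        if g.n < 2:
            raise ValueError(f"each group needs n >= 2 for a defined SD, got n={g.n}")
    total_n = sum(g.n for g in groups)
    mean = sum(g.n * g.mean for g in groups) / total_n
    ss = sum((g.n - 1) * g.sd**2 + g.n * (g.mean - mean) ** 2 for g in groups)
    return GroupSummary(total_n, mean, float(np.sqrt(ss / (total_n - 1))))


@dataclass(frozen=True)
class ScoreSummaryRow:
    """BALFRBC summary (cells/uL) for one endoscopy score."""

    tbe_score: int
    n: int
    mean: float
    sd: float
    median: float
    min: float
    max: float


def score_summary_table(records: Sequence[ExamRecord]) -> list[ScoreSummaryRow]:
    """Per-TBE-score BALFRBC summaries, one row per observed score."""
    scored = [(r.tbe_score, r.balf_rbc) for r in records if r.tbe_score is not None]
    if not scored:
        raise ValueError("no records with a TBE score")
    df = pd.DataFrame(scored, columns=["tbe_score", "balf_rbc"])
    rows = []
    for score, grp in df.groupby("tbe_score", sort=True):
        v = grp["balf_rbc"]
        rows.append(
            ScoreSummaryRow(
                tbe_score=int(score),
                n=int(v.size),
                mean=float(v.mean()),
                sd=float(v.std(ddof=1)) if v.size > 1 else 0.0,
                median=float(v.median()),
                min=float(v.min()),
                max=float(v.max()),
            )
        )
    return rows


class OverlapInterval(NamedTuple):
    """BALFRBC interval covered by every score's observed range."""

    low: float
    high: float

    @property
    def empty(self) -> bool:
        return self.low > self.high


def overlap_interval(rows: Sequence[ScoreSummaryRow]) -> OverlapInterval:
    """Intersection of the per-score (min, max) ranges.

    A wide overlap means the same red-cell count is compatible with every
    endoscopy grade — the key evidence that the two tests disagree.
    """
    if len(rows) < 2:
        raise ValueError("need at least 2 score rows to intersect")
    return OverlapInterval(max(r.min for r in rows), min(r.max for r in rows))


@dataclass(frozen=True)
class CrossTab:
    """2x2 agreement table of the binary TBE call vs the thresholded BALFRBC
    call, with the derived apparent-prevalence percentages.

    tp: TBE+ & RBC+; fn_balf: TBE+ & RBC- (lavage false negative, taking the
    near-perfectly-specific endoscopy positive at face value);
    fp_tbe_absent: TBE- & RBC+ (hemorrhage missed by endoscopy); tn: both
    negative.
    """

    tp: int
    fn_balf: int
    fp_tbe_absent: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fn_balf, self.fp_tbe_absent, self.tn) < 0:
            raise ValueError("cell counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fn_balf + self.fp_tbe_absent + self.tn

    @property
    def tbe_prevalence_pct(self) -> float:
        """Apparent prevalence (%) if TBE score >= 1 defines EIPH."""
        return 100.0 * (self.tp + self.fn_balf) / self.total

    @property
    def balf_prevalence_pct(self) -> float:
        """Apparent prevalence (%) if BALFRBC above threshold defines EIPH."""
        return 100.0 * (self.tp + self.fp_tbe_absent) / self.total

    @property
    def balf_false_negative_pct(self) -> float:
        """Fraction (%) of events TBE-positive but below the BALFRBC threshold."""
        return 100.0 * self.fn_balf / self.total


def cross_tabulate(
    records: Sequence[ExamRecord],
    threshold: float,
    inclusive: bool = True,
) -> CrossTab:
    """Cross-tabulate the TBE call (score >= 1) against the BALFRBC call.

    A count equal to the threshold is positive under the default inclusive
    convention (>=); ``inclusive=False`` switches to strict >.
    """
    if not threshold > 0:
        raise ValueError(f"threshold must be positive, got {threshold}")
    if not records:
        raise ValueError("no records to tabulate")
    tp = fn = fp = tn = 0
    for r in records:
        if r.tbe_score is None:
            raise ValueError(
                f"record {r.horse_id!r} (occasion {r.occasion}) has no TBE score; "
                "cross-tabulation needs both tests"
            )
        tbe_pos = r.tbe_score >= 1
        rbc_pos = r.balf_rbc >= threshold if inclusive else r.balf_rbc > threshold
        if tbe_pos and rbc_pos:
            tp += 1
        elif tbe_pos:
            fn += 1
        elif rbc_pos:
            fp += 1
        else:
            tn += 1
    return CrossTab(tp, fn, fp, tn)
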