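"""Behavioral metrics: social interaction ratio, zone times, tail-suspension
immobility, and group statistics.

The social interaction (SI) ratio is the time spent in the interaction zone
with the CD1 aggressor present divided by the time with it absent; SI < 1
defines stress-susceptible animals and gates the electrophysiology. Group
summaries are reported as mean +/- SEM; two-group contrasts use Welch's
unequal-variance t-test or a permutation test on the mean difference.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

SIT_DURATION_S = 600.0
TST_SCORED_S = 300.0

NUMERIC_FIELDS = ("time_zone_no_cd1_s", "time_zone_with_cd1_s",
                  "tst_immobility_s", "si_ratio")


def si_ratio(time_with_cd1_s: float, time_no_cd1_s: float) -> float:
    """Social interaction ratio = time-with-CD1 / time-no-CD1 (no clipping)."""
    if time_no_cd1_s <= 0:
        raise ValueError("time in zone without the target must be positive")
    return time_with_cd1_s / time_no_cd1_s


@dataclass
class BehaviorRecord:
    subject: str
    group: str
    time_zone_no_cd1_s: float
    time_zone_with_cd1_s: float
    tst_immobility_s: float

    def __post_init__(self) -> None:
        if not (0 <= self.time_zone_no_cd1_s <= SIT_DURATION_S
                and 0 <= self.time_zone_with_cd1_s <= SIT_DURATION_S):
            raise ValueError(f"zone times must lie in [0, {SIT_DURATION_S}] s")
        if not (0 <= self.tst_immobility_s <= TST_SCORED_S):
            raise ValueError(f"immobility must lie in [0, {TST_SCORED_S}] s")

    @property
    def si_ratio(self) -> float:
        return si_ratio(self.time_zone_with_cd1_s, self.time_zone_no_cd1_s)


def records_to_frame(records: Iterable[BehaviorRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append({
            "subject": r.subject,
            "group": r.group,
            "time_zone_no_cd1_s": r.time_zone_no_cd1_s,
            "time_zone_with_cd1_s": r.time_zone_with_cd1_s,
            "tst_immobility_s": r.tst_immobility_s,
            "si_ratio": r.si_ratio,
        })
    return pd.DataFrame(rows)


def summarize_groups(records: Iterable[BehaviorRecord] | pd.DataFrame) -> pd.DataFrame:
    """Per-group mean, SEM (= SD/sqrt(n), ddof=1) and n for every behavioral
    field. Raises if any group has fewer than two records (SEM undefined)."""
    df = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    counts = df.groupby("group").size()
    small = counts[counts < 2]
    if len(small):
        raise ValueError(f"SEM undefined for group(s) with <2 records: "
                         f"{list(small.index)}")
    out = df.groupby("group")[list(NUMERIC_FIELDS)].agg(["mean", "sem", "count"])
    out.columns = [f"{fieldname}_{stat}" if stat != "count" else f"{fieldname}_n"
                   for fieldname, stat in out.columns]
    return out


def group_compare(values_a: Sequence[float], values_b: Sequence[float],
                  method: str = "welch", n_resamples: int = 9999,
                  seed: int | None = None) -> dict:
    """Two-group contrast.

    ``method="welch"``: Welch's unequal-variance t-test, two-sided.
    ``method="permutation"``: permutation test on the difference of means
    (exact when the number of distinct splits is below ``n_resamples``,
    Monte-Carlo otherwise).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least two values per group")
    if method == "welch":
        res = stats.ttest_ind(a, b, equal_var=False)
        return {"method": "welch", "statistic": float(res.statistic),
                "p": float(res.pvalue)}
    if method == "permutation":
        res = stats.permutation_test(
            (a, b), lambda x, y, axis=-1: np.mean(x, axis=axis) - np.mean(y, axis=axis),
            permutation_type="independent", alternative="two-sided",
            n_resamples=n_resamples, rng=seed, vectorized=True,
        )
        return {"method": "permutation", "statistic": float(res.statistic),
                "p": float(res.pvalue)}
    raise ValueError(f"unknown method {method!r}")


def bonferroni(p_values: Sequence[float]) -> list[float]:
    """Plain alpha/m-style correction: p * m, capped at 1."""
    m = len(p_values)
    return [min(1.0, p * m) for p in p_values]
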