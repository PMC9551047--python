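"""Comparison statistics against reference country series.

Two statistics per country and ensemble member: the relative difference of
period-averaged budgets, Diff = (Ref - Study) / Ref x 100 (%), and the
Pearson correlation of the annual series over the overlapping non-missing
years.  The report carries the mean and standard deviation of both across
the ensemble members.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from scipy import stats


@dataclass
class ComparisonReport:
    """Per-country Diff (%) and Pearson r per member, with ensemble stats."""

    diff: pd.DataFrame  # country x member
    r: pd.DataFrame     # country x member

    @property
    def summary(self) -> pd.DataFrame:
        return pd.DataFrame({
            "diff_mean": self.diff.mean(axis=1),
            "diff_sd": self.diff.std(axis=1, ddof=0),
            "r_mean": self.r.mean(axis=1),
            "r_sd": self.r.std(axis=1, ddof=0),
        })


def relative_difference(reference: pd.Series, study: pd.Series) -> float:
    """Diff (%) of period-averaged values; NaN when the reference mean is 0.

    Both series are annual; only their overlapping non-missing years enter
    the period averages.
    """
    joined = pd.concat({"ref": reference, "study": study}, axis=1).dropna()
    if joined.empty:
        return float("nan")
    ref_avg = joined["ref"].mean()
    if ref_avg == 0:
        return float("nan")
    return float((ref_avg - joined["study"].mean()) / ref_avg * 100.0)


def temporal_correlation(reference: pd.Series, study: pd.Series) -> float:
    """Pearson r over overlapping non-missing years (needs at least 3)."""
    joined = pd.concat({"ref": reference, "study": study}, axis=1).dropna()
    if len(joined) < 3:
        return float("nan")
    r, _ = stats.pearsonr(joined["ref"], joined["study"])
    return float(r)


def compare_members(
    reference: pd.DataFrame,
    members: dict[int, pd.DataFrame],
    period: tuple[int, int] | None = None,
) -> ComparisonReport:
    """Diff and r for every country against every ensemble member.

    ``reference`` and each member table are year-indexed with one column
    per country; ``period`` restricts the years considered (inclusive).
    """
    if period is not None:
        y0, y1 = period
        reference = reference.loc[(reference.index >= y0) & (reference.index <= y1)]
    countries = [c for c in reference.columns]
    diff = pd.DataFrame(index=countries, columns=sorted(members), dtype=float)
    r = diff.copy()
    for m, table in members.items():
        t = table
        if period is not None:
            t = t.loc[(t.index >= period[0]) & (t.index <= period[1])]
        for c in countries:
            if c not in t.columns:
                continue
            diff.at[c, m] = relative_difference(reference[c], t[c])
            r.at[c, m] = temporal_correlation(reference[c], t[c])
    return ComparisonReport(diff=diff, r=r)
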