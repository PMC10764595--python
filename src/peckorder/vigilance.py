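"""Vigilance-test scoring: 0–2 fear rubric and HR/LR contingency table.

Each hen's response to a predator stimulus is graded 0 (no discernible
change), 1 (raises head once, returns to feeding), or 2 (alarm call, rapid
walking, or freezing). Multiple test sessions are reduced to one score per
hen; the group-by-score contingency table with row percentages feeds the
chi-square test in :mod:`peckorder.stats`.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["reduce_sessions", "contingency"]

VALID_SCORES = {0, 1, 2}


def _validate(records: pd.DataFrame) -> pd.DataFrame:
    need = {"hen", "score"}
    if not need <= set(records.columns):
        raise ValueError(f"vigilance records need columns {sorted(need)}")
    bad = set(records["score"].unique()) - VALID_SCORES
    if bad:
        raise ValueError(f"scores outside 0-2 rubric: {sorted(bad)}")
    return records


def reduce_sessions(records: pd.DataFrame, rule: str = "modal") -> pd.Series:
    """Collapse per-session scores to one score per hen.

    ``modal``: most frequent score, ties resolved toward the higher (more
    fearful) score; ``max``: highest score across sessions; ``last``: the
    final session's score (requires a ``session`` column sortable in time).
    """
    records = _validate(records)
    if rule == "modal":
        def _modal(s: pd.Series) -> int:
            counts = s.value_counts()
            top = counts[counts == counts.max()].index
            return int(max(top))
        return records.groupby("hen")["score"].agg(_modal)
    if rule == "max":
        return records.groupby("hen")["score"].max()
    if rule == "last":
        if "session" not in records.columns:
            raise ValueError("'last' reduction needs a session column")
        return (records.sort_values("session").groupby("hen")["score"].last())
    raise ValueError("rule must be 'modal', 'max' or 'last'")


def contingency(records: pd.DataFrame, groups: pd.Series,
                rule: str = "modal") -> tuple[pd.DataFrame, pd.DataFrame]:
    """Group x score count table and row percentages (one decimal).

    Every hen must carry a group label and every group must be non-empty.
    Returns ``(counts, percents)`` with score columns 0, 1, 2.
    """
    scores = reduce_sessions(records, rule=rule)
    unlabelled = scores.index.difference(groups.index)
    if len(unlabelled):
        raise ValueError(f"hens without group label: {list(unlabelled[:5])}")
    df = pd.DataFrame({"score": scores, "group": groups.loc[scores.index]})
    counts = (df.groupby(["group", "score"]).size().unstack(fill_value=0)
              .reindex(columns=sorted(VALID_SCORES), fill_value=0))
    counts = counts.loc[sorted(counts.index)]
    if (counts.sum(axis=1) == 0).any() or len(counts) < 2:
        empty = [g for g in groups.unique() if g not in counts.index
                 or counts.loc[g].sum() == 0]
        raise ValueError(f"empty group(s) in contingency table: {empty}")
    percents = (counts.div(counts.sum(axis=1), axis=0) * 100).round(1)
    return counts, percents
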