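"""Sorted-sum rank aggregation for feeding-competition scores.

Hens are scored 0–3 at 30-second intervals of repeated feeding-competition
tests (3 = feeding at the trough, 2 = close/motivated, 1 = displaced or
circling, 0 = disengaged). Each test yields a per-hen score sum; hens are
ranked within their pen per test (rank 1 = highest sum = most dominant); the
per-test ranks are summed over tests into the "sorted sum". The smaller a
hen's sorted sum, the higher her social rank. Final ranks R1..Rn are assigned
per pen in ascending sorted-sum order; the top two hens per pen form the
high-ranking (HR) group and the bottom two the low-ranking (LR) group.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "OBS_COLUMNS",
    "validate_observations",
    "score_test",
    "rank_test",
    "sorted_sum",
    "assign_groups",
    "build_rank_table",
    "read_competition",
    "write_rank_table",
]

OBS_COLUMNS = ["pen", "hen", "test", "interval", "score"]
VALID_SCORES = {0, 1, 2, 3}


def validate_observations(obs: pd.DataFrame) -> pd.DataFrame:
    """Check the long-format observation table and return it typed.

    Requires columns pen/hen/test/interval/score, scores in {0,1,2,3}, and a
    unique (pen, hen, test, interval) key.
    """
    missing = [c for c in OBS_COLUMNS if c not in obs.columns]
    if missing:
        raise ValueError(f"observation table missing columns: {missing}")
    obs = obs[OBS_COLUMNS].copy()
    bad = set(obs["score"].unique()) - VALID_SCORES
    if bad:
        raise ValueError(f"scores outside 0-3 rubric: {sorted(bad)}")
    key = ["pen", "hen", "test", "interval"]
    if obs.duplicated(key).any():
        dup = obs[obs.duplicated(key, keep=False)].head(3)
        raise ValueError(f"duplicate (pen, hen, test, interval) rows, e.g.\n{dup}")
    return obs


def score_test(obs: pd.DataFrame) -> pd.Series:
    """Per-hen score sum for the observations of one pen and one test.

    Every hen must be observed at the same number of intervals; a hen with
    missing intervals is reported by name rather than silently under-summed.
    """
    obs = validate_observations(obs)
    if obs["pen"].nunique() != 1 or obs["test"].nunique() != 1:
        raise ValueError("score_test expects observations of a single pen and test")
    counts = obs.groupby("hen")["interval"].count()
    if counts.nunique() > 1:
        expected = counts.max()
        short = counts[counts < expected]
        detail = ", ".join(f"{h} ({c}/{expected} intervals)" for h, c in short.items())
        raise ValueError(f"missing intervals for hen(s): {detail}")
    return obs.groupby("hen")["score"].sum().rename("score_sum")


def rank_test(score_sums: pd.Series, tie_mode: str = "average") -> pd.Series:
    """Within-pen ranks for one test: rank 1 = largest score sum.

    ``tie_mode='average'`` gives tied hens the mean of the ranks they span
    (fractional ranks; rank sums stay n(n+1)/2). ``'ordinal'`` breaks ties by
    input order for exact-integer replication.
    """
    if len(score_sums) == 0:
        raise ValueError("empty score-sum input")
    method = {"average": "average", "ordinal": "first"}.get(tie_mode)
    if method is None:
        raise ValueError(f"tie_mode must be 'average' or 'ordinal', got {tie_mode!r}")
    return score_sums.rank(ascending=False, method=method).rename("rank")


def sorted_sum(test_ranks: pd.DataFrame) -> pd.Series:
    """Sum each hen's per-test ranks (rows = hens, columns = tests)."""
    return test_ranks.sum(axis=1).rename("sorted_sum")


def assign_groups(sorted_sums: pd.Series, raw_totals: pd.Series | None = None,
                  n_top: int = 2, n_bottom: int = 2) -> pd.Series:
    """HR/LR/MID labels for one pen from its sorted sums.

    The ``n_top`` smallest sorted sums are HR, the ``n_bottom`` largest LR.
    Boundary ties are broken by higher total raw score across all tests
    (dominant hens accumulate more points), then by hen id lexicographically,
    so the assignment is deterministic and order-independent.
    """
    n = len(sorted_sums)
    if n < n_top + n_bottom:
        raise ValueError(f"pen has {n} hens; need at least {n_top + n_bottom}")
    if raw_totals is None:
        raw_totals = pd.Series(0.0, index=sorted_sums.index)
    order = pd.DataFrame({
        "ss": sorted_sums.to_numpy(),
        "neg_raw": -raw_totals.reindex(sorted_sums.index).fillna(0.0).to_numpy(),
        "hen_id": sorted_sums.index.astype(str),
    }, index=sorted_sums.index).sort_values(["ss", "neg_raw", "hen_id"],
                                            kind="mergesort")
    labels = pd.Series("MID", index=sorted_sums.index, name="group")
    labels.loc[order.index[:n_top]] = "HR"
    labels.loc[order.index[n - n_bottom:]] = "LR"
    return labels


def build_rank_table(obs: pd.DataFrame, tie_mode: str = "average",
                     n_top: int = 2, n_bottom: int = 2) -> pd.DataFrame:
    """Full pipeline: observations -> per-test sums/ranks, sorted sum, groups.

    Returns one row per hen with columns ``pen``, ``sum_t<k>`` and
    ``rank_t<k>`` per test, ``sorted_sum``, ``final_rank`` (average ranks on
    ties, within pen) and ``group`` (HR/LR/MID).
    """
    obs = validate_observations(obs)
    rows = []
    for pen, pen_obs in obs.groupby("pen", sort=True):
        tests = sorted(pen_obs["test"].unique())
        sums = pd.DataFrame({t: score_test(pen_obs[pen_obs["test"] == t])
                             for t in tests})
        if sums.isna().any().any():
            missing = sums[sums.isna().any(axis=1)].index.tolist()
            raise ValueError(f"pen {pen}: hens absent from some tests: {missing}")
        ranks = pd.DataFrame({t: rank_test(sums[t], tie_mode=tie_mode)
                              for t in tests})
        ss = sorted_sum(ranks)
        groups = assign_groups(ss, raw_totals=sums.sum(axis=1),
                               n_top=n_top, n_bottom=n_bottom)
        out = pd.DataFrame(index=sums.index)
        out["pen"] = pen
        for t in tests:
            out[f"sum_t{t}"] = sums[t]
            out[f"rank_t{t}"] = ranks[t]
        out["sorted_sum"] = ss
        out["final_rank"] = ss.rank(method="average")
        out["group"] = groups
        rows.append(out.sort_index())
    table = pd.concat(rows)
    table.index.name = "hen"
    return table


def read_competition(path) -> pd.DataFrame:
    """Read a competition-score TSV (pen, hen, test, interval, score)."""
    obs = pd.read_csv(path, sep="\t", dtype={"pen": str, "hen": str})
    return validate_observations(obs)


def write_rank_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", float_format="%.6g")
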