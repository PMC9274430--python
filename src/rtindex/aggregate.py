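"""Aggregation of per-paper scores into group-level indices and trends.

The rigor-and-transparency index (RTI) of a group (journal, institution,
country, or department, optionally per year) is the mean 10-point score over
that group's *scored* papers — papers with score 0 are not applicable and are
excluded from every mean. Groups are only reported when more than a
configurable number of papers were scored (default >10 per year). A paper
matched to k institutions contributes its score to each of the k institutional
means, and multiply to one institution when the same institution repeats in
its affiliation list; a dedupe switch exists but defaults off.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "records_to_frame",
    "compute_rti",
    "criteria_trends",
    "rank_report",
    "COHORTS",
    "CRITERIA_SETS",
]

# Per-dimension key column; list-valued columns are exploded so one paper can
# credit several groups.
_LIST_DIMENSIONS = {"institution": "institutions", "country": "countries", "department": "departments"}

# Named cohort filters for criteria trends. ``cell_line`` mirrors the
# cell-line reporting cohort (≥1 cell line, no IRB and no IACUC detection);
# ``organism`` keeps papers with at least one organism mention.
COHORTS = {
    "all": lambda types: True,
    "cell_line": lambda types: ("cell_line" in types) and ("irb" not in types) and ("iacuc" not in types),
    "organism": lambda types: "organism" in types,
}

# Compound criteria: a paper addresses the criterion when it mentions any
# member type.
CRITERIA_SETS = {
    "replication": ("replication_statement", "n_replications", "replication_type"),
    "data": ("data_availability", "data_id"),
    "code": ("code_availability", "code_id"),
    "protocol": ("protocol_id",),
}


def records_to_frame(records: Iterable[Mapping]) -> pd.DataFrame:
    """Normalize per-paper score records into a DataFrame.

    Expected keys per record: ``paper_id``, ``year``, ``total``; optional
    ``journal``, ``institutions`` (list of ids), ``countries`` (list),
    ``departments`` (list), ``entity_types`` (collection of detected types).
    """
    df = pd.DataFrame(list(records))
    if df.empty:
        return pd.DataFrame(
            columns=["paper_id", "year", "total", "journal", "institutions",
                     "countries", "departments", "entity_types"]
        )
    for col in ("journal",):
        if col not in df:
            df[col] = None
    for col in ("institutions", "countries", "departments"):
        if col not in df:
            df[col] = [[] for _ in range(len(df))]
    if "entity_types" not in df:
        df["entity_types"] = [set() for _ in range(len(df))]
    else:
        df["entity_types"] = df["entity_types"].map(lambda t: set(t) if t is not None else set())
    return df


def compute_rti(
    records,
    dimension: str,
    threshold: int = 10,
    per_year: bool = True,
    dedupe: bool = False,
) -> pd.DataFrame:
    """Mean score per group(-year) over scored papers.

    Groups with ``n_scored <= threshold`` are omitted (strictly-more-than
    inclusion rule). Output columns: dimension, key, year, n_scored, n_na,
    rti — tidy and stable under input permutation.
    """
    df = records_to_frame(records) if not isinstance(records, pd.DataFrame) else records.copy()
    if df.empty:
        return pd.DataFrame(columns=["dimension", "key", "year", "n_scored", "n_na", "rti"])

    if dimension == "journal":
        df = df[df["journal"].notna()].copy()
        df["key"] = df["journal"]
    elif dimension in _LIST_DIMENSIONS:
        col = _LIST_DIMENSIONS[dimension]
        df = df[df[col].map(lambda v: bool(v))].copy()
        if dedupe:
            df[col] = df[col].map(lambda v: sorted(set(v)))
        df = df.explode(col)
        df["key"] = df[col]
    else:
        raise ValueError(f"unknown dimension: {dimension}")

    group_cols = ["key", "year"] if per_year else ["key"]
    rows = []
    for keys, g in df.groupby(group_cols, sort=True):
        keys = keys if isinstance(keys, tuple) else (keys,)
        scored = g[g["total"] > 0]
        n_scored = len(scored)
        if n_scored <= threshold:
            continue
        rows.append(
            {
                "dimension": dimension,
                "key": keys[0],
                "year": keys[1] if per_year else None,
                "n_scored": n_scored,
                "n_na": len(g) - n_scored,
                "rti": float(scored["total"].mean()),
            }
        )
    out = pd.DataFrame(rows, columns=["dimension", "key", "year", "n_scored", "n_na", "rti"])
    return out.sort_values(["year", "key"], na_position="first").reset_index(drop=True)


def _addresses(types: set, criterion: str) -> bool:
    members = CRITERIA_SETS.get(criterion, (criterion,))
    return any(t in types for t in members)


def criteria_trends(
    records,
    cohort: str = "all",
    criteria: Sequence[str] = ("randomization", "blinding", "power_analysis", "replication"),
) -> pd.DataFrame:
    """Per-year proportion of cohort papers addressing each criterion.

    A criterion is addressed when any of its member entity types was detected
    (see :data:`CRITERIA_SETS` for the compound ones). The output has one row
    per year with an ``n_papers`` column and one proportion column per
    criterion, each in [0, 1].
    """
    if cohort not in COHORTS:
        raise ValueError(f"unknown cohort: {cohort!r}; known: {sorted(COHORTS)}")
    df = records_to_frame(records) if not isinstance(records, pd.DataFrame) else records.copy()
    if df.empty:
        return pd.DataFrame(columns=["year", "n_papers", *criteria])
    keep = df["entity_types"].map(COHORTS[cohort])
    df = df[keep]
    rows = []
    for year, g in df.groupby("year", sort=True):
        row = {"year": year, "n_papers": len(g)}
        for crit in criteria:
            row[crit] = float(g["entity_types"].map(lambda t: _addresses(t, crit)).mean())
        rows.append(row)
    return pd.DataFrame(rows)


def rank_report(
    rti_records: pd.DataFrame,
    top_k: int = 25,
    volume_cut: int = 50,
) -> pd.DataFrame:
    """Rank the most prolific groups of one year by their index value.

    The ``volume_cut`` groups with the most scored papers are selected first;
    they are then ordered by rti descending (ties broken by larger n_scored,
    then key order) and the top ``top_k`` emitted with a 1-based ``rank``.
    """
    df = rti_records.copy()
    if df["year"].nunique() > 1:
        raise ValueError("rank_report expects records for a single year")
    prolific = df.sort_values(
        ["n_scored", "key"], ascending=[False, True]
    ).head(volume_cut)
    ranked = prolific.sort_values(
        ["rti", "n_scored", "key"], ascending=[False, False, True]
    )
    if len(ranked) < top_k:
        warnings.warn(
            f"only {len(ranked)} groups available for a top-{top_k} report",
            stacklevel=2,
        )
    out = ranked.head(top_k).reset_index(drop=True)
    out.insert(0, "rank", range(1, len(out) + 1))
    return out
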