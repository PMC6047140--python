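"""Episode-record cleaning and merge to one record per infant.

Mirrors the preparation steps a national neonatal registry applies before
analysis: collapse exact duplicates, reject rows with impossible values
(gestational age outside 22-44 completed weeks, discharge before admission),
merge near-duplicate episodes (same infant, same unit, overlapping dates),
and finally merge all of an infant's retained episodes into a single record
carrying the union of its diagnosis codes.

Episode tables are pandas DataFrames in the CSV dialect defined by
:mod:`neosurv.synthetic_cohort` (``EPISODE_COLUMNS``); dates are ISO-8601
strings, which compare correctly as strings.
"""

from __future__ import annotations

import pandas as pd

from .catalog import format_codes, parse_codes
from .synthetic_cohort import EPISODE_COLUMNS

GESTATION_MIN, GESTATION_MAX = 22, 44

INFANT_COLUMNS: tuple[str, ...] = (
    "infant_id",
    "year",
    "gestational_weeks",
    "codes",
    "n_episodes",
)


def read_episodes(path) -> pd.DataFrame:
    """Read an episode CSV, enforcing schema; bad rows raise with a row number."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = set(EPISODE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"episode CSV missing columns: {sorted(missing)}")
    df = df[list(EPISODE_COLUMNS)]
    for col, conv in (("year", int), ("gestational_weeks", float)):
        try:
            df[col] = [conv(v) if v != "" else float("nan") for v in df[col]]
        except ValueError as err:
            for i, v in enumerate(df[col]):
                try:
                    conv(v) if v != "" else None
                except ValueError:
                    raise ValueError(
                        f"unparseable {col}={v!r} at data row {i + 1}"
                    ) from err
            raise
    return df


def write_episodes(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def _merge_near_duplicates(df: pd.DataFrame) -> pd.DataFrame:
    """Merge overlapping episodes of the same infant at the same unit.

    Overlap chains are collapsed to one episode spanning min(admission) to
    max(discharge) with the union of codes. Rows without overlap pass
    through untouched (registries' real fuzzy-matching rules are
    unpublished; same-unit date overlap is the conservative core case).
    """
    if df.empty:
        return df
    s = df.sort_values(
        ["infant_id", "unit_id", "admission_date", "discharge_date"],
        kind="mergesort",
    ).reset_index(drop=True)
    adm_dt = pd.to_datetime(s["admission_date"], errors="coerce")
    dis_dt = pd.to_datetime(s["discharge_date"], errors="coerce")
    keys = [s["infant_id"], s["unit_id"]]
    prev_max_dis = dis_dt.groupby(keys, sort=False).cummax().groupby(keys, sort=False).shift(1)
    overlap = prev_max_dis.notna() & (adm_dt <= prev_max_dis)
    chain = (~overlap).cumsum()
    if not overlap.any():
        return s
    out = []
    for _, g in s.groupby(chain, sort=True):
        if len(g) == 1:
            out.append(g)
        else:
            row = g.iloc[0].copy()
            row["admission_date"] = g["admission_date"].min()
            row["discharge_date"] = g["discharge_date"].max()
            row["codes"] = format_codes(
                frozenset().union(*(parse_codes(c) for c in g["codes"]))
            )
            out.append(row.to_frame().T)
    return pd.concat(out, ignore_index=True)[list(EPISODE_COLUMNS)]


def clean_episodes(
    records: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Classify every input row exactly once: retained, or rejected with reason.

    Rejection reasons are machine-readable: ``duplicate`` (an exact copy of
    an earlier row), ``gestation_out_of_range`` (outside 22-44 completed
    weeks), ``date_interval_inverted`` (discharge before admission). Missing
    gestational age is retained (tallied downstream), only out-of-range
    numeric values are rejected. Near-duplicate episodes are merged, not
    rejected.

    Returns ``(retained, rejects)``; ``rejects`` carries the episode columns
    plus ``reason``.
    """
    df = records.reset_index(drop=True)
    rejects: list[pd.DataFrame] = []

    dup = df.duplicated(keep="first")
    if dup.any():
        r = df.loc[dup].copy()
        r["reason"] = "duplicate"
        rejects.append(r)
    df = df.loc[~dup]

    ga = pd.to_numeric(df["gestational_weeks"], errors="coerce")
    ga_bad = ga.notna() & ~ga.between(GESTATION_MIN, GESTATION_MAX)
    if ga_bad.any():
        r = df.loc[ga_bad].copy()
        r["reason"] = "gestation_out_of_range"
        rejects.append(r)
    df = df.loc[~ga_bad]

    inverted = df["discharge_date"] < df["admission_date"]
    if inverted.any():
        r = df.loc[inverted].copy()
        r["reason"] = "date_interval_inverted"
        rejects.append(r)
    df = df.loc[~inverted]

    retained = _merge_near_duplicates(df.reset_index(drop=True))
    reject_df = (
        pd.concat(rejects, ignore_index=True)
        if rejects
        else pd.DataFrame(columns=list(EPISODE_COLUMNS) + ["reason"])
    )
    return retained.reset_index(drop=True), reject_df.reset_index(drop=True)


def merge_to_infants(
    retained: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Merge cleaned episodes into exactly one record per infant.

    Codes are unioned across episodes; gestational age and cohort year are
    taken from the earliest admission (closest to birth). Gestational ages
    differing by more than 1 week across an infant's episodes are recorded
    as an inconsistency issue while the earliest-episode value is used.

    Returns ``(infants, issues)``; ``issues`` has columns
    ``infant_id, reason``.
    """
    if retained.empty:
        return (
            pd.DataFrame(columns=list(INFANT_COLUMNS)),
            pd.DataFrame(columns=["infant_id", "reason"]),
        )
    s = retained.sort_values(
        ["infant_id", "admission_date"], kind="mergesort"
    ).reset_index(drop=True)
    s["_ga"] = pd.to_numeric(s["gestational_weeks"], errors="coerce")
    g = s.groupby("infant_id", sort=True)

    first = g.head(1).set_index("infant_id")
    codes = g["codes"].agg(
        lambda col: format_codes(frozenset().union(*(parse_codes(c) for c in col)))
    )
    n_episodes = g.size()
    ga_span = g["_ga"].max() - g["_ga"].min()
    inconsistent = ga_span[ga_span > 1].index
    first = first.loc[codes.index]

    infants = pd.DataFrame(
        {
            "infant_id": codes.index,
            "year": first["admission_date"].astype(str).str.slice(0, 4).astype(int).values,
            "gestational_weeks": first["_ga"].values,
            "codes": codes.values,
            "n_episodes": n_episodes.values,
        }
    ).reset_index(drop=True)
    issues = pd.DataFrame(
        {"infant_id": list(inconsistent), "reason": "gestation_inconsistent"}
    )
    return infants, issues


def write_infants(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False)


def read_infants(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"infant_id": str, "codes": str}, keep_default_na=False)
    df["codes"] = df["codes"].astype(str)
    df["gestational_weeks"] = pd.to_numeric(df["gestational_weeks"], errors="coerce")
    return df
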