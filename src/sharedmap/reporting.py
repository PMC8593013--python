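"""Crude-rate descriptives and ranking tables."""

from __future__ import annotations

import math
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .model import CountData

MARGINS = ("disease", "area", "gender", "age_group")


def counts_to_frame(data: CountData) -> pd.DataFrame:
    """Long-format view of the lattice: one row per cell."""
    d, i, g, j = np.meshgrid(
        np.arange(2), np.arange(data.I), np.arange(2), np.arange(data.J),
        indexing="ij",
    )
    return pd.DataFrame({
        "disease": np.asarray(data.disease_labels)[d.ravel()],
        "area": np.asarray(data.area_ids)[i.ravel()],
        "gender": np.asarray(data.gender_labels)[g.ravel()],
        "age_group": np.asarray(data.age_labels)[j.ravel()],
        "deaths": data.O.ravel(),
        "population": data.n.ravel(),
    })


def crude_rates(data: CountData, by: Sequence[str]) -> pd.DataFrame:
    """Crude mortality rates per 100,000 aggregated over the margins not in ``by``.

    Groups with zero aggregated population and zero deaths get a missing
    rate; zero population with positive deaths is rejected (it cannot arise
    from a valid :class:`CountData`, but aggregation is checked anyway).
    """
    by = list(by)
    unknown = set(by) - set(MARGINS)
    if unknown:
        raise ValueError(f"unknown margins: {sorted(unknown)}")
    df = counts_to_frame(data)
    if by:
        agg = df.groupby(by, sort=False, as_index=False)[["deaths", "population"]].sum()
    else:
        agg = pd.DataFrame([{"deaths": df["deaths"].sum(),
                             "population": df["population"].sum()}])
    bad = (agg["population"] == 0) & (agg["deaths"] > 0)
    if bad.any():
        raise ValueError("aggregated population is zero where deaths are positive")
    with np.errstate(invalid="ignore", divide="ignore"):
        rate = 1e5 * agg["deaths"] / agg["population"]
    agg["rate_per_100k"] = rate.where(agg["population"] > 0, np.nan)
    return agg


def share_of_total(part: int, total: int) -> int:
    """Percentage ``100 * part / total`` rounded to the nearest integer,
    halves away from zero (the convention used for printed percentages)."""
    if total <= 0:
        raise ValueError("total must be positive")
    if part < 0:
        raise ValueError("part must be nonnegative")
    x = 100.0 * part / total
    return int(math.floor(x + 0.5))


def rank_top(summary: pd.DataFrame, quantity: str = "rate", k: int = 10) -> pd.DataFrame:
    """Top-``k`` areas by posterior median within each (gender, age) stratum.

    Expects a summary table with ``quantity``, ``area``, ``median``,
    ``ci_low``, ``ci_high`` columns (plus any of ``disease``, ``gender``,
    ``age_group``).  Sort is stable and descending by median; ties keep the
    table's area order.
    """
    df = summary[summary["quantity"] == quantity].copy()
    if df.empty:
        raise ValueError(f"no rows with quantity {quantity!r}")
    strata = [c for c in ("disease", "gender", "age_group") if c in df.columns]
    pieces = []
    if strata:
        for _, grp in df.groupby(strata, sort=False):
            top = grp.sort_values("median", ascending=False, kind="stable").head(k)
            top = top.assign(rank=np.arange(1, len(top) + 1))
            pieces.append(top)
        out = pd.concat(pieces, ignore_index=True)
    else:
        out = df.sort_values("median", ascending=False, kind="stable").head(k)
        out = out.assign(rank=np.arange(1, len(out) + 1))
    return out
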