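"""Growth-curve establishment detection and heterosis-over-time.

Early seedling-area series confound two heterotic signals: earlier
establishment (germination timing) and faster growth after establishment.
To separate them, each plant's series is re-indexed to t0 — the first day its
projected leaf area exceeds a detection threshold (default 2 mm^2, roughly
the stage where cotyledons emerge).  Mid-parent heterosis of leaf area is
then computed per time offset from genotype-mean curves, either on raw
days-after-sowing or on t0-normalized offsets; the normalization removes a
pure time-shift between genotypes exactly.

Hourly input is collapsed to daily maxima before t0 assignment (the rule is
phrased in days).  The first-crossing rule is used even for noisy curves that
dip back under the threshold; ``confirm_days`` optionally requires k
consecutive above-threshold days.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps

from heteroscan.core import validate_pedigree
from heteroscan.stats import mid_parent_heterosis

__all__ = [
    "collapse_daily",
    "detect_establishment",
    "establishment_table",
    "establishment_fraction",
    "mph_over_time",
]

DEFAULT_THRESHOLD = 2.0  # mm^2

CURVE_COLUMNS = ["plant_id", "genotype_id", "role", "population", "time", "area_mm2"]


def _check_curves(curves: pd.DataFrame) -> None:
    missing = [c for c in CURVE_COLUMNS if c not in curves.columns]
    if missing:
        raise ValueError(f"growth-curve table missing column(s): {missing}")
    if (curves["area_mm2"].dropna() < 0).any():
        raise ValueError("negative leaf areas")


def collapse_daily(curves: pd.DataFrame) -> pd.DataFrame:
    """Collapse sub-daily time points to per-day maxima.

    ``time`` is interpreted in days; fractional times are floored to the day
    they fall in.  Already-daily input passes through unchanged (up to the
    max aggregation, which is the identity there).
    """
    _check_curves(curves)
    out = curves.copy()
    out["time"] = np.floor(out["time"].to_numpy(dtype=float)).astype(int)
    keys = ["plant_id", "genotype_id", "role", "population", "time"]
    return out.groupby(keys, sort=True, as_index=False)["area_mm2"].max()


def detect_establishment(
    times, areas, threshold: float = DEFAULT_THRESHOLD, confirm_days: int = 1
):
    """First time point at which area exceeds the threshold, or None.

    ``confirm_days > 1`` requires that many consecutive above-threshold
    observations before calling the crossing (debounce for noisy series);
    the reported t0 is still the first day of the confirmed run.
    """
    t = np.asarray(times, dtype=float)
    a = np.asarray(areas, dtype=float)
    if t.size == 0:
        raise ValueError("empty series")
    order = np.argsort(t, kind="mergesort")
    t, a = t[order], a[order]
    above = a > threshold
    if confirm_days <= 1:
        idx = np.flatnonzero(above)
        return float(t[idx[0]]) if idx.size else None
    run = 0
    for i, flag in enumerate(above):
        run = run + 1 if flag else 0
        if run >= confirm_days:
            return float(t[i - confirm_days + 1])
    return None


def establishment_table(
    curves: pd.DataFrame, threshold: float = DEFAULT_THRESHOLD, confirm_days: int = 1
) -> pd.DataFrame:
    """Per-plant t0 (day of first threshold crossing; NaN if never)."""
    daily = collapse_daily(curves)
    rows = []
    for (pid, gid, role, pop), grp in daily.groupby(
        ["plant_id", "genotype_id", "role", "population"], sort=False
    ):
        t0 = detect_establishment(grp["time"], grp["area_mm2"], threshold, confirm_days)
        rows.append(
            {"plant_id": pid, "genotype_id": gid, "role": role, "population": pop,
             "t0": np.nan if t0 is None else t0}
        )
    return pd.DataFrame(rows)


def establishment_fraction(
    curves: pd.DataFrame,
    days=None,
    threshold: float = DEFAULT_THRESHOLD,
) -> pd.DataFrame:
    """Fraction of plants visible (area above threshold) per role per day.

    Hybrid vs parent (parent + reference pooled) difference is tested per day
    with a two-proportion z-test; days where either role is empty get NaN.
    """
    daily = collapse_daily(curves)
    if days is None:
        days = sorted(daily["time"].unique())
    et = establishment_table(curves, threshold)
    et["parental"] = et["role"].isin(["parent", "reference"])

    rows = []
    for pop, grp in et.groupby("population", sort=True):
        for day in days:
            frac = {}
            counts = {}
            for label, sub in (("hybrid", grp[~grp["parental"]]), ("parent", grp[grp["parental"]])):
                if len(sub) == 0:
                    frac[label], counts[label] = np.nan, (0, 0)
                    continue
                vis = (sub["t0"] <= day).sum()
                frac[label] = vis / len(sub)
                counts[label] = (int(vis), len(sub))
            pv = np.nan
            (x1, n1), (x2, n2) = counts["hybrid"], counts["parent"]
            if n1 and n2:
                pooled = (x1 + x2) / (n1 + n2)
                se = np.sqrt(pooled * (1 - pooled) * (1 / n1 + 1 / n2))
                if se > 0:
                    z = (x1 / n1 - x2 / n2) / se
                    pv = 2 * sps.norm.sf(abs(z))
                else:
                    pv = 1.0
            rows.append(
                {"population": pop, "day": day,
                 "fraction_hybrid": frac["hybrid"], "fraction_parent": frac["parent"],
                 "p_value": pv}
            )
    return pd.DataFrame(rows)


def _genotype_mean_curves(daily: pd.DataFrame, align: str, threshold: float, min_plants: int):
    """Genotype-mean area per (population, genotype, offset).

    In t0-normalized mode each plant is re-indexed to days since its own t0
    before averaging; plants that never establish are dropped.
    """
    if align == "t0":
        et = establishment_table(daily, threshold).set_index("plant_id")["t0"]
        daily = daily.assign(offset=daily["time"].to_numpy() - et.reindex(daily["plant_id"]).to_numpy())
        daily = daily.dropna(subset=["offset"])
    elif align == "raw":
        daily = daily.assign(offset=daily["time"])
    else:
        raise ValueError(f"unknown alignment {align!r}")
    g = daily.groupby(["population", "genotype_id", "offset"])["area_mm2"]
    means = g.agg(mean="mean", n_plants=lambda s: daily.loc[s.index, "plant_id"].nunique())
    means = means[means["n_plants"] >= min_plants]
    return means["mean"]


def mph_over_time(
    curves: pd.DataFrame,
    pedigree: pd.DataFrame,
    align: str = "t0",
    threshold: float = DEFAULT_THRESHOLD,
    min_plants: int = 2,
) -> pd.DataFrame:
    """Per-hybrid mid-parent heterosis of leaf area at each time offset.

    ``align="raw"`` uses days after sowing; ``align="t0"`` first re-indexes
    each plant to days since its own establishment, so a pure establishment
    time shift between genotypes no longer contributes.  Offsets supported by
    fewer than ``min_plants`` plants for any of the three genotypes are
    dropped.  Returns (hybrid_id, population, offset, mph, mph_abs, mpv).
    """
    _check_curves(curves)
    validate_pedigree(pedigree)
    daily = collapse_daily(curves)
    means = _genotype_mean_curves(daily, align, threshold, min_plants)

    rows = []
    for rec in pedigree.itertuples(index=False):
        pop = str(rec.population)
        try:
            f1 = means.loc[pop, rec.hybrid_id]
            p1 = means.loc[pop, rec.parent_id]
            p2 = means.loc[pop, rec.reference_id]
        except KeyError:
            continue
        shared = f1.index.intersection(p1.index).intersection(p2.index)
        for off in shared:
            mp = mid_parent_heterosis(f1[off], p1[off], p2[off])
            rows.append(
                {"hybrid_id": rec.hybrid_id, "population": pop, "offset": float(off),
                 "mph": mp["mph"], "mph_abs": mp["mph_abs"], "mpv": mp["mpv"]}
            )
    return pd.DataFrame(rows)
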