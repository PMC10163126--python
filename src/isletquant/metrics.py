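"""Donor-level aggregation of islet infiltration data.

All metrics take islets that already passed the cellularity filter.  The two
density framings used in the field are both computed and labelled
distinctly:

* *pooled* density — sum of infiltrating cells over sum of islet areas
  (cells/mm^2), the donor-level statistic the density-threshold rule uses;
* *mean islet* density — the unweighted mean of per-islet densities over a
  stated islet subset (all, LOW: 1-5 cells, HIGH: >= 6 cells).

Metrics that are undefined on a donor (no analysed islets, zero
denominator) propagate as NaN, never as zero: a donor with no highly
infiltrated islets has pct_high == 0, but a donor with no islets at all has
pct_high == NaN.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .quant import InfiltrationCategory, categorize
from .records import MARKERS, DonorRecord, Group, InsulinStatus, IsletRecord, _canonical_marker

__all__ = [
    "DonorSummary",
    "percent_infiltrated",
    "pooled_density",
    "mean_islet_density",
    "exocrine_density",
    "endo_exo_ratio",
    "cd8_ratio",
    "percent_change",
    "summarize_donor",
    "summarize_cohort",
    "summaries_frame",
    "group_summary",
    "group_ici_idi_percent_change",
]

#: subsets of islets over which density metrics are reported
SUBSETS = ("all", "low", "high")


def _subset_islets(islets: list[IsletRecord], marker: str, subset: str) -> list[IsletRecord]:
    marker = _canonical_marker(marker)
    if subset == "all":
        return list(islets)
    cat = InfiltrationCategory[subset.upper()]
    return [i for i in islets if categorize(i.marker_count(marker)) is cat]


def percent_infiltrated(
    islets: list[IsletRecord], marker: str = "cd3", category_filter: str = "all"
) -> float:
    """Percentage of islets whose ``marker`` count falls in ``category_filter``.

    ``category_filter`` is one of ``"all"`` (>= 1 cell), ``"low"`` (1-5) or
    ``"high"`` (>= 6).  Returns NaN on an empty islet list.
    """
    if not islets:
        return math.nan
    marker = _canonical_marker(marker)
    if category_filter == "all":
        hits = sum(1 for i in islets if i.marker_count(marker) >= 1)
    else:
        cat = InfiltrationCategory[category_filter.upper()]
        hits = sum(1 for i in islets if categorize(i.marker_count(marker)) is cat)
    return 100.0 * hits / len(islets)


def pooled_density(islets: list[IsletRecord], marker: str = "cd3") -> float:
    """Donor-pooled density: sum of counts over sum of areas, cells/mm^2.

    Equals the area-weighted mean of per-islet densities.  NaN on an empty
    list.
    """
    if not islets:
        return math.nan
    marker = _canonical_marker(marker)
    total = sum(i.marker_count(marker) for i in islets)
    area = sum(i.area_mm2 for i in islets)
    return total / area


def mean_islet_density(
    islets: list[IsletRecord], marker: str = "cd3", subset: str = "all"
) -> float:
    """Unweighted mean of per-islet densities over ``subset``; NaN if empty."""
    marker = _canonical_marker(marker)
    sub = _subset_islets(islets, marker, subset)
    if not sub:
        return math.nan
    return float(np.mean([i.marker_count(marker) / i.area_mm2 for i in sub]))


def exocrine_density(donor: DonorRecord, marker: str = "cd3") -> float:
    """Exocrine infiltration density: cells over (total - endocrine) area."""
    exo_area = donor.exocrine_area_mm2
    if not exo_area > 0 or math.isnan(exo_area):
        raise ValueError(
            f"donor {donor.donor_id}: exocrine area must be positive, got {exo_area}"
        )
    return donor.exocrine_marker_count(marker) / exo_area


def endo_exo_ratio(
    donor: DonorRecord,
    marker: str = "cd3",
    islet_subset: str = "all",
    islets: list[IsletRecord] | None = None,
) -> float:
    """Ratio of islet (pooled) to exocrine density for one donor.

    ``islet_subset`` restricts the numerator islets by insulin status:
    ``"all"``, ``"ICI"`` or ``"IDI"``.  Pass ``islets`` to use a pre-filtered
    list (e.g. after the cellularity filter); defaults to all donor islets.
    NaN when the exocrine density is zero or the subset is empty.
    """
    pool = list(donor.islets) if islets is None else list(islets)
    if islet_subset.upper() in ("ICI", "IDI"):
        status = InsulinStatus[islet_subset.upper()]
        pool = [i for i in pool if i.insulin_status is status]
    exo = exocrine_density(donor, marker)
    if exo == 0:
        return math.nan
    dens = pooled_density(pool, marker)
    return dens / exo


def cd8_ratio(cd3cd8neg: float, cd3cd8pos: float) -> float:
    """CD3+CD8- : CD3+CD8+ ratio; NaN when the CD8+ count is zero."""
    if cd3cd8pos == 0:
        return math.nan
    return cd3cd8neg / cd3cd8pos


def percent_change(value_ici: float, value_idi: float) -> float:
    """Percent change of an ICI metric relative to its IDI counterpart."""
    if not value_idi > 0:
        return math.nan
    return 100.0 * (value_ici - value_idi) / value_idi


@dataclass
class DonorSummary:
    """All per-donor derived metrics.

    Dictionaries are keyed by marker (``cd3``, ``cd3cd8pos``, ``cd3cd8neg``);
    ``mean_islet_density`` additionally by islet subset.  ``ici_idi`` holds
    the same metrics restratified by insulin status when both statuses are
    present among the analysed islets.
    """

    donor_id: str
    group: Group
    n_islets_analysed: int
    n_islets_excluded: int
    pct_infiltrated: dict[str, float]
    pct_low: dict[str, float]
    pct_high: dict[str, float]
    pooled_density: dict[str, float]
    mean_islet_density: dict[str, dict[str, float]]
    pct_ici: float
    exocrine_density: dict[str, float]
    endo_exo_ratio: dict[str, float]
    cd8_ratio_islets: float
    cd8_ratio_exocrine: float
    ici_idi: dict[str, "StatusBreakdown"] = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    def flat(self) -> dict[str, float]:
        """Flatten to a single {metric_name: value} mapping."""
        out: dict[str, float] = {
            "n_islets_analysed": self.n_islets_analysed,
            "n_islets_excluded": self.n_islets_excluded,
            "pct_ici": self.pct_ici,
            "cd8_ratio_islets": self.cd8_ratio_islets,
            "cd8_ratio_exocrine": self.cd8_ratio_exocrine,
        }
        for m in MARKERS:
            out[f"pct_infiltrated_{m}"] = self.pct_infiltrated[m]
            out[f"pct_low_{m}"] = self.pct_low[m]
            out[f"pct_high_{m}"] = self.pct_high[m]
            out[f"pooled_density_{m}"] = self.pooled_density[m]
            out[f"exocrine_density_{m}"] = self.exocrine_density[m]
            out[f"endo_exo_ratio_{m}"] = self.endo_exo_ratio[m]
            for s in SUBSETS:
                out[f"mean_islet_density_{m}_{s}"] = self.mean_islet_density[m][s]
        for status, br in self.ici_idi.items():
            for k, v in br.flat().items():
                out[f"{status.lower()}_{k}"] = v
        return out


@dataclass
class StatusBreakdown:
    """Per-insulin-status restratification of the islet metrics."""

    n_islets: int
    pct_infiltrated: dict[str, float]
    pct_low: dict[str, float]
    pct_high: dict[str, float]
    pooled_density: dict[str, float]
    mean_islet_density: dict[str, dict[str, float]]
    endo_exo_ratio: dict[str, float]

    def flat(self) -> dict[str, float]:
        out: dict[str, float] = {"n_islets": self.n_islets}
        for m in MARKERS:
            out[f"pct_infiltrated_{m}"] = self.pct_infiltrated[m]
            out[f"pct_low_{m}"] = self.pct_low[m]
            out[f"pct_high_{m}"] = self.pct_high[m]
            out[f"pooled_density_{m}"] = self.pooled_density[m]
            out[f"endo_exo_ratio_{m}"] = self.endo_exo_ratio[m]
            for s in SUBSETS:
                out[f"mean_islet_density_{m}_{s}"] = self.mean_islet_density[m][s]
        return out


def _islet_metrics(islets: list[IsletRecord]):
    pct_inf = {m: percent_infiltrated(islets, m, "all") for m in MARKERS}
    pct_low = {m: percent_infiltrated(islets, m, "low") for m in MARKERS}
    pct_high = {m: percent_infiltrated(islets, m, "high") for m in MARKERS}
    pooled = {m: pooled_density(islets, m) for m in MARKERS}
    mid = {m: {s: mean_islet_density(islets, m, s) for s in SUBSETS} for m in MARKERS}
    return pct_inf, pct_low, pct_high, pooled, mid


def summarize_donor(
    donor: DonorRecord,
    min_cells: int = 30,
    pre_filtered: bool = False,
) -> DonorSummary:
    """Compute every per-donor metric from a donor record.

    Applies the >= ``min_cells`` cellularity filter first unless
    ``pre_filtered``.  The ICI/IDI breakdown is emitted whenever analysed
    islets of both statuses are present (recent-onset T1D donors).
    """
    from .quant import filter_islets

    if pre_filtered:
        kept, excluded = list(donor.islets), []
    else:
        kept, excluded = filter_islets(donor.islets, min_cells)

    pct_inf, pct_low, pct_high, pooled, mid = _islet_metrics(kept)
    has_section = donor.exocrine_area_mm2 > 0
    if has_section:
        exo = {m: exocrine_density(donor, m) for m in MARKERS}
        ratio = {m: (pooled[m] / exo[m] if exo[m] > 0 else math.nan) for m in MARKERS}
        exo_cd8 = cd8_ratio(donor.exocrine_cd3cd8neg, donor.exocrine_cd3cd8pos)
    else:
        exo = {m: math.nan for m in MARKERS}
        ratio = {m: math.nan for m in MARKERS}
        exo_cd8 = math.nan

    known = [i for i in kept if i.insulin_status is not InsulinStatus.UNKNOWN]
    pct_ici = (
        100.0 * sum(1 for i in known if i.insulin_status is InsulinStatus.ICI) / len(known)
        if known else math.nan
    )

    ici_idi: dict[str, StatusBreakdown] = {}
    by_status = {
        st: [i for i in kept if i.insulin_status is st]
        for st in (InsulinStatus.ICI, InsulinStatus.IDI)
    }
    if all(len(v) > 0 for v in by_status.values()):
        for st, sub in by_status.items():
            s_inf, s_low, s_high, s_pool, s_mid = _islet_metrics(sub)
            s_ratio = {
                m: (s_pool[m] / exo[m] if has_section and exo[m] > 0 else math.nan)
                for m in MARKERS
            }
            ici_idi[st.value] = StatusBreakdown(
                n_islets=len(sub), pct_infiltrated=s_inf, pct_low=s_low,
                pct_high=s_high, pooled_density=s_pool,
                mean_islet_density=s_mid, endo_exo_ratio=s_ratio,
            )

    neg = sum(i.cd3cd8neg_count for i in kept)
    pos = sum(i.cd3cd8pos_count for i in kept)
    return DonorSummary(
        donor_id=donor.donor_id,
        group=donor.group,
        n_islets_analysed=len(kept),
        n_islets_excluded=len(excluded),
        pct_infiltrated=pct_inf,
        pct_low=pct_low,
        pct_high=pct_high,
        pooled_density=pooled,
        mean_islet_density=mid,
        pct_ici=pct_ici,
        exocrine_density=exo,
        endo_exo_ratio=ratio,
        cd8_ratio_islets=cd8_ratio(neg, pos),
        cd8_ratio_exocrine=exo_cd8,
        ici_idi=ici_idi,
        metadata=dict(donor.metadata),
    )


def summarize_cohort(donors: list[DonorRecord], min_cells: int = 30) -> list[DonorSummary]:
    """Per-donor summaries for a whole cohort (order preserved)."""
    return [summarize_donor(d, min_cells=min_cells) for d in donors]


def summaries_frame(summaries: list[DonorSummary]) -> pd.DataFrame:
    """Tidy per-donor metric table: one row per donor, one column per metric."""
    rows = []
    for s in summaries:
        row = {"donor_id": s.donor_id, "group": s.group.value}
        row.update(s.flat())
        rows.append(row)
    return pd.DataFrame(rows)


def group_summary(
    summaries: list[DonorSummary], group: Group | str | None = None
) -> pd.DataFrame:
    """Group-level mean, SD, median and quartiles per metric.

    The donor is the unit of analysis: statistics are over per-donor values,
    NaN-skipping (a metric undefined on a donor does not zero it out).  SD is
    NaN for a single donor.  ``group=None`` aggregates each group present.
    """
    df = summaries_frame(summaries)
    if group is not None:
        key = group.value if isinstance(group, Group) else str(group)
        df = df[df["group"] == key]
        if df.empty:
            raise ValueError(f"no donors in group {key}")
    metrics = [c for c in df.columns if c not in ("donor_id", "group")]
    out = []
    for gname, sub in df.groupby("group", sort=False):
        for m in metrics:
            vals = sub[m].astype(float)
            n = int(vals.notna().sum())
            out.append({
                "group": gname,
                "metric": m,
                "n_donors": n,
                "mean": float(vals.mean()) if n else math.nan,
                "sd": float(vals.std(ddof=1)) if n > 1 else math.nan,
                "median": float(vals.median()) if n else math.nan,
                "q1": float(vals.quantile(0.25)) if n else math.nan,
                "q3": float(vals.quantile(0.75)) if n else math.nan,
            })
    return pd.DataFrame(out)


def group_ici_idi_percent_change(
    summaries: list[DonorSummary], metric: str, group: Group = Group.T1D
) -> dict[str, float]:
    """Percent change (ICI relative to IDI) of a metric in one group.

    ``metric`` is a flattened metric name without the status prefix, e.g.
    ``"pct_infiltrated_cd3"`` or ``"pooled_density_cd3"``.  Returns both the
    change computed from group means (the figure-style framing) and the mean
    of per-donor changes.
    """
    df = summaries_frame(summaries)
    df = df[df["group"] == group.value]
    ici = df.get(f"ici_{metric}")
    idi = df.get(f"idi_{metric}")
    if ici is None or idi is None or df.empty:
        return {"from_group_means": math.nan, "mean_of_donor_changes": math.nan}
    from_means = percent_change(float(ici.mean()), float(idi.mean()))
    per_donor = [
        percent_change(a, b)
        for a, b in zip(ici.astype(float), idi.astype(float))
        if not (math.isnan(a) or math.isnan(b) or not b > 0)
    ]
    return {
        "from_group_means": from_means,
        "mean_of_donor_changes": float(np.mean(per_donor)) if per_donor else math.nan,
    }
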