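"""Candidate-region calling and cross-method intersection.

Markers whose statistic exceeds its method's threshold are grouped into
maximal runs (consecutive significant markers no further apart than
``merge_gap``), giving per-method candidate intervals whose bounds are the
first and last significant marker positions.  The final candidate regions
are the genomic intersection of the methods' interval sets: maximal
intervals covered by at least ``min_methods`` of the three methods.

All coordinates are 1-based inclusive; interval length in Mb is
``(end - start + 1) / 1e6`` rounded to two decimals.  A BED export
(0-based half-open) is provided for genome browsers.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

METHODS = ("SNP_INDEX", "G_PRIME", "ED5")


def region_length_mb(start: int, end: int) -> float:
    """Interval length in megabases, 1-based inclusive, 2 decimals."""
    if not 1 <= start <= end:
        raise ValueError("need 1 <= start <= end")
    return round((end - start + 1) / 1e6, 2)


@dataclass
class CandidateRegion:
    """A linkage-group interval supported by one or more methods."""

    linkage_group: str
    start: int
    end: int
    methods: frozenset = field(default_factory=frozenset)
    level: float = 0.95
    n_markers: int = 0

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError("region start must be <= end")
        self.methods = frozenset(self.methods)
        if not self.methods:
            raise ValueError("region must name at least one method")

    @property
    def length_mb(self) -> float:
        return region_length_mb(self.start, self.end)


def _lg_sort_key(lg: str):
    m = re.search(r"(\d+)$", lg)
    return (re.sub(r"\d+$", "", lg), int(m.group(1)) if m else -1)


def _significance_mask(stats: pd.DataFrame, thresholds, method: str,
                       level: float) -> np.ndarray:
    if method == "SNP_INDEX":
        col = "delta_smooth" if "delta_smooth" in stats else "delta_index"
        depth = 0.5 * (stats["ref_high"] + stats["alt_high"]
                       + stats["ref_low"] + stats["alt_low"]).to_numpy()
        lo, hi = thresholds.delta_band(depth, level)
        v = stats[col].to_numpy()
        return (v < lo) | (v > hi)
    if method == "G_PRIME":
        if "q_value" not in stats:
            raise ValueError("G_PRIME calling needs a q_value column")
        return stats["q_value"].to_numpy() < thresholds.gprime_alpha(level)
    if method == "ED5":
        col = "ed5_smooth" if "ed5_smooth" in stats else "ed5"
        return stats[col].to_numpy() > thresholds.ed5_cutoff(level)
    raise ValueError(f"unknown method: {method!r}")


def call_method_intervals(stats: pd.DataFrame, thresholds, method: str,
                          level: float = 0.95, merge_gap: int = 500_000,
                          ) -> list[CandidateRegion]:
    """Candidate intervals of one method at one confidence level.

    ``stats`` is a per-marker statistics table sorted by
    (linkage_group, position) as produced by
    :func:`bsrmap.bsa_stats.compute_stats` (with a ``q_value`` column for
    the G' method).  Significant markers closer than ``merge_gap`` bp
    join one interval; interval bounds are the first/last significant
    marker positions.
    """
    sig = _significance_mask(stats, thresholds, method, level)
    regions: list[CandidateRegion] = []
    for lg, idx in stats.groupby("linkage_group", sort=False).indices.items():
        pos = stats["position"].to_numpy()[idx]
        sig_pos = pos[sig[idx]]
        if sig_pos.size == 0:
            continue
        breaks = np.flatnonzero(np.diff(sig_pos) > merge_gap)
        starts = np.concatenate([[0], breaks + 1])
        ends = np.concatenate([breaks, [sig_pos.size - 1]])
        for s, e in zip(starts, ends):
            regions.append(CandidateRegion(
                linkage_group=str(lg), start=int(sig_pos[s]),
                end=int(sig_pos[e]), methods={method}, level=level,
                n_markers=int(e - s + 1)))
    regions.sort(key=lambda r: (_lg_sort_key(r.linkage_group), r.start))
    return regions


def intersect_methods(intervals_by_method: dict[str, list[CandidateRegion]],
                      min_methods: int = 3, stats: pd.DataFrame | None = None,
                      level: float | None = None) -> list[CandidateRegion]:
    """Maximal intervals covered by >= ``min_methods`` methods.

    Within each method an interval set must be sorted and non-overlapping
    (as produced by :func:`call_method_intervals`).  Adjacent qualifying
    segments merge; the reported method set is the union of supporting
    methods over the merged span.  If ``stats`` is given, ``n_markers``
    counts its markers inside each region.
    """
    lgs = sorted({r.linkage_group for regs in intervals_by_method.values()
                  for r in regs}, key=_lg_sort_key)
    out: list[CandidateRegion] = []
    for lg in lgs:
        events: list[tuple[int, int, str]] = []  # (coord, +1/-1, method)
        for method, regs in intervals_by_method.items():
            for r in regs:
                if r.linkage_group == lg:
                    events.append((r.start, +1, method))
                    events.append((r.end + 1, -1, method))
        coords = sorted({c for c, _, _ in events})
        active: dict[str, int] = {}
        segments: list[tuple[int, int, frozenset]] = []
        for a, b in zip(coords, coords[1:]):
            for c, delta, method in events:
                if c == a:
                    active[method] = active.get(method, 0) + delta
            covering = frozenset(m for m, k in active.items() if k > 0)
            if len(covering) >= min_methods:
                segments.append((a, b - 1, covering))
        # merge touching qualifying segments
        merged: list[list] = []
        for s, e, cov in segments:
            if merged and s == merged[-1][1] + 1:
                merged[-1][1] = e
                merged[-1][2] = merged[-1][2] | cov
            else:
                merged.append([s, e, cov])
        for s, e, cov in merged:
            n = 0
            if stats is not None:
                sub = stats[stats["linkage_group"] == lg]
                n = int(((sub["position"] >= s)
                         & (sub["position"] <= e)).sum())
            lv = level
            if lv is None:
                levels = {r.level for regs in intervals_by_method.values()
                          for r in regs}
                lv = levels.pop() if len(levels) == 1 else 0.95
            out.append(CandidateRegion(linkage_group=lg, start=s, end=e,
                                       methods=cov, level=lv, n_markers=n))
    return out


def region_table(regions: list[CandidateRegion], label: str = "",
                 ) -> pd.DataFrame:
    """Candidate regions as a table with start/end/length(Mb) columns."""
    rows = [{
        "Tissue": label,
        "Linkage group": r.linkage_group,
        "Starting position": r.start,
        "Ending position": r.end,
        "Length(Mb)": r.length_mb,
        "Methods": ",".join(sorted(r.methods)),
        "Level": r.level,
        "N markers": r.n_markers,
    } for r in regions]
    cols = ["Tissue", "Linkage group", "Starting position",
            "Ending position", "Length(Mb)", "Methods", "Level", "N markers"]
    return pd.DataFrame(rows, columns=cols)


def parse_region_table(table: pd.DataFrame) -> list[CandidateRegion]:
    """Inverse of :func:`region_table`."""
    return [CandidateRegion(
        linkage_group=str(row["Linkage group"]),
        start=int(row["Starting position"]),
        end=int(row["Ending position"]),
        methods=frozenset(str(row["Methods"]).split(",")),
        level=float(row["Level"]),
        n_markers=int(row["N markers"]),
    ) for _, row in table.iterrows()]


def regions_to_bed(regions: list[CandidateRegion]) -> pd.DataFrame:
    """0-based half-open BED representation of the regions."""
    return pd.DataFrame([{
        "chrom": r.linkage_group, "chromStart": r.start - 1,
        "chromEnd": r.end,
        "name": f"{','.join(sorted(r.methods))}@{r.level:g}",
    } for r in regions])
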