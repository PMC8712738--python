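"""Two-bulk variant input and filtering.

Reads a two-sample VCF into per-marker records carrying each bulk's
ref/alt allele depths, then applies the two filter layers used for
pooled-bulk mapping:

* hard site filters on the caller's quality annotations
  (``QD < 4 || FS > 60 || MQ < 40``), a per-bulk genotype-quality screen
  (``GQ < 20`` marks that bulk missing), and a SNP-cluster filter
  (>= ``cluster_size`` variants spanning <= ``cluster_window`` bp);
* marker filters: no missing genotype in either bulk, per-bulk depth
  within [10, 500], and exclusion of near-monomorphic markers where both
  bulks' SNP-index is < 0.3 or both > 0.7.

Filters are applied in a fixed order (site metrics, cluster, missing,
depth, index); every record is attributed to exactly one removal stage or
retained, so the :class:`FilterReport` counts conserve the input.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from bsrmap.synthetic import MARKER_COLUMNS

HARD_STAGES = ["site_metrics", "cluster"]
MARKER_STAGES = ["missing", "depth", "index"]
CLASSES = ["SNP", "INDEL"]


@dataclass
class MarkerRecord:
    """One biallelic variant with per-bulk depths and site metrics."""

    linkage_group: str
    position: int
    ref_allele: str
    alt_allele: str
    variant_class: str
    ref_high: int
    alt_high: int
    ref_low: int
    alt_low: int
    gq_high: float
    gq_low: float
    qd: float
    fs: float
    mq: float
    missing_high: bool = False
    missing_low: bool = False

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError("position must be >= 1")
        if min(self.ref_high, self.alt_high, self.ref_low, self.alt_low) < 0:
            raise ValueError("allele depths must be non-negative")
        expected = ("SNP" if len(self.ref_allele) == 1
                    and len(self.alt_allele) == 1 else "INDEL")
        if self.variant_class != expected:
            raise ValueError(
                f"variant_class {self.variant_class!r} inconsistent with "
                f"alleles {self.ref_allele}>{self.alt_allele}")


@dataclass
class FilterReport:
    """Per-stage removal counts split by variant class.

    ``input = retained + sum(removed per stage)`` for every class.
    """

    label: str = ""
    stages: list[str] = field(default_factory=list)
    input_counts: dict[str, int] = field(default_factory=dict)
    removed: dict[str, dict[str, int]] = field(default_factory=dict)
    retained_counts: dict[str, int] = field(default_factory=dict)

    def check_conservation(self) -> bool:
        for cls in CLASSES:
            total = self.retained_counts.get(cls, 0) + sum(
                self.removed.get(st, {}).get(cls, 0) for st in self.stages)
            if total != self.input_counts.get(cls, 0):
                return False
        return True

    def to_frame(self) -> pd.DataFrame:
        rows = [{"stage": "input", **self.input_counts}]
        rows += [{"stage": st, **{c: self.removed[st].get(c, 0)
                                  for c in CLASSES}} for st in self.stages]
        rows.append({"stage": "retained", **self.retained_counts})
        df = pd.DataFrame(rows).fillna(0)
        df[CLASSES] = df[CLASSES].astype(int)
        df.insert(0, "label", self.label)
        df["Total"] = df[CLASSES].sum(axis=1)
        return df


def markers_to_frame(records: list[MarkerRecord]) -> pd.DataFrame:
    """Marker records as a DataFrame with :data:`MARKER_COLUMNS`."""
    if not records:
        return pd.DataFrame(columns=MARKER_COLUMNS)
    return pd.DataFrame([dataclasses.asdict(r) for r in records])[
        MARKER_COLUMNS]


def frame_to_markers(frame: pd.DataFrame) -> list[MarkerRecord]:
    return [MarkerRecord(**row) for row in
            frame[MARKER_COLUMNS].to_dict("records")]


def read_bulk_vcf(path: str | Path, bulk_high_name: str, bulk_low_name: str,
                  multiallelic: str = "drop") -> list[MarkerRecord]:
    """Read a two-bulk VCF into sorted :class:`MarkerRecord` objects.

    ``multiallelic`` is ``"drop"`` (default: skip sites with more than one
    ALT allele) or ``"split"`` (decompose each ALT against REF).  Records
    are sorted by (contig order of appearance, position).  Raises
    ``ValueError`` if a bulk sample is absent or a record lacks AD.
    """
    from cyvcf2 import VCF

    if multiallelic not in ("drop", "split"):
        raise ValueError(f"unknown multiallelic policy: {multiallelic!r}")
    vcf = VCF(str(path))
    samples = vcf.samples
    for name in (bulk_high_name, bulk_low_name):
        if name not in samples:
            raise ValueError(
                f"sample {name!r} not in VCF (has {samples})")
    i_high = samples.index(bulk_high_name)
    i_low = samples.index(bulk_low_name)

    records: list[MarkerRecord] = []
    lg_rank: dict[str, int] = {}
    for v in vcf:
        alts = v.ALT
        if len(alts) == 0:
            continue
        if len(alts) > 1 and multiallelic == "drop":
            continue
        ad = v.format("AD")
        if ad is None:
            raise ValueError(
                f"record {v.CHROM}:{v.POS} has no AD field")
        ad = np.asarray(ad)
        gq = v.gt_quals
        gt_types = v.gt_types  # 2 == unknown
        qd = v.INFO.get("QD")
        fs = v.INFO.get("FS")
        mq = v.INFO.get("MQ")
        lg_rank.setdefault(v.CHROM, len(lg_rank))
        for ai, alt in enumerate(alts, start=1):
            depths = {}
            for role, si in (("high", i_high), ("low", i_low)):
                ref_d = max(int(ad[si, 0]), 0)
                alt_d = max(int(ad[si, ai]), 0)
                depths[f"ref_{role}"] = ref_d
                depths[f"alt_{role}"] = alt_d
                depths[f"missing_{role}"] = bool(
                    gt_types[si] == 2 or ref_d + alt_d == 0)
            vclass = "SNP" if len(v.REF) == 1 and len(alt) == 1 else "INDEL"
            records.append(MarkerRecord(
                linkage_group=v.CHROM, position=v.POS,
                ref_allele=v.REF, alt_allele=alt, variant_class=vclass,
                gq_high=float(gq[i_high]) if np.isfinite(gq[i_high]) else 0.0,
                gq_low=float(gq[i_low]) if np.isfinite(gq[i_low]) else 0.0,
                qd=float(qd) if qd is not None else np.nan,
                fs=float(fs) if fs is not None else np.nan,
                mq=float(mq) if mq is not None else np.nan,
                missing_high=depths.pop("missing_high"),
                missing_low=depths.pop("missing_low"),
                **depths))
    records.sort(key=lambda r: (lg_rank[r.linkage_group], r.position))
    return records


def _as_frame(records):
    """Accept a record list or a frame; return (frame, was_list)."""
    if isinstance(records, pd.DataFrame):
        return records.reset_index(drop=True), False
    return markers_to_frame(records), True


def _class_counts(frame: pd.DataFrame, mask=None) -> dict[str, int]:
    sub = frame if mask is None else frame[mask]
    vc = sub["variant_class"].value_counts()
    return {c: int(vc.get(c, 0)) for c in CLASSES}


def _cluster_mask(frame: pd.DataFrame, window: int, size: int) -> np.ndarray:
    """True where a variant sits in a run of >= `size` variants spanning
    <= `window` bp on one linkage group (positions assumed sorted)."""
    mask = np.zeros(len(frame), dtype=bool)
    for _, idx in frame.groupby("linkage_group", sort=False).indices.items():
        pos = frame["position"].to_numpy()[idx]
        n = len(pos)
        if n < size:
            continue
        span = pos[size - 1:] - pos[:n - size + 1] + 1
        for j in np.flatnonzero(span <= window):
            mask[idx[j:j + size]] = True
    return mask


def apply_hard_filters(records, qd_min: float = 4.0, fs_max: float = 60.0,
                       mq_min: float = 40.0, gq_min: float = 20.0,
                       cluster_window: int = 4, cluster_size: int = 3,
                       label: str = ""):
    """Site-metric and cluster filters; per-bulk GQ marks genotypes missing.

    Removes records where ``QD < qd_min`` or ``FS > fs_max`` or
    ``MQ < mq_min`` (a missing metric passes), then removes every record
    in a run of >= ``cluster_size`` variants spanning <= ``cluster_window``
    bp.  A bulk whose GQ is below ``gq_min`` has its genotype marked
    missing (removal happens in :func:`apply_marker_filters`).  Returns
    the surviving records (same container type as the input) and a
    :class:`FilterReport`.
    """
    frame, was_list = _as_frame(records)
    report = FilterReport(label=label, stages=list(HARD_STAGES),
                          input_counts=_class_counts(frame))

    qd = frame["qd"].to_numpy(dtype=float)
    fs = frame["fs"].to_numpy(dtype=float)
    mq = frame["mq"].to_numpy(dtype=float)
    bad = np.zeros(len(frame), dtype=bool)
    with np.errstate(invalid="ignore"):
        bad |= np.where(np.isnan(qd), False, qd < qd_min)
        bad |= np.where(np.isnan(fs), False, fs > fs_max)
        bad |= np.where(np.isnan(mq), False, mq < mq_min)
    report.removed["site_metrics"] = _class_counts(frame, bad)
    frame = frame[~bad].reset_index(drop=True)

    clustered = _cluster_mask(frame, cluster_window, cluster_size)
    report.removed["cluster"] = _class_counts(frame, clustered)
    frame = frame[~clustered].reset_index(drop=True)

    frame = frame.copy()
    frame["missing_high"] = frame["missing_high"] | (
        frame["gq_high"] < gq_min)
    frame["missing_low"] = frame["missing_low"] | (frame["gq_low"] < gq_min)

    report.retained_counts = _class_counts(frame)
    return (frame_to_markers(frame) if was_list else frame), report


def apply_marker_filters(records, depth_min: int = 10, depth_max: int = 500,
                         index_low: float = 0.3, index_high: float = 0.7,
                         label: str = ""):
    """Missing-genotype, per-bulk depth, and SNP-index marker filters.

    Retains markers where (a) neither bulk is missing, (b) each bulk's
    total depth lies within ``[depth_min, depth_max]`` (inclusive), and
    (c) the marker is not near-monomorphic: removed when both bulks'
    SNP-index < ``index_low`` or both > ``index_high``.
    """
    frame, was_list = _as_frame(records)
    report = FilterReport(label=label, stages=list(MARKER_STAGES),
                          input_counts=_class_counts(frame))

    missing = (frame["missing_high"] | frame["missing_low"]).to_numpy()
    report.removed["missing"] = _class_counts(frame, missing)
    frame = frame[~missing].reset_index(drop=True)

    dp_high = (frame["ref_high"] + frame["alt_high"]).to_numpy()
    dp_low = (frame["ref_low"] + frame["alt_low"]).to_numpy()
    bad_depth = ((dp_high < depth_min) | (dp_high > depth_max)
                 | (dp_low < depth_min) | (dp_low > depth_max))
    report.removed["depth"] = _class_counts(frame, bad_depth)
    frame = frame[~bad_depth].reset_index(drop=True)

    dp_high = (frame["ref_high"] + frame["alt_high"]).to_numpy()
    dp_low = (frame["ref_low"] + frame["alt_low"]).to_numpy()
    idx_high = frame["alt_high"].to_numpy() / dp_high
    idx_low = frame["alt_low"].to_numpy() / dp_low
    monomorphic = (((idx_high < index_low) & (idx_low < index_low))
                   | ((idx_high > index_high) & (idx_low > index_high)))
    report.removed["index"] = _class_counts(frame, monomorphic)
    frame = frame[~monomorphic].reset_index(drop=True)

    report.retained_counts = _class_counts(frame)
    return (frame_to_markers(frame) if was_list else frame), report


def summarize_variants(before, after, label: str = "") -> pd.DataFrame:
    """Before/after variant counts in the Total/SNP/Indel layout.

    ``before`` and ``after`` are class->count mappings or
    :class:`FilterReport` objects (a report contributes its input counts
    as "before" and its retained counts as "after").  Total is recomputed
    as SNP + Indel in every cell.
    """
    def counts(x, which):
        if isinstance(x, FilterReport):
            return x.input_counts if which == "before" else x.retained_counts
        return {c: int(x.get(c, 0)) for c in CLASSES}

    b = counts(before, "before")
    a = counts(after, "after")
    rows = [
        {"Variation": "Total",
         "Before filter": sum(b.values()), "After filter": sum(a.values())},
        {"Variation": "SNP",
         "Before filter": b.get("SNP", 0), "After filter": a.get("SNP", 0)},
        {"Variation": "Indel",
         "Before filter": b.get("INDEL", 0),
         "After filter": a.get("INDEL", 0)},
    ]
    df = pd.DataFrame(rows)
    if label:
        df.insert(0, "Sample", label)
    return df
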