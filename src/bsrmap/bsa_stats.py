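"""Per-marker divergence statistics for two pooled bulks.

Three complementary statistics quantify allele-frequency divergence
between the bulks at each marker:

* **SNP-index** per bulk, ``alt / (ref + alt)``, and their difference
  ``Delta(SNP-index) = index_high - index_low`` (near 0 genome-wide,
  deviating where the trait locus distorts segregation);
* the **G statistic**, the 2x2 likelihood-ratio statistic
  ``G = 2 * sum_i O_i ln(O_i / E_i)`` on the ref/alt x bulk depth table;
* the **Euclidean distance** between the bulks' allele-frequency vectors,
  ``ED = sqrt((Alt_h - Alt_l)^2 + (Ref_h - Ref_l)^2) = sqrt(2)|Delta alt|``,
  raised to the fifth power (ED^5) to suppress background noise.

G is computed on raw depth counts, as in the G' mapping approach; ED on
allele-depth fractions so it measures divergence, not coverage.  All three
can be tricube-kernel smoothed along each linkage group (G smoothed is
conventionally written G').
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def snp_index(ref_depth, alt_depth):
    """Alternate-allele read fraction ``alt / (ref + alt)`` of one bulk.

    Accepts scalars or arrays; total depth must be positive.
    """
    ref = np.asarray(ref_depth, dtype=float)
    alt = np.asarray(alt_depth, dtype=float)
    total = ref + alt
    if np.any(total <= 0):
        raise ValueError("SNP-index undefined at zero total depth")
    out = alt / total
    return float(out) if out.ndim == 0 else out


def delta_snp_index(index_high, index_low):
    """``index_high - index_low``, in [-1, 1]."""
    hi = np.asarray(index_high, dtype=float)
    lo = np.asarray(index_low, dtype=float)
    if np.any((hi < 0) | (hi > 1) | (lo < 0) | (lo > 1)):
        raise ValueError("SNP-index values must be in [0, 1]")
    out = hi - lo
    return float(out) if out.ndim == 0 else out


def g_statistic(ref_high, alt_high, ref_low, alt_low):
    """2x2 likelihood-ratio (G) statistic on per-bulk ref/alt depths.

    Expected counts are the usual independence expectations
    ``E_ij = row_i * col_j / N``; observed zeros contribute nothing.  A
    zero row or column total (no reads in a bulk, or a monomorphic site)
    carries no information and yields G = 0.  Vectorized over arrays.
    """
    o = np.stack([np.asarray(x, dtype=float) for x in
                  (ref_high, alt_high, ref_low, alt_low)], axis=-1)
    scalar = o.ndim == 1
    o = np.atleast_2d(o)
    n = o.sum(axis=-1)
    if np.any(n <= 0):
        raise ValueError("G statistic undefined for an all-zero table")
    row_high = o[..., 0] + o[..., 1]
    row_low = o[..., 2] + o[..., 3]
    col_ref = o[..., 0] + o[..., 2]
    col_alt = o[..., 1] + o[..., 3]
    e = np.stack([row_high * col_ref, row_high * col_alt,
                  row_low * col_ref, row_low * col_alt], axis=-1) / n[..., None]
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(o > 0, o * np.log(o / e), 0.0)
    g = 2.0 * np.nansum(terms, axis=-1)
    # degenerate margins carry no information
    g = np.where((row_high == 0) | (row_low == 0)
                 | (col_ref == 0) | (col_alt == 0), 0.0, g)
    g = np.maximum(g, 0.0)
    return float(g[0]) if scalar else g


def euclidean_distance(freq_alt_high, freq_alt_low):
    """(ED, ED^5) between the bulks' allele-frequency vectors.

    With per-bulk ref frequency = 1 - alt frequency this reduces to
    ``ED = sqrt(2) * |freq_alt_high - freq_alt_low|``.
    """
    hi = np.asarray(freq_alt_high, dtype=float)
    lo = np.asarray(freq_alt_low, dtype=float)
    if np.any((hi < 0) | (hi > 1) | (lo < 0) | (lo > 1)):
        raise ValueError("allele frequencies must be in [0, 1]")
    ed = np.sqrt((hi - lo) ** 2 + ((1 - hi) - (1 - lo)) ** 2)
    ed5 = ed ** 5
    if ed.ndim == 0:
        return float(ed), float(ed5)
    return ed, ed5


def euclidean_distance_depths(ref_high, alt_high, ref_low, alt_low):
    """(ED, ED^5) computed on raw allele depths instead of frequencies.

    Literal counts-based variant of :func:`euclidean_distance`:
    ``sqrt((Alt_h - Alt_l)^2 + (Ref_h - Ref_l)^2)`` on read counts.  This
    confounds coverage with divergence and is provided only for strict
    replication of depth-based workflows; the frequency form is the
    default everywhere.
    """
    ah = np.asarray(alt_high, dtype=float)
    al = np.asarray(alt_low, dtype=float)
    rh = np.asarray(ref_high, dtype=float)
    rl = np.asarray(ref_low, dtype=float)
    ed = np.sqrt((ah - al) ** 2 + (rh - rl) ** 2)
    ed5 = ed ** 5
    if ed.ndim == 0:
        return float(ed), float(ed5)
    return ed, ed5


def tricube_smooth(positions, values, half_width: float):
    """Tricube-kernel weighted mean over a +-``half_width`` bp window.

    ``positions`` must be sorted ascending within a single linkage group.
    The smoothed value at marker i is ``sum_j w_ij v_j / sum_j w_ij`` over
    markers j with ``|pos_j - pos_i| <= half_width``, with
    ``w = (1 - (d / half_width)^3)^3``.  ``values`` may be 1-D (n,) or
    2-D (n, k) to smooth several statistics in one pass.
    """
    pos = np.asarray(positions, dtype=float)
    vals = np.asarray(values, dtype=float)
    if half_width <= 0:
        raise ValueError("half_width must be positive")
    if pos.size == 0:
        return vals.copy()
    if np.any(np.diff(pos) < 0):
        raise ValueError("positions must be sorted ascending")
    one_d = vals.ndim == 1
    v = vals[:, None] if one_d else vals
    n = len(pos)
    out = np.empty_like(v)
    left = 0
    right = 0
    for i in range(n):
        lo = pos[i] - half_width
        hi = pos[i] + half_width
        while pos[left] < lo:
            left += 1
        if right < i + 1:
            right = i + 1
        while right < n and pos[right] <= hi:
            right += 1
        d = np.abs(pos[left:right] - pos[i]) / half_width
        w = (1.0 - d ** 3) ** 3
        out[i] = w @ v[left:right] / w.sum()
    return out[:, 0] if one_d else out


def compute_stats(markers: pd.DataFrame, half_width: float = 1_000_000.0,
                  smooth_delta: bool = True, smooth_ed5: bool = True,
                  ed_mode: str = "frequency") -> pd.DataFrame:
    """All per-marker statistics for a filtered marker table.

    Adds SNP-index per bulk, delta_index, g_stat, ed, ed5, and the
    tricube-smoothed columns g_prime (always), delta_smooth and ed5_smooth
    (optional).  Smoothing is per linkage group; the input must be sorted
    by (linkage_group, position).
    """
    out = markers.reset_index(drop=True).copy()
    idx_high = snp_index(out["ref_high"].to_numpy(),
                         out["alt_high"].to_numpy())
    idx_low = snp_index(out["ref_low"].to_numpy(), out["alt_low"].to_numpy())
    out["snp_index_high"] = idx_high
    out["snp_index_low"] = idx_low
    out["delta_index"] = delta_snp_index(idx_high, idx_low)
    out["g_stat"] = g_statistic(out["ref_high"].to_numpy(),
                                out["alt_high"].to_numpy(),
                                out["ref_low"].to_numpy(),
                                out["alt_low"].to_numpy())
    if ed_mode == "frequency":
        ed, ed5 = euclidean_distance(idx_high, idx_low)
    elif ed_mode == "depth":
        ed, ed5 = euclidean_distance_depths(
            out["ref_high"].to_numpy(), out["alt_high"].to_numpy(),
            out["ref_low"].to_numpy(), out["alt_low"].to_numpy())
    else:
        raise ValueError(f"unknown ed_mode: {ed_mode!r}")
    out["ed"] = ed
    out["ed5"] = ed5

    cols = ["g_stat"]
    if smooth_delta:
        cols.append("delta_index")
    if smooth_ed5:
        cols.append("ed5")
    smoothed = np.empty((len(out), len(cols)))
    for _, idx in out.groupby("linkage_group", sort=False).indices.items():
        pos = out["position"].to_numpy()[idx]
        smoothed[idx] = tricube_smooth(pos, out[cols].to_numpy()[idx],
                                       half_width)
    out["g_prime"] = smoothed[:, 0]
    if smooth_delta:
        out["delta_smooth"] = smoothed[:, cols.index("delta_index")]
    if smooth_ed5:
        out["ed5_smooth"] = smoothed[:, cols.index("ed5")]
    return out
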