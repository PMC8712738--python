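"""Significance thresholds for the three divergence statistics.

Each statistic gets its own null calibration, matching how pooled-bulk
studies treat them:

* **SNP-index / Delta(SNP-index)** -- Monte-Carlo confidence bands: the
  null sampling chain (bulk composition given population type and pool
  size, then binomial read sampling at a given depth) is simulated many
  times per depth, and central quantile bands of the simulated index and
  delta are taken as the fluctuation range attributable to sampling alone.
* **G'** -- a parametric null: log G' is cleaned with the Hampel rule
  (median +- 3 x 1.4826 x MAD) and a normal distribution fitted to the
  retained values, i.e. a trimmed log-normal null for G'; upper-tail
  p-values are Benjamini-Hochberg corrected to q-values thresholded at
  0.05 / 0.01.
* **ED^5** -- empirical genome-wide quantiles (0.95 / 0.99) of the
  observed values.

Quantiles use the empirical inverse-CDF (type-1) definition throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from bsrmap.synthetic import PopulationModel, sample_bulk_allele_freqs

QUANTILE_METHOD = "inverted_cdf"
MAD_SCALE = 1.4826  # normal-consistency factor for the MAD
HAMPEL_K = 3.0


class DegenerateNullError(ValueError):
    """Raised when the trimmed G' null has zero variance."""


@dataclass
class ThresholdTable:
    """Thresholds for one method plus simulation metadata.

    For ``SNP_INDEX``, ``bands`` holds one row per (depth, level) with the
    central quantile band of the simulated per-bulk index and of delta.
    For ``G_PRIME``, ``alpha`` maps confidence level -> q-value cutoff.
    For ``ED5``, ``quantiles`` maps level -> genome-wide ED^5 quantile.
    """

    method: str
    bands: pd.DataFrame | None = None
    alpha: dict[float, float] = field(default_factory=dict)
    quantiles: dict[float, float] = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    def delta_band(self, depths, level: float):
        """(low, high) delta band at the given level, linearly
        interpolated in depth and clamped to the simulated grid."""
        return self._interp(depths, level, "delta_low", "delta_high")

    def index_band(self, depths, level: float):
        return self._interp(depths, level, "index_low", "index_high")

    def _interp(self, depths, level, lo_col, hi_col):
        if self.bands is None:
            raise ValueError(f"no simulated bands on {self.method} table")
        sub = self.bands[np.isclose(self.bands["level"], level)]
        if sub.empty:
            raise KeyError(f"level {level} not simulated")
        sub = sub.sort_values("depth")
        d = np.asarray(depths, dtype=float)
        lo = np.interp(d, sub["depth"], sub[lo_col])
        hi = np.interp(d, sub["depth"], sub[hi_col])
        return lo, hi

    def ed5_cutoff(self, level: float) -> float:
        if level not in self.quantiles:
            raise KeyError(f"level {level} not available")
        return self.quantiles[level]

    def gprime_alpha(self, level: float) -> float:
        if level not in self.alpha:
            raise KeyError(f"level {level} not available")
        return self.alpha[level]

    def to_frame(self) -> pd.DataFrame:
        if self.method == "SNP_INDEX":
            return self.bands.copy()
        if self.method == "G_PRIME":
            return pd.DataFrame(
                [{"level": lv, "q_cutoff": a} for lv, a in self.alpha.items()])
        return pd.DataFrame(
            [{"level": lv, "ed5_quantile": q}
             for lv, q in self.quantiles.items()])


def simulate_index_bands(model: PopulationModel, depths,
                         n_sims: int = 10_000,
                         levels=(0.95, 0.99), seed: int = 0,
                         ) -> ThresholdTable:
    """Monte-Carlo confidence bands for SNP-index and Delta(SNP-index).

    For each depth, draws ``n_sims`` null replicates: each bulk's pooled
    allele frequency from the population model at its null frequency,
    then binomial read counts at that depth, giving one simulated
    (index_high, index_low, delta) triple.  Bands are the central
    type-1 quantile intervals at each confidence level; the per-bulk
    index band pools both bulks' simulated indices.
    """
    if n_sims < 100:
        raise ValueError("n_sims must be >= 100")
    depths = sorted({int(d) for d in np.atleast_1d(depths)})
    if min(depths) < 1:
        raise ValueError("depths must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    p0 = model.null_freq
    rows = []
    for d in depths:
        f_hi = sample_bulk_allele_freqs(model, p0, n_sims, rng)
        f_lo = sample_bulk_allele_freqs(model, p0, n_sims, rng)
        idx_hi = rng.binomial(d, f_hi) / d
        idx_lo = rng.binomial(d, f_lo) / d
        delta = idx_hi - idx_lo
        pooled = np.concatenate([idx_hi, idx_lo])
        for lv in sorted(levels):
            tail = (1.0 - lv) / 2.0
            rows.append({
                "depth": d, "level": lv,
                "index_low": float(np.quantile(pooled, tail,
                                               method=QUANTILE_METHOD)),
                "index_high": float(np.quantile(pooled, 1 - tail,
                                                method=QUANTILE_METHOD)),
                "delta_low": float(np.quantile(delta, tail,
                                               method=QUANTILE_METHOD)),
                "delta_high": float(np.quantile(delta, 1 - tail,
                                                method=QUANTILE_METHOD)),
            })
    meta = {"n_sims": n_sims, "seed": seed, "population": model.kind,
            "n_per_bulk": model.n_per_bulk, "null_freq": p0,
            "quantile_rule": QUANTILE_METHOD, "depths": depths}
    return ThresholdTable(method="SNP_INDEX", bands=pd.DataFrame(rows),
                          meta=meta)


def gprime_null_pvalues(g_prime) -> np.ndarray:
    """Upper-tail p-values for G' under a Hampel-trimmed log-normal null.

    Takes ln G', discards values outside median +- 3 x 1.4826 x MAD
    (the Hampel rule), fits Normal(mu, sigma) to the retained values, and
    returns ``p_i = P(Z > ln G'_i)`` under that fit.  G' = 0 markers are
    excluded from the fit and assigned p = 1.  Raises
    :class:`DegenerateNullError` if the trimmed null has zero spread.
    """
    g = np.asarray(g_prime, dtype=float)
    if np.any(g < 0):
        raise ValueError("G' values must be non-negative")
    pos = g > 0
    if not np.any(pos):
        raise DegenerateNullError("no positive G' values to fit")
    ln_g = np.log(g[pos])
    med = np.median(ln_g)
    mad = np.median(np.abs(ln_g - med))
    keep = np.abs(ln_g - med) <= HAMPEL_K * MAD_SCALE * mad
    trimmed = ln_g[keep]
    mu = float(np.mean(trimmed))
    sigma = float(np.std(trimmed, ddof=1)) if trimmed.size > 1 else 0.0
    if not np.isfinite(sigma) or sigma <= 1e-12 * max(1.0, abs(mu)):
        raise DegenerateNullError(
            "trimmed ln G' null has zero variance (all values equal?)")
    p = np.ones_like(g)
    p[pos] = sps.norm.sf(ln_g, loc=mu, scale=sigma)
    return p


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must be in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def ed5_quantile_thresholds(ed5, levels=(0.95, 0.99)) -> ThresholdTable:
    """Genome-wide empirical (type-1) quantiles of ED^5."""
    v = np.asarray(ed5, dtype=float)
    if v.size == 0:
        raise ValueError("no ED^5 values")
    quantiles = {float(lv): float(np.quantile(v, lv, method=QUANTILE_METHOD))
                 for lv in levels}
    return ThresholdTable(method="ED5", quantiles=quantiles,
                          meta={"n_markers": int(v.size),
                                "quantile_rule": QUANTILE_METHOD})


def gprime_thresholds(levels=(0.95, 0.99)) -> ThresholdTable:
    """q-value cutoffs per confidence level (0.95 -> 0.05, 0.99 -> 0.01)."""
    alpha = {float(lv): round(1.0 - float(lv), 10) for lv in levels}
    return ThresholdTable(method="G_PRIME", alpha=alpha,
                          meta={"tail": "upper", "correction": "fdr_bh"})
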