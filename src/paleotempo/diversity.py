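"""Range-through taxonomic diversity and the diversity-disparity trajectory.

Diversity per bin counts every taxon whose first-last appearance interval
covers the bin (range-through assumption).  The joint trajectory plots
range-standardized log diversity against range-standardized disparity: under
constant-rate Brownian-motion-like phenotypic change, log taxon count and
disparity grow in proportion, so the trajectory tracks the 1:1 diagonal.
Points above the diagonal mean disparity is outpacing diversification;
points below mean the reverse.  Whether a deviation is significant is judged
by a paired-bootstrap percentile interval of (y - x) excluding zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_io import StratRanges, Timescale
from .disparity import DisparitySeries

__all__ = [
    "DiversitySeries",
    "range_through_counts",
    "bootstrap_counts",
    "range_standardize",
    "dd_trajectory",
]


@dataclass
class DiversitySeries:
    """Per-bin range-through counts with bootstrap intervals."""

    bin_names: list[str]
    counts: np.ndarray
    boot_mean: np.ndarray = None
    lo95: np.ndarray = None
    hi95: np.ndarray = None
    replicates: np.ndarray = field(repr=False, default=None)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"bin": self.bin_names, "count": self.counts})
        if self.boot_mean is not None:
            df["boot_mean"] = self.boot_mean
            df["lo95"] = self.lo95
            df["hi95"] = self.hi95
        return df


def _counts_from_ranges(first: np.ndarray, last: np.ndarray, n_bins: int) -> np.ndarray:
    bins = np.arange(n_bins)
    return ((first[:, None] <= bins[None, :]) & (bins[None, :] <= last[:, None])).sum(axis=0)


def range_through_counts(r: StratRanges, ts: Timescale) -> DiversitySeries:
    """Taxa per bin under the range-through assumption."""
    taxa = r.taxa
    first = np.array([r.first[t] for t in taxa])
    last = np.array([r.last[t] for t in taxa])
    if len(taxa) and last.max() >= len(ts):
        bad = [t for t in taxa if r.last[t] >= len(ts)]
        raise ValueError(f"ranges reference bins outside the timescale: {bad[:5]}")
    return DiversitySeries(bin_names=ts.names, counts=_counts_from_ranges(first, last, len(ts)))


def bootstrap_counts(
    r: StratRanges, ts: Timescale, n_boot: int = 1000, seed: int | None = None
) -> DiversitySeries:
    """Monte-Carlo uncertainty on range-through counts: resample taxa with
    replacement and recompute; 95% percentile intervals per bin."""
    if len(r) < 2:
        raise ValueError("need >= 2 taxa to bootstrap")
    rng = np.random.default_rng(seed)
    taxa = r.taxa
    first = np.array([r.first[t] for t in taxa])
    last = np.array([r.last[t] for t in taxa])
    base = _counts_from_ranges(first, last, len(ts))
    reps = np.zeros((n_boot, len(ts)))
    for i in range(n_boot):
        take = rng.integers(0, len(taxa), size=len(taxa))
        reps[i] = _counts_from_ranges(first[take], last[take], len(ts))
    return DiversitySeries(
        bin_names=ts.names,
        counts=base,
        boot_mean=reps.mean(axis=0),
        lo95=np.percentile(reps, 2.5, axis=0),
        hi95=np.percentile(reps, 97.5, axis=0),
        replicates=reps,
    )


def range_standardize(x) -> np.ndarray:
    """Affine rescale of a series onto [0, 1]: (x - min) / (max - min).

    NaNs pass through; a constant series has no scale and is an error.
    """
    x = np.asarray(x, dtype=float)
    lo, hi = np.nanmin(x), np.nanmax(x)
    if not np.isfinite(lo) or hi == lo:
        raise ValueError("range standardization undefined for a constant series")
    return (x - lo) / (hi - lo)


def dd_trajectory(
    div: DiversitySeries, disp: DisparitySeries, min_count: int = 1
) -> pd.DataFrame:
    """Diversity-disparity trajectory with paired-bootstrap deviations.

    Per usable bin (disparity defined, count >= ``min_count``):
    x = range-standardized ln(count), y = range-standardized disparity,
    deviation = y - x.  Replicate r of the diversity bootstrap is paired
    with replicate r of the disparity bootstrap and pushed through the same
    log + standardization pipeline, giving a 95% percentile interval on each
    deviation; a bin is classified "above"/"below" the 1:1 line only when
    that interval excludes zero, else "on".

    The natural log is used; the base is irrelevant after range
    standardization.  Multiplying all counts by a constant leaves the
    trajectory unchanged for the same reason.
    """
    if list(div.bin_names) != list(disp.bin_names):
        raise ValueError("diversity and disparity series must share one bin set")
    use = np.isfinite(disp.point) & (div.counts >= min_count)
    if use.sum() < 2:
        raise ValueError("need >= 2 usable bins (defined disparity, positive counts)")
    x = range_standardize(np.log(div.counts[use].astype(float)))
    y = range_standardize(disp.point[use])
    dev = y - x

    lo = np.full(dev.shape, np.nan)
    hi = np.full(dev.shape, np.nan)
    if div.replicates is not None and disp.replicates is not None:
        n_boot = min(div.replicates.shape[0], disp.replicates.shape[0])
        devs = np.full((n_boot, int(use.sum())), np.nan)
        for r in range(n_boot):
            with np.errstate(divide="ignore", invalid="ignore"):
                xr = np.log(div.replicates[r, use])
            yr = disp.replicates[r, use]
            xr[~np.isfinite(xr)] = np.nan
            if (np.nanmax(xr) == np.nanmin(xr)) or (np.nanmax(yr) == np.nanmin(yr)):
                continue  # degenerate replicate: no scale
            xs = (xr - np.nanmin(xr)) / (np.nanmax(xr) - np.nanmin(xr))
            ys = (yr - np.nanmin(yr)) / (np.nanmax(yr) - np.nanmin(yr))
            devs[r] = ys - xs
        import warnings

        with np.errstate(invalid="ignore"), warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN bins
            lo = np.nanpercentile(devs, 2.5, axis=0)
            hi = np.nanpercentile(devs, 97.5, axis=0)

    cls = np.where(lo > 0, "above", np.where(hi < 0, "below", "on"))
    return pd.DataFrame(
        {
            "bin": [b for b, u in zip(div.bin_names, use) if u],
            "log_diversity_std": x,
            "disparity_std": y,
            "deviation": dev,
            "dev_lo95": lo,
            "dev_hi95": hi,
            "classification": cls,
        }
    )
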