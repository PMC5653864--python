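"""Gower distances, disparity through time, and principal-coordinates
morphospace.

The pairwise dissimilarity between two taxa is the Gower distance over the
unordered characters codable in both: the fraction of comparable characters
whose state tokens differ.  (The classic Gower coefficient is the
complementary *similarity* sum(S_ijk)/sum(delta_ijk), where delta_ijk flags
character k codable in both taxa; with unordered tokens the per-character
similarity is 1 for a match and 0 otherwise, so distance = 1 - similarity =
differences / comparable count.)  For a complete binary matrix this is
exactly Hamming distance / n_characters.

Disparity of a taxon set is the mean squared pairwise distance; its
uncertainty comes from bootstrap resampling of taxa (disparity is a
between-taxon statistic, so taxa — not characters — are resampled).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, stats

from .data_io import MISSING, CharacterMatrix, StratRanges, Timescale, TimeTree

__all__ = [
    "DistanceMatrix",
    "Ordination",
    "DisparitySeries",
    "gower",
    "msd_disparity",
    "disparity_series",
    "bin_membership",
    "pco",
    "ancestral_scores",
    "axis_trait_correlation",
]


class DisparityError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Gower distances
# ---------------------------------------------------------------------------


@dataclass
class DistanceMatrix:
    """Symmetric pairwise Gower distances in [0, 1].

    ``values[i, j]`` is NaN where a pair shares no comparable character;
    such pairs are listed in :meth:`undefined_pairs` and must be resolved
    (drop a taxon, or impute) before ordination.
    """

    labels: list[str]
    values: np.ndarray
    comparable: np.ndarray  # per-pair comparable-character counts

    def __len__(self) -> int:
        return len(self.labels)

    def undefined_pairs(self) -> list[tuple[str, str]]:
        i, j = np.where(np.triu(~np.isfinite(self.values), k=1))
        return [(self.labels[a], self.labels[b]) for a, b in zip(i, j)]

    def submatrix(self, taxa) -> "DistanceMatrix":
        idx = [self.labels.index(t) for t in taxa]
        return DistanceMatrix(
            labels=list(taxa),
            values=self.values[np.ix_(idx, idx)].copy(),
            comparable=self.comparable[np.ix_(idx, idx)].copy(),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


def gower(m: CharacterMatrix, informative_only: bool = True) -> DistanceMatrix:
    """Pairwise Gower distances from a character matrix.

    MISSING cells are excluded from both the difference count and the
    comparable count.  Invariant characters are excluded by default — they
    can only dilute distances.
    """
    if m.n_taxa < 2:
        raise DisparityError("need >= 2 taxa")
    codes = m.codes
    if informative_only:
        codes = codes[:, m.informative_mask()]
    scored = codes != MISSING
    both = scored[:, None, :] & scored[None, :, :]
    differ = (codes[:, None, :] != codes[None, :, :]) & both
    comp = both.sum(axis=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        d = differ.sum(axis=2) / comp
    d[comp == 0] = np.nan
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(labels=list(m.taxon_labels), values=d, comparable=comp)


def msd_disparity(d: DistanceMatrix, taxa=None) -> float:
    """Mean squared pairwise distance over a taxon multiset.

    Duplicated labels (as arise under bootstrap resampling) are legitimate
    and contribute zero-distance pairs.  NaN for fewer than two taxa; an
    undefined constituent pair is an error naming the pair.
    """
    if taxa is None:
        sub = d.values
        labels = d.labels
    else:
        idx = [d.labels.index(t) for t in taxa]
        sub = d.values[np.ix_(idx, idx)]
        labels = list(taxa)
    n = sub.shape[0]
    if n < 2:
        return float("nan")
    iu = np.triu_indices(n, k=1)
    vals = sub[iu]
    if not np.all(np.isfinite(vals)):
        bad = [(labels[a], labels[b]) for a, b in zip(*iu) if not np.isfinite(sub[a, b])]
        raise DisparityError(f"undefined distances for pairs: {bad[:5]}")
    return float(np.mean(vals ** 2))


# ---------------------------------------------------------------------------
# Disparity through time
# ---------------------------------------------------------------------------


def bin_membership(ranges: StratRanges, ts: Timescale) -> dict[str, list[str]]:
    """Range-through occupancy: a taxon occupies every bin its stratigraphic
    range crosses."""
    out: dict[str, list[str]] = {name: [] for name in ts.names}
    for t in ranges.taxa:
        for b in range(ranges.first[t], ranges.last[t] + 1):
            out[ts.names[b]].append(t)
    return out


@dataclass
class DisparitySeries:
    """Per-bin disparity with bootstrap uncertainty.

    ``replicates[r, b]`` holds bootstrap replicate ``r`` for bin ``b`` (NaN
    for bins with < 2 taxa), kept so downstream statistics (e.g. the
    diversity-disparity trajectory) can pair replicates.
    """

    bin_names: list[str]
    n_taxa: np.ndarray
    point: np.ndarray
    boot_mean: np.ndarray
    lo95: np.ndarray
    hi95: np.ndarray
    replicates: np.ndarray = field(repr=False, default=None)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin": self.bin_names,
                "n_taxa": self.n_taxa,
                "disparity": self.point,
                "boot_mean": self.boot_mean,
                "lo95": self.lo95,
                "hi95": self.hi95,
            }
        )


def disparity_series(
    d: DistanceMatrix,
    membership: dict[str, list[str]],
    n_boot: int = 1000,
    seed: int | None = None,
) -> DisparitySeries:
    """Disparity per time bin with taxon-bootstrap percentile intervals.

    Bins holding fewer than two taxa get NaN throughout (count retained in
    ``n_taxa``).
    """
    rng = np.random.default_rng(seed)
    bins = list(membership)
    nb = len(bins)
    point = np.full(nb, np.nan)
    reps = np.full((n_boot, nb), np.nan)
    n_taxa = np.zeros(nb, dtype=int)
    lut = {t: i for i, t in enumerate(d.labels)}
    for bi, b in enumerate(bins):
        taxa = membership[b]
        n_taxa[bi] = len(taxa)
        if len(taxa) < 2:
            continue
        idx = np.array([lut[t] for t in taxa])
        sub = d.values[np.ix_(idx, idx)] ** 2
        if not np.all(np.isfinite(sub)):
            raise DisparityError(f"bin {b!r}: undefined pairwise distances")
        iu = np.triu_indices(len(idx), k=1)
        point[bi] = sub[iu].mean()
        for r in range(n_boot):
            res = rng.integers(0, len(idx), size=len(idx))
            rsub = sub[np.ix_(res, res)]
            reps[r, bi] = rsub[np.triu_indices(len(res), k=1)].mean()
    import warnings

    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN bins
        return DisparitySeries(
            bin_names=bins,
            n_taxa=n_taxa,
            point=point,
            boot_mean=np.nanmean(reps, axis=0) if n_boot else np.full(nb, np.nan),
            lo95=np.nanpercentile(reps, 2.5, axis=0) if n_boot else np.full(nb, np.nan),
            hi95=np.nanpercentile(reps, 97.5, axis=0) if n_boot else np.full(nb, np.nan),
            replicates=reps,
        )


# ---------------------------------------------------------------------------
# Principal coordinates
# ---------------------------------------------------------------------------


@dataclass
class Ordination:
    """Classical-scaling (PCO) result.

    ``proportion_explained`` is each positive eigenvalue's share of the
    positive-eigenvalue sum; negative eigenvalues (non-Euclidean input) are
    reported but carry no axes.
    """

    labels: list[str]
    eigenvalues: np.ndarray            # all, sorted descending
    scores: np.ndarray                 # (n_taxa, n_positive_axes)
    proportion_explained: np.ndarray   # per positive axis
    correction: str = "none"

    @property
    def n_axes(self) -> int:
        return self.scores.shape[1]

    def to_frame(self) -> pd.DataFrame:
        cols = [f"PCO{i + 1}" for i in range(self.n_axes)]
        return pd.DataFrame(self.scores, index=self.labels, columns=cols)


def _double_center(d2: np.ndarray) -> np.ndarray:
    n = d2.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    return -0.5 * j @ d2 @ j


def _cailliez_constant(d: np.ndarray) -> float:
    # smallest c such that d_ij + c (i != j) is Euclidean (Cailliez 1983)
    n = d.shape[0]
    d1 = _double_center(d ** 2)
    d2 = _double_center(d)
    upper = np.hstack([np.zeros((n, n)), 2.0 * d1])
    lower = np.hstack([-np.eye(n), -4.0 * d2])
    eig = np.linalg.eigvals(np.vstack([upper, lower]))
    return float(max(0.0, np.max(eig.real)))


def pco(d: DistanceMatrix, correction: str = "none", eps: float = 1e-9) -> Ordination:
    """Principal coordinates analysis (classical metric scaling).

    Double-centers the squared distances, eigendecomposes, and keeps the
    positive axes; ``correction='cailliez'`` first adds the smallest additive
    constant making the distances Euclidean (useful when missing data make
    the Gower matrix non-metric).
    """
    if d.undefined_pairs():
        raise DisparityError(
            "distance matrix has undefined pairs; drop taxa or impute before "
            f"ordination: {d.undefined_pairs()[:5]}"
        )
    dd = d.values.copy()
    if correction == "cailliez":
        c = _cailliez_constant(dd)
        dd = dd + c
        np.fill_diagonal(dd, 0.0)
    elif correction != "none":
        raise ValueError(f"unknown correction {correction!r}")
    b = _double_center(dd ** 2)
    w, v = linalg.eigh((b + b.T) / 2.0)
    order = np.argsort(w)[::-1]
    w, v = w[order], v[:, order]
    pos = w > eps * max(1.0, abs(w[0]))
    scores = v[:, pos] * np.sqrt(w[pos])
    return Ordination(
        labels=list(d.labels),
        eigenvalues=w,
        scores=scores,
        proportion_explained=w[pos] / w[pos].sum(),
        correction=correction,
    )


# ---------------------------------------------------------------------------
# Phylomorphospace ancestral scores
# ---------------------------------------------------------------------------


def ancestral_scores(tree: TimeTree, tip_values) -> np.ndarray:
    """Brownian-motion ML ancestral values for a continuous tip trait
    (e.g. an ordination axis score), one value per tree node.

    Equivalent to the generalized-least-squares reconstruction: the ML
    estimates minimize sum over branches of (x_parent - x_child)^2 / length,
    a weighted-Laplacian linear solve with tips clamped to their scores.
    Zero-length branches act as (near-)rigid links, so a node on a
    zero-length branch takes its child's value.
    """
    if isinstance(tip_values, dict):
        vals = np.array([tip_values[l] for l in tree.tip_labels], dtype=float)
    else:
        vals = np.asarray(tip_values, dtype=float)
        if vals.size != tree.n_tips:
            raise ValueError("one tip value per tip required")
    n = tree.n_nodes
    x = np.zeros(n)
    x[tree.tip_indices] = vals
    internal = np.flatnonzero(~tree.is_tip)
    pos = {int(v): i for i, v in enumerate(internal)}
    mean_len = max(float(tree.duration[tree.duration > 0].mean()) if np.any(tree.duration > 0) else 1.0, 1e-12)
    A = np.zeros((internal.size, internal.size))
    rhs = np.zeros(internal.size)
    for i in range(n):
        if i == tree.root:
            continue
        p = int(tree.parent[i])
        w = 1.0 / max(float(tree.duration[i]), 1e-9 * mean_len)
        for end_a, end_b in ((i, p), (p, i)):
            if not tree.is_tip[end_a]:
                ia = pos[end_a]
                A[ia, ia] += w
                if tree.is_tip[end_b]:
                    rhs[ia] += w * x[end_b]
                else:
                    A[ia, pos[end_b]] -= w
    x[internal] = np.linalg.solve(A, rhs)
    return x


def axis_trait_correlation(scores, trait) -> dict:
    """Spearman rank correlation (tie-corrected) between an ordination axis
    and an ecological trait; missing trait values are pairwise-deleted and
    the retained count reported."""
    s = np.asarray(scores, dtype=float)
    t = np.asarray(trait, dtype=float)
    ok = np.isfinite(s) & np.isfinite(t)
    if ok.sum() < 4:
        raise DisparityError(f"need >= 4 taxa scored on both, have {int(ok.sum())}")
    if np.unique(t[ok]).size < 2 or np.unique(s[ok]).size < 2:
        return {"rho": float("nan"), "p": float("nan"), "n": int(ok.sum())}
    rho, p = stats.spearmanr(s[ok], t[ok])
    return {"rho": float(rho), "p": float(p), "n": int(ok.sum())}
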