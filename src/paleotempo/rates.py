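"""Rates of discrete character evolution on time-calibrated trees.

The per-branch rate of morphological evolution is the number of inferred
character changes along a branch divided by the product of the branch
duration and the proportion of characters comparable at both of its ends.
Changes are inferred by comparing maximum-likelihood marginal ancestral
states (symmetric Mk model, per-character rate fitted by 1-D ML) at the two
ends of each branch.  Branches are then partitioned across the bins of a
chronostratigraphic timescale, each bin's pooled rate is tested against the
pooled remainder with a Poisson likelihood-ratio test (Benjamini-Hochberg
corrected across bins within a tree), and the per-tree verdicts are
aggregated over a posterior sample of trees into HIGH / LOW / BACKGROUND
calls per bin.

Likelihood machinery is vectorized across characters.  For a symmetric
k-state Mk process with total change rate r the transition probability over
time t has the closed form

    P(same)  = 1/k + (k-1)/k * exp(-k r t / (k - 1))
    P(other) = 1/k -   1/k   * exp(-k r t / (k - 1))

so a pruning step reduces to ``p_diff * sum(L) + exp(...) * L`` per state —
no matrix exponentials are needed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln, xlogy
from statsmodels.stats.multitest import multipletests

from .data_io import MISSING, CharacterMatrix, Timescale, TimeTree

__all__ = [
    "ASRResult",
    "MultiASR",
    "BranchChangeTable",
    "BinSegmentTable",
    "BinRateResult",
    "mk_asr",
    "mk_asr_all",
    "count_branch_changes",
    "branch_rate",
    "partition_by_bins",
    "bin_lrt",
    "bh_adjust",
    "tree_bin_rates",
    "rates_over_trees",
    "aggregate_over_trees",
    "rate_trend",
]

_RATE_LO, _RATE_HI = 1e-8, 10.0  # changes/Myr bracket for the 1-D rate ML


class RateAnalysisError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Vectorized Mk pruning
# ---------------------------------------------------------------------------


def _align(tree: TimeTree, matrix: CharacterMatrix) -> np.ndarray:
    """Row index into ``matrix`` for each tree tip (by label)."""
    lut = {t: i for i, t in enumerate(matrix.taxon_labels)}
    missing = [l for l in tree.tip_labels if l not in lut]
    if missing:
        raise RateAnalysisError(f"tree tips absent from matrix: {missing[:5]}")
    return np.array([lut[l] for l in tree.tip_labels])


class _MkEngine:
    """Shared pruning state for one (tree, matrix) pair.

    Characters are padded to the maximum state count and masked, so every
    pass is a single sweep of numpy operations over all characters at once.
    """

    def __init__(self, tree: TimeTree, matrix: CharacterMatrix, char_indices: np.ndarray):
        self.tree = tree
        self.char_indices = np.asarray(char_indices)
        rows = _align(tree, matrix)
        codes = matrix.codes[np.ix_(rows, self.char_indices)]  # (n_tips, nc)
        # recode onto observed states only (k = number of observed states)
        self.k = np.zeros(len(self.char_indices), dtype=np.int64)
        self.state_maps: list[np.ndarray] = []  # engine state -> matrix code
        recoded = np.full_like(codes, MISSING)
        for j in range(codes.shape[1]):
            col = codes[:, j]
            observed = np.unique(col[col != MISSING])
            self.k[j] = observed.size
            self.state_maps.append(observed)
            lut = {int(s): i for i, s in enumerate(observed)}
            recoded[:, j] = [lut[int(c)] if c != MISSING else MISSING for c in col]
        if np.any(self.k < 2):
            bad = self.char_indices[self.k < 2]
            raise RateAnalysisError(f"invariant characters passed to Mk engine: {bad}")
        self.kmax = int(self.k.max())
        nc = len(self.char_indices)
        self.mask = np.arange(self.kmax)[None, :] < self.k[:, None]  # (nc, kmax)
        self.prior = self.mask / self.k[:, None]

        n = tree.n_nodes
        self.tipL = np.zeros((tree.n_tips, nc, self.kmax))
        for ti in range(tree.n_tips):
            for j in range(nc):
                c = recoded[ti, j]
                if c == MISSING:
                    self.tipL[ti, j, : self.k[j]] = 1.0
                else:
                    self.tipL[ti, j, c] = 1.0
        self.tip_slot = np.full(n, -1, dtype=np.int64)
        for slot, node in enumerate(tree.tip_indices):
            self.tip_slot[int(node)] = slot

    # -- transition application -------------------------------------------
    def _propagate(self, L: np.ndarray, t: float, rate: np.ndarray) -> np.ndarray:
        """Apply P(t) to partial likelihoods L (nc, kmax); symmetric Mk."""
        a = np.exp(-self.k * rate * t / (self.k - 1))
        p_diff = (1.0 - a) / self.k
        out = p_diff[:, None] * L.sum(axis=1)[:, None] + a[:, None] * L
        out *= self.mask
        return out

    def down_pass(self, rate: np.ndarray, keep_messages: bool = False):
        """Post-order partials; returns (L, per-char log-likelihood[, msgs]).

        ``msgs[c]`` is the message from child c to its parent (after
        propagation along c's branch), needed by the marginal up-pass.
        """
        tree = self.tree
        nc, kmax = len(self.char_indices), self.kmax
        L = np.zeros((tree.n_nodes, nc, kmax))
        logscale = np.zeros(nc)
        msgs: dict[int, np.ndarray] = {}
        for i in tree.postorder:
            i = int(i)
            if tree.is_tip[i]:
                L[i] = self.tipL[self.tip_slot[i]]
                continue
            prod = np.ones((nc, kmax)) * self.mask
            for c in tree.children[i]:
                m = self._propagate(L[c], float(tree.duration[c]), rate)
                if keep_messages:
                    msgs[c] = m
                prod = prod * m
            s = prod.max(axis=1)
            s = np.where(s > 0, s, 1.0)
            L[i] = prod / s[:, None]
            logscale += np.log(s)
        root_like = (L[tree.root] * self.prior).sum(axis=1)
        loglik = np.log(np.maximum(root_like, 1e-300)) + logscale
        if keep_messages:
            return L, loglik, msgs
        return L, loglik

    def loglik(self, rate: np.ndarray) -> np.ndarray:
        return self.down_pass(rate)[1]

    def fit_rates(self, max_iter: int = 48) -> np.ndarray:
        """Per-character ML change rate by vectorized golden-section search
        on log10(rate) over [1e-8, 10] changes/Myr."""
        invphi = (math.sqrt(5.0) - 1.0) / 2.0
        a = np.full(len(self.char_indices), math.log10(_RATE_LO))
        b = np.full(len(self.char_indices), math.log10(_RATE_HI))
        c = b - invphi * (b - a)
        d = a + invphi * (b - a)
        fc = self.loglik(10.0 ** c)
        fd = self.loglik(10.0 ** d)
        for _ in range(max_iter):
            left = fc >= fd  # keep [a, d] where the left probe wins, else [c, b]
            a = np.where(left, a, c)
            b = np.where(left, d, b)
            c = b - invphi * (b - a)
            d = a + invphi * (b - a)
            # golden-ratio nesting: where left, the new d is the old c (value
            # reusable) and only the new c needs evaluating; mirrored on the
            # right.  One vectorized evaluation serves both cases.
            probe = np.where(left, c, d)
            f_probe = self.loglik(10.0 ** probe)
            fc_old = fc
            fc = np.where(left, f_probe, fd)
            fd = np.where(left, fc_old, f_probe)
        return 10.0 ** (0.5 * (a + b))

    def marginals(self, rate: np.ndarray) -> np.ndarray:
        """Marginal state probabilities (n_nodes, nc, kmax), masked rows
        normalized to 1."""
        tree = self.tree
        L, _, msgs = self.down_pass(rate, keep_messages=True)
        U = np.zeros_like(L)
        U[tree.root] = self.prior
        for i in tree.preorder:
            i = int(i)
            if tree.is_tip[i]:
                continue
            for c in tree.children[i]:
                outside = U[i].copy()
                for s in tree.children[i]:
                    if s != c:
                        outside = outside * msgs[s]
                m = self._propagate(outside, float(tree.duration[c]), rate)
                smax = m.max(axis=1)
                smax = np.where(smax > 0, smax, 1.0)
                U[c] = m / smax[:, None]
        post = L * U
        tot = post.sum(axis=2, keepdims=True)
        tot = np.where(tot > 0, tot, 1.0)
        return post / tot


# ---------------------------------------------------------------------------
# ASR results
# ---------------------------------------------------------------------------


@dataclass
class ASRResult:
    """Marginal ancestral reconstruction of one character."""

    character_index: int
    rate: float                   # fitted change rate (changes/Myr)
    loglik: float
    states: np.ndarray            # matrix state codes used by the engine
    marginals: np.ndarray         # (n_nodes, k) node marginal probabilities
    map_state: np.ndarray         # (n_nodes,) MAP matrix state code


@dataclass
class MultiASR:
    """Reconstruction of all informative characters on one tree."""

    char_indices: np.ndarray
    rates: np.ndarray
    logliks: np.ndarray
    k: np.ndarray
    marginals: np.ndarray         # (n_nodes, nc, kmax) in engine state space
    map_state: np.ndarray         # (n_nodes, nc) matrix state codes
    engine: "_MkEngine" = field(repr=False, default=None)


def mk_asr_all(tree: TimeTree, matrix: CharacterMatrix, rates: np.ndarray | None = None) -> MultiASR:
    """Fit per-character Mk rates by ML and reconstruct marginal ancestral
    states for every informative character; invariant characters are
    excluded (they carry no change signal)."""
    info = np.flatnonzero(matrix.subset_taxa(tree.tip_labels).informative_mask())
    if info.size == 0:
        raise RateAnalysisError("no informative characters")
    eng = _MkEngine(tree, matrix, info)
    if rates is None:
        rates = eng.fit_rates()
    rates = np.asarray(rates, dtype=float)
    logliks = eng.loglik(rates)
    marg = eng.marginals(rates)
    if not np.all(np.isfinite(marg)):
        raise RateAnalysisError("non-finite marginal probabilities")
    # MAP with deterministic tie-break: argmax returns the lowest index, and
    # engine states are sorted by matrix code, i.e. by state symbol
    masked = np.where(eng.mask[None, :, :], marg, -1.0)
    map_engine = masked.argmax(axis=2)
    map_code = np.zeros_like(map_engine)
    for j, sm in enumerate(eng.state_maps):
        map_code[:, j] = sm[map_engine[:, j]]
    return MultiASR(
        char_indices=info, rates=rates, logliks=logliks, k=eng.k,
        marginals=marg, map_state=map_code, engine=eng,
    )


def mk_asr(
    tree: TimeTree, matrix: CharacterMatrix, character_index: int, rate: float | None = None
) -> ASRResult:
    """Marginal Mk ancestral reconstruction of a single character.

    ``k`` is the number of states observed among scored cells; MISSING tips
    contribute a flat partial likelihood.  With ``rate=None`` the change rate
    is fitted by bounded 1-D ML.
    """
    col = matrix.codes[[matrix.taxon_labels.index(t) for t in tree.tip_labels], character_index]
    if np.unique(col[col != MISSING]).size < 2:
        raise RateAnalysisError(f"character {character_index} is invariant on these tips")
    eng = _MkEngine(tree, matrix, np.array([character_index]))
    r = eng.fit_rates() if rate is None else np.array([float(rate)])
    ll = eng.loglik(r)
    marg = eng.marginals(r)[:, 0, : eng.k[0]]
    map_engine = marg.argmax(axis=1)
    return ASRResult(
        character_index=character_index,
        rate=float(r[0]),
        loglik=float(ll[0]),
        states=eng.state_maps[0],
        marginals=marg,
        map_state=eng.state_maps[0][map_engine],
    )


# ---------------------------------------------------------------------------
# Branch change counting and rates
# ---------------------------------------------------------------------------


@dataclass
class BranchChangeTable:
    """Per-branch inferred changes and comparability.

    One row per non-root node (the branch above it): duration in Myr, number
    of comparable characters, inferred change count C, and the proportion
    comparable p = n_comparable / n_characters (informative characters
    only).
    """

    node: np.ndarray
    duration: np.ndarray
    n_comparable: np.ndarray
    changes: np.ndarray
    n_characters: int
    change_flags: np.ndarray  # (n_branches, nc) bool

    @property
    def proportion_comparable(self) -> np.ndarray:
        return self.n_comparable / self.n_characters

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "node": self.node,
                "duration_myr": self.duration,
                "n_comparable": self.n_comparable,
                "changes": self.changes,
                "proportion_comparable": self.proportion_comparable,
            }
        )


def count_branch_changes(
    tree: TimeTree, matrix: CharacterMatrix, asr: MultiASR
) -> BranchChangeTable:
    """Score a change wherever parent and child endpoint states differ.

    Endpoint states are observed states at scored tips and MAP marginal
    states at internal nodes.  A character is not comparable on a terminal
    branch whose tip is MISSING (internal nodes always have a MAP state);
    non-comparable characters contribute to neither the change count nor the
    comparable proportion.
    """
    rows = _align(tree, matrix)
    codes = matrix.codes[np.ix_(rows, asr.char_indices)]
    nc = len(asr.char_indices)
    branch_nodes = np.array([int(i) for i in tree.postorder if int(i) != tree.root])

    child_state = np.zeros((len(branch_nodes), nc), dtype=np.int64)
    comparable = np.ones((len(branch_nodes), nc), dtype=bool)
    parent_state = np.zeros_like(child_state)
    slot_of = {int(n): s for s, n in enumerate(tree.tip_indices)}
    for r, i in enumerate(branch_nodes):
        parent_state[r] = asr.map_state[tree.parent[i]]
        if tree.is_tip[i]:
            obs = codes[slot_of[int(i)]]
            comparable[r] = obs != MISSING
            child_state[r] = np.where(obs != MISSING, obs, 0)
        else:
            child_state[r] = asr.map_state[i]
    change = comparable & (child_state != parent_state)
    return BranchChangeTable(
        node=branch_nodes,
        duration=tree.duration[branch_nodes],
        n_comparable=comparable.sum(axis=1),
        changes=change.sum(axis=1),
        n_characters=nc,
        change_flags=change,
    )


def branch_rate(
    changes: float,
    duration: float,
    proportion_comparable: float,
    n_characters: int | None = None,
) -> float:
    """Changes / (duration x proportion comparable).

    Per-matrix units by default (changes per Myr of fully-comparable
    matrix); pass ``n_characters`` for changes/character/Myr.  Undefined
    (NaN) when duration or the comparable proportion is zero — callers must
    exclude such branches rather than propagate the NaN.
    """
    if duration <= 0 or proportion_comparable <= 0:
        return float("nan")
    r = changes / (duration * proportion_comparable)
    if n_characters is not None:
        r /= n_characters
    return r


# ---------------------------------------------------------------------------
# Bin partitioning
# ---------------------------------------------------------------------------


@dataclass
class BinSegmentTable:
    """Per-bin change counts and opportunity after slicing branches at bin
    boundaries.

    ``opportunity[b]`` = sum over branch segments of (segment duration x
    proportion comparable); ``changes[b]`` is the (possibly fractional)
    change count allocated to the bin.
    """

    bin_names: list[str]
    opportunity: np.ndarray
    changes: np.ndarray
    excluded_branches: list[dict] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"bin": self.bin_names, "changes": self.changes, "opportunity": self.opportunity}
        )


def partition_by_bins(
    table: BranchChangeTable,
    tree: TimeTree,
    ts: Timescale,
    allocation: str = "proportional",
    extend_edges: bool = False,
) -> BinSegmentTable:
    """Allocate branch changes and opportunity to time bins.

    ``allocation='proportional'`` slices each branch at bin boundaries,
    crediting opportunity exactly (segment duration x proportion comparable)
    and changes proportionally to segment duration (fractional counts
    allowed) — the expectation under within-branch rate homogeneity.
    ``allocation='midpoint'`` assigns the whole branch to the bin containing
    its temporal midpoint (sensitivity-analysis alternative).

    Zero-duration branches (sampled ancestors) have no time to allocate and
    are excluded (listed in ``excluded_branches`` with their change counts).
    With ``extend_edges`` the terminal bins absorb any overhang of the tree
    beyond the timescale span; otherwise an out-of-span branch is an error.
    """
    starts, ends = ts.starts().copy(), ts.ends().copy()
    span_old, span_young = starts[0], ends[-1]
    if extend_edges:
        starts[0] = np.inf
        ends[-1] = -np.inf
    n_bins = len(ts)
    T = np.zeros(n_bins)
    C = np.zeros(n_bins)
    excluded: list[dict] = []
    p = table.proportion_comparable
    for r in range(len(table.node)):
        node = int(table.node[r])
        young = float(tree.age[node])
        old = float(tree.age[tree.parent[node]])
        dur = old - young
        if dur <= 0:
            excluded.append(
                {"node": node, "reason": "zero_duration", "changes": int(table.changes[r])}
            )
            continue
        if not extend_edges and (old > span_old + 1e-9 or young < span_young - 1e-9):
            raise RateAnalysisError(
                f"branch above node {node} ([{young}, {old}] Ma) outside the "
                f"timescale span [{span_young}, {span_old}] Ma"
            )
        if allocation == "proportional":
            ov = np.clip(np.minimum(old, starts) - np.maximum(young, ends), 0.0, None)
            T += ov * p[r]
            C += table.changes[r] * ov / dur
        elif allocation == "midpoint":
            mid = float(np.clip(0.5 * (old + young), span_young, span_old))
            b = ts.bin_of_age(mid)
            T[b] += dur * p[r]
            C[b] += table.changes[r]
        else:
            raise ValueError(f"unknown allocation {allocation!r}")
    return BinSegmentTable(
        bin_names=ts.names, opportunity=T, changes=C, excluded_branches=excluded
    )


# ---------------------------------------------------------------------------
# Poisson likelihood-ratio test per bin
# ---------------------------------------------------------------------------


def _pois_loglik(c: float, lam: float, t: float) -> float:
    # gamma-function generalization so fractional allocated counts are valid
    if t <= 0:
        return 0.0
    return float(xlogy(c, lam * t) - lam * t - gammaln(c + 1.0))


def bin_lrt(seg: BinSegmentTable, focal: int) -> tuple[float, float, str]:
    """Test the focal bin's rate against the pooled remaining bins.

    Null: one Poisson rate for all bins (MLE sum(C)/sum(T)); alternative:
    separate rates for the focal bin and the pooled remainder.  Statistic
    2(lnL1 - lnL0) ~ chi-square with 1 df.  Returns (statistic, p,
    direction) with direction "high" iff the focal rate exceeds the
    remainder rate; (nan, nan, "na") when either side has zero opportunity.
    """
    Tb, Cb = float(seg.opportunity[focal]), float(seg.changes[focal])
    Tr = float(seg.opportunity.sum() - Tb)
    Cr = float(seg.changes.sum() - Cb)
    if Tb <= 0 or Tr <= 0:
        return float("nan"), float("nan"), "na"
    lam0 = (Cb + Cr) / (Tb + Tr)
    lam_b, lam_r = Cb / Tb, Cr / Tr
    l1 = _pois_loglik(Cb, lam_b, Tb) + _pois_loglik(Cr, lam_r, Tr)
    l0 = _pois_loglik(Cb, lam0, Tb) + _pois_loglik(Cr, lam0, Tr)
    stat = max(0.0, 2.0 * (l1 - l0))
    p = float(stats.chi2.sf(stat, df=1))
    return stat, p, ("high" if lam_b > lam_r else "low")


def bh_adjust(pvals, alpha: float = 0.01):
    """Benjamini-Hochberg step-up adjusted p-values and rejection flags.

    NaN entries (undefined tests) are passed through as NaN / not rejected
    and do not count toward the family size.
    """
    p = np.asarray(pvals, dtype=float)
    adj = np.full_like(p, np.nan)
    rej = np.zeros(p.shape, dtype=bool)
    ok = np.isfinite(p)
    if ok.any():
        r, a, *_ = multipletests(p[ok], alpha=alpha, method="fdr_bh")
        adj[ok] = a
        rej[ok] = a <= alpha
    return adj, rej


# ---------------------------------------------------------------------------
# Per-tree analysis and cross-tree aggregation
# ---------------------------------------------------------------------------


def tree_bin_rates(
    tree: TimeTree,
    matrix: CharacterMatrix,
    ts: Timescale,
    alpha: float = 0.01,
    allocation: str = "proportional",
    extend_edges: bool = False,
    significance: str = "raw",
) -> pd.DataFrame:
    """Full single-tree analysis: ASR -> branch changes -> bin partition ->
    per-bin LRT.  Returns one row per bin.

    ``significance`` selects which p-value the per-tree verdict uses:
    ``'raw'`` (default) flags bins with LRT p <= alpha — the cross-tree
    >55% aggregation is the guard against per-tree flukes — while ``'bh'``
    demands the Benjamini-Hochberg adjusted p (computed and reported either
    way) clear alpha within each tree.
    """
    asr = mk_asr_all(tree, matrix)
    table = count_branch_changes(tree, matrix, asr)
    seg = partition_by_bins(table, tree, ts, allocation=allocation, extend_edges=extend_edges)
    stats_, ps, dirs = [], [], []
    for b in range(len(ts)):
        st, p, d = bin_lrt(seg, b)
        stats_.append(st)
        ps.append(p)
        dirs.append(d)
    adj, rej_bh = bh_adjust(ps, alpha=alpha)
    if significance == "raw":
        rej = np.asarray([np.isfinite(p) and p <= alpha for p in ps])
    elif significance == "bh":
        rej = rej_bh
    else:
        raise ValueError(f"unknown significance rule {significance!r}")
    with np.errstate(invalid="ignore", divide="ignore"):
        rate = np.where(seg.opportunity > 0, seg.changes / seg.opportunity, np.nan)
        rate_pc = rate / table.n_characters
    return pd.DataFrame(
        {
            "bin": ts.names,
            "changes": seg.changes,
            "opportunity": seg.opportunity,
            "rate": rate,                      # changes/Myr, whole-matrix units
            "rate_per_char": rate_pc,          # changes/character/Myr
            "lrt_stat": stats_,
            "p": ps,
            "p_adj": adj,
            "direction": dirs,
            "significant": rej,
        }
    )


def rates_over_trees(
    trees: list[TimeTree],
    matrix: CharacterMatrix,
    ts: Timescale,
    alpha: float = 0.01,
    threshold: float = 0.55,
    allocation: str = "proportional",
    extend_edges: bool = False,
    significance: str = "raw",
) -> "BinRateResult":
    per_tree = [
        tree_bin_rates(t, matrix, ts, alpha=alpha, allocation=allocation,
                       extend_edges=extend_edges, significance=significance)
        for t in trees
    ]
    return aggregate_over_trees(per_tree, threshold=threshold)


@dataclass
class BinRateResult:
    """Cross-tree aggregation of per-bin rates and significance calls."""

    summary: pd.DataFrame          # one row per bin
    per_tree: list[pd.DataFrame]
    threshold: float

    def classes(self) -> pd.Series:
        return self.summary.set_index("bin")["class"]


def aggregate_over_trees(per_tree: list[pd.DataFrame], threshold: float = 0.55) -> BinRateResult:
    """Aggregate per-tree bin verdicts into HIGH / LOW / BACKGROUND calls.

    A bin is HIGH (LOW) when *strictly more than* ``threshold`` of the trees
    found it significantly high (low) after the within-tree B-H correction;
    rate summaries are percentile-based across trees (tree samples are small
    and skewed, so no normal approximation).
    """
    if not per_tree:
        raise ValueError("need >= 1 per-tree result")
    bins = per_tree[0]["bin"].tolist()
    rates = np.stack([df["rate"].to_numpy() for df in per_tree])          # (n_trees, n_bins)
    rates_pc = np.stack([df["rate_per_char"].to_numpy() for df in per_tree])
    sig = np.stack([df["significant"].to_numpy() for df in per_tree])
    high = np.stack([(df["direction"] == "high").to_numpy() for df in per_tree])
    frac_high = (sig & high).mean(axis=0)
    frac_low = (sig & ~high).mean(axis=0)
    cls = np.where(frac_high > threshold, "HIGH",
                   np.where(frac_low > threshold, "LOW", "BACKGROUND"))
    import warnings

    with np.errstate(invalid="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN bins
        summary = pd.DataFrame(
            {
                "bin": bins,
                "mean_rate": np.nanmean(rates, axis=0),
                "median_rate": np.nanmedian(rates, axis=0),
                "lo95_rate": np.nanpercentile(rates, 2.5, axis=0),
                "hi95_rate": np.nanpercentile(rates, 97.5, axis=0),
                "mean_rate_per_char": np.nanmean(rates_pc, axis=0),
                "frac_high": frac_high,
                "frac_low": frac_low,
                "class": cls,
            }
        )
    return BinRateResult(summary=summary, per_tree=per_tree, threshold=threshold)


def rate_trend(rates, midpoints_ma) -> dict:
    """Spearman rank correlation of per-bin rates against time.

    Time increases toward the present (i.e. the rank correlate is
    ``-midpoint_Ma``), so a secular slowdown yields a negative rho.  Bins
    with undefined rates are dropped; needs >= 4 defined bins.  The p-value
    is scipy's (exact for very small n, t-approximation otherwise).
    """
    r = np.asarray(rates, dtype=float)
    t = -np.asarray(midpoints_ma, dtype=float)
    ok = np.isfinite(r) & np.isfinite(t)
    if ok.sum() < 4:
        raise RateAnalysisError(f"need >= 4 bins with defined rates, have {int(ok.sum())}")
    if np.unique(r[ok]).size < 2:
        return {"rho": float("nan"), "p": float("nan"), "n": int(ok.sum())}
    rho, p = stats.spearmanr(t[ok], r[ok])
    return {"rho": float(rho), "p": float(p), "n": int(ok.sum())}
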