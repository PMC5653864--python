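"""Synthetic fossil clades with known ground truth.

Generates time-calibrated birth--death trees whose extinct lineages are kept
as dated fossil tips, evolves unordered multistate characters along them
under a symmetric Mk process whose instantaneous rate is modulated
bin-by-bin (piecewise constant along a branch as it crosses bin boundaries),
injects missing data, and fabricates posterior-like tree samples by
jittering node ages.  Every realized change is recorded in a
:class:`TruthLedger`, so downstream rate estimates can be scored against the
truth they are trying to recover.

What this emulates — and what it does not: bin-wise rate multipliers mimic
epoch-scale shifts in evolutionary tempo (an early burst, an isolated late
spike); they do not emulate lineage-specific (relaxed-clock) rate
heterogeneity, correlated characters, or non-random missingness, all of
which real matrices may have.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from .data_io import MISSING, CharacterMatrix, StratRanges, Timescale, TimeTree

__all__ = [
    "SimScenario",
    "TruthLedger",
    "simulate_tree",
    "simulate_characters",
    "inject_missing",
    "make_posterior_like",
    "subsample_tips",
    "ranges_from_tree",
    "palaeozoic_scenario",
    "small_scenario",
]


class SimulationError(RuntimeError):
    pass


@dataclass
class SimScenario:
    """Parameters of one synthetic-clade experiment.

    Rates are per lineage per Myr (birth/death) or per character per Myr
    (``base_rate``); ``bin_multipliers[b]`` scales the instantaneous change
    rate while a lineage traverses bin ``b``.
    """

    timescale: Timescale
    birth: float = 0.06
    death: float = 0.045
    origin_ma: float | None = None          # default: oldest bin boundary
    n_characters: int = 92
    min_states: int = 2
    max_states: int = 5
    base_rate: float = 0.001                # changes/character/Myr
    bin_multipliers: np.ndarray | None = None
    p_miss: float = 0.2
    tip_sampling: float = 1.0               # fossil-recovery filter on tips
    sample_tips: int | None = None          # draw exactly this many tips
    min_tips: int = 4
    max_tips: int | None = None
    seed: int = 0

    def __post_init__(self):
        if self.origin_ma is None:
            self.origin_ma = self.timescale.start_ma
        if self.bin_multipliers is None:
            self.bin_multipliers = np.ones(len(self.timescale))
        self.bin_multipliers = np.asarray(self.bin_multipliers, dtype=float)
        if self.bin_multipliers.size != len(self.timescale):
            raise ValueError("need one rate multiplier per time bin")
        if np.any(self.bin_multipliers < 0) or min(self.birth, self.death, self.base_rate) < 0:
            raise ValueError("rates and multipliers must be >= 0")
        if not 0.0 <= self.p_miss <= 1.0:
            raise ValueError("p_miss must be in [0, 1]")

    # -- provenance --------------------------------------------------------
    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["timescale"] = self.timescale.to_frame().to_dict("records")
        d["bin_multipliers"] = [float(x) for x in self.bin_multipliers]
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimScenario":
        d = yaml.safe_load(Path(path).read_text())
        import pandas as pd

        d["timescale"] = Timescale.from_frame(pd.DataFrame(d["timescale"]))
        d["bin_multipliers"] = np.asarray(d["bin_multipliers"], dtype=float)
        return cls(**d)


def palaeozoic_scenario(seed: int = 0, spike_bin: int = 9, spike: float = 2.5) -> SimScenario:
    """Preset emulating a ~200 Myr Palaeozoic clade: origin 453 Ma, 13 bins,
    92 characters (2-5 states), 20% missing cells, and one late bin whose
    change rate is multiplied by ``spike`` (an isolated late rate spike).

    All values are simulator choices.  Turnover (birth 0.10, death 0.09
    /lineage/Myr) gives species durations around 11 Myr; the surviving
    complete clade carries several hundred fossil species, of which exactly
    82 are sampled uniformly — taxon sampling in real matrices is a sparse
    representative draw from a much larger clade.  The base change rate
    gives roughly 1-2 realized changes per character over the sampled tree.
    """
    ts = Timescale.equal_bins(453.0, 254.0, 13)
    m = np.ones(13)
    m[spike_bin] = spike
    return SimScenario(
        timescale=ts, birth=0.10, death=0.09, n_characters=92,
        base_rate=0.001, bin_multipliers=m, p_miss=0.2,
        sample_tips=82, min_tips=82, seed=seed,
    )


def small_scenario(
    seed: int = 0,
    n_characters: int = 40,
    multipliers: np.ndarray | None = None,
) -> SimScenario:
    """Scaled-down preset (30 sampled tips, 40 characters by default) for
    fast experiments.  The base rate is higher than the full preset's so
    per-bin change counts stay informative on the much shorter sampled
    tree; with ~17-25 Myr branch durations the Mk process is still far from
    saturation."""
    ts = Timescale.equal_bins(453.0, 254.0, 13)
    return SimScenario(
        timescale=ts, birth=0.10, death=0.09, n_characters=n_characters,
        base_rate=0.003, bin_multipliers=multipliers, p_miss=0.2,
        sample_tips=30, min_tips=30, seed=seed,
    )


# ---------------------------------------------------------------------------
# Birth-death tree with fossil tips
# ---------------------------------------------------------------------------


def _one_bd_tree(s: SimScenario, rng: np.random.Generator) -> TimeTree | None:
    """One birth-death realization from the origin; extinct lineages become
    fossil tips at their extinction age, survivors become tips at the young
    end of the timescale.  Returns None if the stem dies before splitting or
    the tip count falls outside [min_tips, max_tips]."""
    end = s.timescale.end_ma
    parent: list[int] = []
    age: list[float] = []
    labels: list[str | None] = []

    def new_node(p: int, a: float) -> int:
        parent.append(p)
        age.append(a)
        labels.append(None)
        return len(parent) - 1

    # stem lineage from the origin; the returned tree is rooted at the first
    # split, so a stem that dies childless aborts the replicate
    stack: list[tuple[int, float]] = []  # (node index of lineage start, start age)
    root = None
    # walk the stem until it splits or dies
    t = float(s.origin_ma)
    while True:
        wait = rng.exponential(1.0 / s.birth) if s.birth > 0 else np.inf
        dwait = rng.exponential(1.0 / s.death) if s.death > 0 else np.inf
        ev = t - min(wait, dwait)
        if ev <= end:
            return None  # stem survived unsplit: a 1-tip "clade"
        if dwait < wait:
            return None  # stem extinct before any split
        root = new_node(-1, ev)
        stack.append((root, ev))
        break

    # each stack entry spawns two daughter lineages
    while stack:
        if s.max_tips is not None and len(parent) > 4 * s.max_tips:
            return None  # runaway clade; reject early
        node, t0 = stack.pop()
        for _ in range(2):
            t = t0
            wait = rng.exponential(1.0 / s.birth) if s.birth > 0 else np.inf
            dwait = rng.exponential(1.0 / s.death) if s.death > 0 else np.inf
            ev = t - min(wait, dwait)
            if ev <= end:
                new_node(node, end)          # survivor tip at the young edge
            elif dwait < wait:
                new_node(node, ev)           # fossil tip at extinction age
            else:
                split = new_node(node, ev)
                stack.append((split, ev))

    parent_arr = np.array(parent)
    n_children = np.zeros(len(parent), dtype=int)
    for p in parent_arr:
        if p >= 0:
            n_children[p] += 1
    tips = np.flatnonzero(n_children == 0)
    if tips.size < s.min_tips or (s.max_tips is not None and tips.size > s.max_tips):
        return None
    # condition on the clade spanning the whole timescale (>= 1 lineage
    # alive at the young boundary), as required for downstream binning
    if not np.any(np.asarray(age)[tips] <= end + 1e-9):
        return None
    for j, i in enumerate(tips, start=1):
        labels[int(i)] = f"t{j}"
    return TimeTree(parent_arr, np.array(age), labels)


def simulate_tree(s: SimScenario, max_retries: int = 2000) -> TimeTree:
    """Constant-rate birth-death tree spanning the scenario's timescale.

    Reproducible under the scenario seed; raises :class:`SimulationError`
    with the retry count if no acceptable clade (>= ``min_tips`` tips)
    arises within ``max_retries`` attempts.
    """
    if s.birth <= 0:
        raise ValueError("birth rate must be > 0")
    rng = np.random.default_rng(s.seed)
    for attempt in range(max_retries):
        tree = _one_bd_tree(s, rng)
        if tree is not None:
            if s.tip_sampling < 1.0:
                keep = [
                    l for l in tree.tip_labels if rng.random() < s.tip_sampling
                ]
                if len(keep) < s.min_tips:
                    continue
                tree = subsample_tips(tree, keep)
            if s.sample_tips is not None:
                if tree.n_tips < s.sample_tips:
                    continue
                keep = list(
                    np.array(tree.tip_labels)[
                        rng.choice(tree.n_tips, size=s.sample_tips, replace=False)
                    ]
                )
                tree = subsample_tips(tree, keep)
            return tree
    raise SimulationError(
        f"no clade with >= {s.min_tips} tips after {max_retries} attempts "
        f"(birth={s.birth}, death={s.death})"
    )


def subsample_tips(tree: TimeTree, keep: list[str]) -> TimeTree:
    """Restrict to a tip subset, suppressing the resulting unifurcations.

    Models incomplete fossil recovery as a filter on the complete tree.
    """
    keep_set = set(keep)
    n = tree.n_nodes
    retained = np.zeros(n, dtype=bool)
    for i in tree.tip_indices:
        if tree.labels[int(i)] in keep_set:
            j = int(i)
            while j >= 0 and not retained[j]:
                retained[j] = True
                j = int(tree.parent[j])
    if not retained.any():
        raise ValueError("tip subset is empty")

    def retained_children(i: int) -> list[int]:
        return [c for c in tree.children[i] if retained[c]]

    def splice_down(j: int) -> int:
        # skip retained unifurcation chains to the next branching node or tip
        while not tree.is_tip[j] and len(retained_children(j)) == 1:
            j = retained_children(j)[0]
        return j

    root = splice_down(int(np.flatnonzero(tree.parent < 0)[0]))
    new_parent: list[int] = []
    new_age: list[float] = []
    new_labels: list[str | None] = []
    stack = [(root, -1)]
    while stack:
        i, new_p = stack.pop()
        idx = len(new_parent)
        new_parent.append(new_p)
        new_age.append(float(tree.age[i]))
        new_labels.append(tree.labels[i] if tree.is_tip[i] else None)
        for c in retained_children(i):
            stack.append((splice_down(c), idx))
    return TimeTree(np.array(new_parent), np.array(new_age), new_labels)


# ---------------------------------------------------------------------------
# Character evolution with per-bin rate multipliers
# ---------------------------------------------------------------------------


@dataclass
class TruthLedger:
    """Realized (true) evolution bookkeeping for one simulated matrix.

    ``branch_changes[i, k]`` is the number of state changes of character ``k``
    on the branch subtending node ``i``; bin totals come from the same event
    draws, so the conservation identity
    ``branch_changes.sum() == bin_changes.sum()`` holds exactly.
    ``bin_opportunity`` is the summed branch duration per bin (scored
    fraction 1: recorded before any missing-data injection), so the true
    per-character rate in bin ``b`` is
    ``bin_changes[b] / (n_characters * bin_opportunity[b])``.
    """

    bin_names: list[str]
    branch_changes: np.ndarray
    bin_changes: np.ndarray
    bin_opportunity: np.ndarray
    n_characters: int

    def true_rates(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            return self.bin_changes / (self.n_characters * self.bin_opportunity)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "bin": self.bin_names,
                "true_changes": self.bin_changes,
                "true_opportunity_myr": self.bin_opportunity,
                "true_rate_per_char_per_myr": self.true_rates(),
            }
        )


def _branch_bin_overlaps(tree: TimeTree, ts: Timescale) -> np.ndarray:
    """(n_nodes, n_bins) matrix of branch-bin overlap durations (root row 0)."""
    starts, ends = ts.starts(), ts.ends()
    young = tree.age
    old = np.where(tree.parent >= 0, tree.age[np.clip(tree.parent, 0, None)], tree.age)
    ov = np.clip(
        np.minimum(old[:, None], starts[None, :]) - np.maximum(young[:, None], ends[None, :]),
        0.0,
        None,
    )
    ov[tree.parent < 0, :] = 0.0
    return ov


def simulate_characters(
    tree: TimeTree, s: SimScenario, rng: np.random.Generator | None = None
) -> tuple[CharacterMatrix, TruthLedger]:
    """Evolve unordered multistate characters along the tree.

    Each character has ``k`` states drawn uniformly from
    ``[min_states, max_states]`` and follows a symmetric Mk process: while a
    lineage traverses bin ``b`` the total change rate is
    ``base_rate * bin_multipliers[b]`` and each change moves to one of the
    other ``k - 1`` states uniformly.  The root state is uniform over states.
    """
    if rng is None:
        rng = np.random.default_rng(s.seed + 1)
    nc = s.n_characters
    k = rng.integers(s.min_states, s.max_states + 1, size=nc)
    if not s.timescale.covers(tree.root_age, tree.youngest_tip_age):
        raise ValueError("tree span exceeds the scenario timescale")
    ov = _branch_bin_overlaps(tree, s.timescale)
    lam = s.base_rate * s.bin_multipliers  # per-character rate per bin

    n = tree.n_nodes
    states = np.zeros((n, nc), dtype=np.int64)
    branch_changes = np.zeros((n, nc), dtype=np.int64)
    bin_changes = np.zeros(len(s.timescale), dtype=np.int64)

    states[tree.root] = rng.integers(0, k)
    for i in tree.preorder:
        i = int(i)
        if i == tree.root:
            continue
        st = states[tree.parent[i]].copy()
        n_events = np.zeros(nc, dtype=np.int64)
        for b in np.flatnonzero(ov[i] > 0):
            ev_b = rng.poisson(lam[b] * ov[i, b], size=nc)
            n_events += ev_b
            bin_changes[b] += int(ev_b.sum())
        branch_changes[i] = n_events
        for j in range(int(n_events.max()) if n_events.size else 0):
            live = n_events > j
            if not live.any():
                break
            u = rng.integers(0, k[live] - 1)
            st[live] = u + (u >= st[live])
        states[i] = st

    codes = states[tree.tip_indices]
    matrix = CharacterMatrix(
        taxon_labels=list(tree.tip_labels),
        state_symbols=[[str(x) for x in range(int(kk))] for kk in k],
        codes=codes,
    )
    ledger = TruthLedger(
        bin_names=s.timescale.names,
        branch_changes=branch_changes,
        bin_changes=bin_changes,
        bin_opportunity=ov.sum(axis=0),
        n_characters=nc,
    )
    return matrix, ledger


def inject_missing(m: CharacterMatrix, p_miss: float, seed: int | None = None) -> CharacterMatrix:
    """Set each cell to MISSING independently with probability ``p_miss``."""
    if not 0.0 <= p_miss <= 1.0:
        raise ValueError("p_miss must be in [0, 1]")
    rng = np.random.default_rng(seed)
    codes = m.codes.copy()
    codes[rng.random(codes.shape) < p_miss] = MISSING
    return CharacterMatrix(
        taxon_labels=list(m.taxon_labels),
        state_symbols=[list(s) for s in m.state_symbols],
        codes=codes,
        ordering_flags=list(m.ordering_flags),
    )


# ---------------------------------------------------------------------------
# Posterior-like tree samples
# ---------------------------------------------------------------------------


def make_posterior_like(
    tree: TimeTree, n_trees: int, age_jitter_sd: float, seed: int | None = None
) -> list[TimeTree]:
    """Fabricate a posterior-like sample: copies of ``tree`` with internal
    node ages independently jittered by a truncated normal (sd in Myr),
    topology and tip ages fixed.

    Truncation keeps ages monotone — each node stays below its (already
    jittered) parent and above the oldest tip of its own clade — and is
    applied as a *symmetric* window around the original age, so each node's
    jitter has mean zero conditional on its parent (no systematic push of
    node ages toward the past or present).
    """
    if n_trees < 1:
        raise ValueError("n_trees must be >= 1")
    rng = np.random.default_rng(seed)
    # oldest descendant tip per node = hard lower bound on its age
    lb = np.where(tree.is_tip, tree.age, -np.inf)
    for i in tree.postorder:
        i = int(i)
        for c in tree.children[i]:
            lb[i] = max(lb[i], lb[c])
    out = []
    for _ in range(n_trees):
        age = tree.age.copy()
        if age_jitter_sd > 0:
            for i in tree.preorder:
                i = int(i)
                if tree.is_tip[i]:
                    continue
                hi = np.inf if i == tree.root else age[tree.parent[i]]
                lo = lb[i]
                orig = float(tree.age[i])
                half = min(orig - lo, hi - orig)
                if half <= 0:
                    age[i] = float(np.clip(orig, lo, hi))
                    continue
                for _try in range(200):  # rejection within the symmetric window
                    delta = rng.normal(0.0, age_jitter_sd)
                    if abs(delta) <= half:
                        age[i] = orig + delta
                        break
                else:
                    age[i] = orig
        out.append(TimeTree(tree.parent.copy(), age, list(tree.labels)))
    return out


# ---------------------------------------------------------------------------
# Stratigraphic ranges implied by a simulated tree
# ---------------------------------------------------------------------------


def ranges_from_tree(tree: TimeTree, ts: Timescale, mode: str = "branch") -> StratRanges:
    """Derive first/last-appearance bins for each tip.

    ``mode='branch'`` treats a tip lineage as observable over its subtending
    branch (first appearance at the parent node's age, last at the tip age);
    ``mode='point'`` records the tip age only.  Both are simulator
    conventions standing in for real occurrence data.
    """
    first, last = {}, {}
    for i in tree.tip_indices:
        i = int(i)
        tip_age = min(max(tree.age[i], ts.end_ma), ts.start_ma)
        if mode == "point":
            b = ts.bin_of_age(tip_age)
            first[tree.labels[i]] = b
            last[tree.labels[i]] = b
        elif mode == "branch":
            old = min(tree.age[tree.parent[i]], ts.start_ma) if tree.parent[i] >= 0 else tip_age
            old = max(old, tip_age)
            first[tree.labels[i]] = ts.bin_of_age(old)
            last[tree.labels[i]] = ts.bin_of_age(tip_age)
        else:
            raise ValueError(f"unknown mode {mode!r}")
    return StratRanges(first, last)
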