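"""Core containers and file I/O for the pipeline.

Conventions used throughout the package (stated once, here):

* All ages and node heights are in **Ma before present** — larger numbers are
  older.  Branch durations are ``age(parent) - age(child) >= 0`` in Myr.
* Time bins run **old → young** and are contiguous: bin ``i`` covers
  ``(end_ma, start_ma]`` with ``start_ma > end_ma``; the youngest bin also
  contains its own young boundary, so every age in the covered span maps to
  exactly one bin.
* Character states are compared as **tokens**, never as integers; all
  characters are unordered, so only equality of tokens matters.
* ``'?'`` (missing), ``'-'`` (inapplicable) and polymorphic codings such as
  ``{01}`` all reduce to MISSING (coded ``-1``); polymorphism reductions are
  counted so the loss is visible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

MISSING = -1

__all__ = [
    "MISSING",
    "CharacterMatrix",
    "TimeTree",
    "TimeBin",
    "Timescale",
    "StratRanges",
    "read_nexus_matrix",
    "write_nexus_matrix",
    "read_trees",
    "write_trees",
    "missing_data_summary",
    "builtin_timescale",
]


class MatrixValidationError(ValueError):
    """Raised when a character matrix violates its invariants."""


# ---------------------------------------------------------------------------
# CharacterMatrix
# ---------------------------------------------------------------------------


@dataclass
class CharacterMatrix:
    """Taxa x unordered multistate characters, with missing cells.

    ``codes[i, k]`` is an index into ``state_symbols[k]`` or ``MISSING``.
    ``state_symbols[k]`` is the ordered list of state tokens observed for
    character ``k`` (sorted lexicographically, so symbol order is stable but
    carries no meaning — characters are unordered).
    """

    taxon_labels: list[str]
    state_symbols: list[list[str]]
    codes: np.ndarray
    ordering_flags: list[str] = field(default_factory=list)
    n_polymorphic_reduced: int = 0

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int64)
        if not self.ordering_flags:
            self.ordering_flags = ["unordered"] * self.n_characters
        self.validate()

    # -- basic shape -------------------------------------------------------
    @property
    def n_taxa(self) -> int:
        return len(self.taxon_labels)

    @property
    def n_characters(self) -> int:
        return self.codes.shape[1]

    def validate(self) -> None:
        if len(set(self.taxon_labels)) != len(self.taxon_labels):
            dupes = sorted({t for t in self.taxon_labels if self.taxon_labels.count(t) > 1})
            raise MatrixValidationError(f"duplicate taxon labels: {dupes}")
        if self.codes.shape != (len(self.taxon_labels), len(self.state_symbols)):
            raise MatrixValidationError(
                f"codes shape {self.codes.shape} does not match "
                f"{len(self.taxon_labels)} taxa x {len(self.state_symbols)} characters"
            )
        for k, syms in enumerate(self.state_symbols):
            col = self.codes[:, k]
            scored = col[col != MISSING]
            if scored.size and (scored.min() < 0 or scored.max() >= len(syms)):
                raise MatrixValidationError(f"character {k}: state code outside symbol list")

    # -- character classification -----------------------------------------
    def n_observed_states(self) -> np.ndarray:
        """Number of distinct states actually scored, per character."""
        out = np.zeros(self.n_characters, dtype=int)
        for k in range(self.n_characters):
            col = self.codes[:, k]
            out[k] = np.unique(col[col != MISSING]).size
        return out

    def informative_mask(self) -> np.ndarray:
        """True for characters with >= 2 observed states among scored cells.

        Characters failing this are *invariant* and are excluded from rate
        and disparity computations.
        """
        return self.n_observed_states() >= 2

    def row(self, taxon: str) -> np.ndarray:
        return self.codes[self.taxon_labels.index(taxon)]

    def subset_taxa(self, taxa: Sequence[str]) -> "CharacterMatrix":
        idx = [self.taxon_labels.index(t) for t in taxa]
        return CharacterMatrix(
            taxon_labels=list(taxa),
            state_symbols=[list(s) for s in self.state_symbols],
            codes=self.codes[idx].copy(),
            ordering_flags=list(self.ordering_flags),
        )

    def tokens(self) -> pd.DataFrame:
        """The matrix as state tokens ('?' for MISSING), taxa as index."""
        data = {}
        for k in range(self.n_characters):
            syms = self.state_symbols[k]
            data[k] = ["?" if c == MISSING else syms[c] for c in self.codes[:, k]]
        return pd.DataFrame(data, index=self.taxon_labels)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CharacterMatrix):
            return NotImplemented
        if self.taxon_labels != other.taxon_labels:
            return False
        return self.tokens().equals(other.tokens())


def missing_data_summary(m: CharacterMatrix) -> dict:
    """Missing-cell fractions per taxon, per character, and overall.

    For a complete rectangular matrix the overall fraction equals the mean of
    the per-taxon fractions and the mean of the per-character fractions.
    """
    miss = m.codes == MISSING
    per_taxon = pd.Series(miss.mean(axis=1), index=m.taxon_labels)
    per_character = pd.Series(miss.mean(axis=0))
    return {
        "per_taxon": per_taxon,
        "per_character": per_character,
        "overall": float(miss.mean()),
    }


# ---------------------------------------------------------------------------
# NEXUS matrix I/O (parsing via dendropy; writing is a small exact writer)
# ---------------------------------------------------------------------------


def _matrix_from_dendropy(dm: dendropy.StandardCharacterMatrix) -> CharacterMatrix:
    taxa = [t.label for t in dm.taxon_namespace]
    rows: list[list[str | None]] = []
    n_poly = 0
    nchar = max(len(dm[t]) for t in dm.taxon_namespace)
    for t in dm.taxon_namespace:
        row: list[str | None] = []
        for cell in dm[t]:
            # fundamental states carry denomination 0 and a symbol; anything
            # ambiguous/polymorphic (incl. '?') has denomination != 0
            if cell.state_denomination == 0 and cell.symbol not in (None, "-", "?"):
                row.append(cell.symbol)
            else:
                if cell.member_states is not None and cell.symbol is None:
                    # explicit {..} codings have no symbol of their own,
                    # unlike '?'/'-' which carry one
                    members = [s.symbol for s in cell.member_states if s.symbol not in (None, "-")]
                    if len(members) > 1:
                        n_poly += 1
                row.append(None)
        if len(row) != nchar:
            raise MatrixValidationError(f"taxon {t.label!r}: row length {len(row)} != {nchar}")
        rows.append(row)

    state_symbols: list[list[str]] = []
    codes = np.full((len(taxa), nchar), MISSING, dtype=np.int64)
    for k in range(nchar):
        observed = sorted({r[k] for r in rows if r[k] is not None})
        state_symbols.append(observed)
        lut = {s: i for i, s in enumerate(observed)}
        for i, r in enumerate(rows):
            if r[k] is not None:
                codes[i, k] = lut[r[k]]
    return CharacterMatrix(
        taxon_labels=taxa,
        state_symbols=state_symbols,
        codes=codes,
        n_polymorphic_reduced=n_poly,
    )


def read_nexus_matrix(path: str | Path) -> CharacterMatrix:
    """Read a NEXUS DATA/CHARACTERS block into a :class:`CharacterMatrix`.

    ``'?'`` and ``'-'`` both map to MISSING; polymorphic codings like
    ``{01}`` are reduced to MISSING and counted in
    ``n_polymorphic_reduced``.
    """
    try:
        dm = dendropy.StandardCharacterMatrix.get(path=str(path), schema="nexus")
    except Exception as exc:  # dendropy raises several error types
        raise MatrixValidationError(f"failed to parse NEXUS matrix {path}: {exc}") from exc
    return _matrix_from_dendropy(dm)


def write_nexus_matrix(m: CharacterMatrix, path: str | Path) -> None:
    """Write a NEXUS CHARACTERS block readable by :func:`read_nexus_matrix`."""
    all_syms = sorted({s for syms in m.state_symbols for s in syms})
    toks = m.tokens()
    width = max(len(t) for t in m.taxon_labels) + 2
    lines = [
        "#NEXUS",
        "BEGIN DATA;",
        f"DIMENSIONS NTAX={m.n_taxa} NCHAR={m.n_characters};",
        f'FORMAT DATATYPE=STANDARD SYMBOLS="{"".join(all_syms)}" MISSING=? GAP=-;',
        "MATRIX",
    ]
    for taxon in m.taxon_labels:
        lines.append(f"{taxon:<{width}}" + "".join(toks.loc[taxon]))
    lines += [";", "END;", ""]
    Path(path).write_text("\n".join(lines))


# ---------------------------------------------------------------------------
# TimeTree
# ---------------------------------------------------------------------------


class TreeError(ValueError):
    pass


class TimeTree:
    """Rooted tree with node ages in Ma before present.

    Stored as flat arrays (parent pointers, ages, postorder) for fast
    vectorized traversal; conversion to/from dendropy handles file formats.
    Zero-length branches are allowed (sampled-ancestor encoding).
    """

    def __init__(self, parent: np.ndarray, age: np.ndarray, labels: Sequence[str | None]):
        self.parent = np.asarray(parent, dtype=np.int64)
        self.age = np.asarray(age, dtype=float)
        self.labels = list(labels)
        n = self.parent.size
        if not (self.age.size == n and len(self.labels) == n):
            raise TreeError("parent/age/labels length mismatch")
        roots = np.flatnonzero(self.parent < 0)
        if roots.size != 1:
            raise TreeError(f"expected exactly one root, found {roots.size}")
        self.root = int(roots[0])
        self.children: list[list[int]] = [[] for _ in range(n)]
        for i in range(n):
            if i != self.root:
                self.children[self.parent[i]].append(i)
        self.is_tip = np.array([len(c) == 0 for c in self.children])
        # durations: parent age - own age (root: 0)
        dur = np.zeros(n)
        nz = np.arange(n) != self.root
        dur[nz] = self.age[self.parent[nz]] - self.age[nz]
        if np.any(dur < -1e-9):
            bad = int(np.argmin(dur))
            raise TreeError(
                f"negative branch duration at node {bad}: "
                f"child age {self.age[bad]} > parent age {self.age[self.parent[bad]]}"
            )
        self.duration = np.clip(dur, 0.0, None)
        self.postorder = self._postorder()
        self.preorder = self.postorder[::-1]
        tips = np.flatnonzero(self.is_tip)
        lbls = [self.labels[i] for i in tips]
        if any(l is None for l in lbls):
            raise TreeError("unlabelled tip")
        if len(set(lbls)) != len(lbls):
            raise TreeError("duplicate tip labels")
        self.tip_indices = tips
        self.tip_labels = lbls

    def _postorder(self) -> np.ndarray:
        order, stack = [], [(self.root, False)]
        while stack:
            node, done = stack.pop()
            if done:
                order.append(node)
            else:
                stack.append((node, True))
                for c in self.children[node]:
                    stack.append((c, False))
        return np.array(order, dtype=np.int64)

    @property
    def n_nodes(self) -> int:
        return self.parent.size

    @property
    def n_tips(self) -> int:
        return len(self.tip_labels)

    @property
    def root_age(self) -> float:
        return float(self.age[self.root])

    @property
    def youngest_tip_age(self) -> float:
        return float(self.age[self.tip_indices].min())

    def total_branch_length(self) -> float:
        return float(self.duration.sum())

    # -- conversion --------------------------------------------------------
    @classmethod
    def from_dendropy(
        cls,
        tree: dendropy.Tree,
        youngest_tip_age: float | None = 0.0,
        tip_ages: Mapping[str, float] | None = None,
        root_age: float | None = None,
    ) -> "TimeTree":
        """Build from a dendropy tree with branch lengths in Myr.

        Node ages are reconstructed from branch lengths anchored by (in order
        of precedence) an explicit ``root_age``, a ``tip_ages`` table (taxon
        label -> Ma), or ``youngest_tip_age`` (default 0 = the present).
        """
        nodes = list(tree.preorder_node_iter())
        index = {id(nd): i for i, nd in enumerate(nodes)}
        n = len(nodes)
        parent = np.full(n, -1, dtype=np.int64)
        depth = np.zeros(n)
        labels: list[str | None] = [None] * n
        for i, nd in enumerate(nodes):
            if nd.parent_node is not None:
                if nd.edge.length is None:
                    raise TreeError("tree has a branch without a length")
                parent[i] = index[id(nd.parent_node)]
                depth[i] = depth[parent[i]] + float(nd.edge.length)
            if nd.is_leaf():
                if nd.taxon is None or nd.taxon.label is None:
                    raise TreeError("unlabelled tip in input tree")
                labels[i] = nd.taxon.label
        if root_age is not None:
            offset = root_age
        elif tip_ages is not None:
            anchors = [
                tip_ages[labels[i]] + depth[i] for i in range(n) if labels[i] in tip_ages
            ]
            if not anchors:
                raise TreeError(
                    "no tip in the tree appears in the tip-age table; "
                    "provide tip_ages covering >= 1 tip or an explicit root_age"
                )
            offset = float(np.mean(anchors))
        elif youngest_tip_age is not None:
            tip_depth = max(depth[i] for i in range(n) if labels[i] is not None)
            offset = tip_depth + youngest_tip_age
        else:
            raise TreeError("an age anchor (root_age, tip_ages or youngest_tip_age) is required")
        return cls(parent, offset - depth, labels)

    def to_dendropy(self, taxon_namespace: dendropy.TaxonNamespace | None = None) -> dendropy.Tree:
        ns = taxon_namespace or dendropy.TaxonNamespace()
        tree = dendropy.Tree(taxon_namespace=ns)
        dnodes = {self.root: tree.seed_node}
        for i in self.preorder:
            i = int(i)
            if i != self.root:
                nd = dnodes[self.parent[i]].new_child()
                nd.edge.length = float(self.duration[i])
                dnodes[i] = nd
        for i, lbl in enumerate(self.labels):
            if lbl is not None and i in dnodes and len(self.children[i]) == 0:
                dnodes[i].taxon = ns.require_taxon(label=lbl)
        return tree

    def to_newick(self) -> str:
        return self.to_dendropy().as_string(schema="newick", suppress_rooting=True).strip()

    @classmethod
    def from_newick(cls, s: str, **anchor) -> "TimeTree":
        t = dendropy.Tree.get(data=s, schema="newick")
        return cls.from_dendropy(t, **anchor)

    def copy(self) -> "TimeTree":
        return TimeTree(self.parent.copy(), self.age.copy(), list(self.labels))


def read_trees(
    path: str | Path,
    n_sample: int | None = None,
    seed: int | None = None,
    youngest_tip_age: float | None = 0.0,
    tip_ages: Mapping[str, float] | None = None,
    root_age: float | None = None,
) -> list[TimeTree]:
    """Read time trees (NEXUS or Newick) and draw a uniform subsample.

    ``n_sample`` trees are drawn uniformly *without* replacement (all trees if
    the file holds fewer).  Node ages are reconstructed from branch lengths;
    see :meth:`TimeTree.from_dendropy` for the anchoring rules.
    """
    text = Path(path).read_text()
    schema = "nexus" if text.lstrip().lower().startswith("#nexus") else "newick"
    tl = dendropy.TreeList.get(data=text, schema=schema)
    if len(tl) == 0:
        raise TreeError(f"no trees found in {path}")
    idx = np.arange(len(tl))
    if n_sample is not None and n_sample < len(tl):
        rng = np.random.default_rng(seed)
        idx = np.sort(rng.choice(len(tl), size=n_sample, replace=False))
    return [
        TimeTree.from_dendropy(
            tl[int(i)], youngest_tip_age=youngest_tip_age, tip_ages=tip_ages, root_age=root_age
        )
        for i in idx
    ]


def write_trees(trees: Iterable[TimeTree], path: str | Path) -> None:
    ns = dendropy.TaxonNamespace()
    tl = dendropy.TreeList(taxon_namespace=ns)
    for t in trees:
        tl.append(t.to_dendropy(taxon_namespace=ns))
    tl.write(path=str(path), schema="nexus")


# ---------------------------------------------------------------------------
# Timescale
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TimeBin:
    name: str
    start_ma: float  # older boundary
    end_ma: float    # younger boundary

    def __post_init__(self):
        if not self.start_ma > self.end_ma:
            raise ValueError(f"bin {self.name!r}: start_ma must exceed end_ma")

    @property
    def duration(self) -> float:
        return self.start_ma - self.end_ma

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.start_ma + self.end_ma)


class Timescale:
    """Ordered, contiguous, non-overlapping time bins (old -> young)."""

    def __init__(self, bins: Sequence[TimeBin]):
        if not bins:
            raise ValueError("timescale needs >= 1 bin")
        for a, b in zip(bins, bins[1:]):
            if abs(a.end_ma - b.start_ma) > 1e-9:
                raise ValueError(
                    f"bins not contiguous: {a.name!r} ends {a.end_ma}, "
                    f"{b.name!r} starts {b.start_ma}"
                )
        self.bins = list(bins)

    def __len__(self) -> int:
        return len(self.bins)

    def __iter__(self):
        return iter(self.bins)

    def __getitem__(self, i) -> TimeBin:
        return self.bins[i]

    @property
    def names(self) -> list[str]:
        return [b.name for b in self.bins]

    @property
    def start_ma(self) -> float:
        return self.bins[0].start_ma

    @property
    def end_ma(self) -> float:
        return self.bins[-1].end_ma

    def starts(self) -> np.ndarray:
        return np.array([b.start_ma for b in self.bins], dtype=float)

    def ends(self) -> np.ndarray:
        return np.array([b.end_ma for b in self.bins], dtype=float)

    def midpoints(self) -> np.ndarray:
        return np.array([b.midpoint for b in self.bins])

    def durations(self) -> np.ndarray:
        return np.array([b.duration for b in self.bins])

    def index_of(self, name: str) -> int:
        return self.names.index(name)

    def bin_of_age(self, age_ma: float) -> int:
        """Index of the bin containing ``age_ma`` ((end, start]; youngest bin
        closed on both sides)."""
        if age_ma > self.start_ma or age_ma < self.end_ma:
            raise ValueError(
                f"age {age_ma} Ma outside timescale span "
                f"[{self.end_ma}, {self.start_ma}]"
            )
        for i, b in enumerate(self.bins):
            if age_ma >= b.end_ma:
                return i
        return len(self.bins) - 1

    def covers(self, older: float, younger: float) -> bool:
        return self.start_ma >= older - 1e-9 and self.end_ma <= younger + 1e-9

    # -- serialization -----------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"name": self.names, "start_ma": self.starts(), "end_ma": self.ends()}
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_frame().to_dict("records"), indent=1))

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "Timescale":
        return cls([TimeBin(str(r["name"]), float(r["start_ma"]), float(r["end_ma"]))
                    for _, r in df.iterrows()])

    @classmethod
    def from_file(cls, path: str | Path) -> "Timescale":
        p = Path(path)
        if p.suffix.lower() == ".json":
            return cls.from_frame(pd.DataFrame(json.loads(p.read_text())))
        return cls.from_frame(pd.read_csv(p, sep="\t"))

    @classmethod
    def equal_bins(cls, start_ma: float, end_ma: float, n: int, prefix: str = "bin") -> "Timescale":
        edges = np.linspace(start_ma, end_ma, n + 1)
        return cls([
            TimeBin(f"{prefix}{i + 1:02d}", float(edges[i]), float(edges[i + 1]))
            for i in range(n)
        ])


# Stage-level boundaries (Ma) after the 2016 international chronostratigraphic
# chart, with Silurian binned at series level and the Carboniferous collapsed
# to its two subperiods. Shipped as editable data, not hard-coded truth:
# pass any Timescale to override.
_DEFAULT_BINS = [
    ("Katian", 453.0, 445.2),
    ("Hirnantian", 445.2, 443.8),
    ("Llandovery", 443.8, 433.4),
    ("Wenlock", 433.4, 427.4),
    ("Ludlow", 427.4, 423.0),
    ("Pridoli", 423.0, 419.2),
    ("Lochkovian", 419.2, 410.8),
    ("Pragian", 410.8, 407.6),
    ("Emsian", 407.6, 393.3),
    ("Eifelian", 393.3, 387.7),
    ("Givetian", 387.7, 382.7),
    ("Frasnian", 382.7, 372.2),
    ("Famennian", 372.2, 358.9),
    ("Mississippian", 358.9, 323.2),
    ("Pennsylvanian", 323.2, 298.9),
    ("Asselian", 298.9, 295.0),
    ("Sakmarian", 295.0, 290.1),
    ("Artinskian", 290.1, 283.5),
    ("Kungurian", 283.5, 272.3),
    ("Roadian", 272.3, 268.8),
    ("Wordian", 268.8, 265.1),
    ("Capitanian", 265.1, 259.8),
    ("Wuchiapingian", 259.8, 254.2),
]


def builtin_timescale() -> Timescale:
    """Katian -> Wuchiapingian bin table (stages; Silurian series;
    Carboniferous subperiods)."""
    return Timescale([TimeBin(n, s, e) for n, s, e in _DEFAULT_BINS])


# ---------------------------------------------------------------------------
# Stratigraphic ranges
# ---------------------------------------------------------------------------


@dataclass
class StratRanges:
    """First/last appearance bin indices per taxon (old -> young ordering)."""

    first: dict[str, int]
    last: dict[str, int]

    def __post_init__(self):
        if set(self.first) != set(self.last):
            raise ValueError("first/last appearance taxon sets differ")
        for t in self.first:
            if self.first[t] > self.last[t]:
                raise ValueError(f"taxon {t!r}: first appearance after last")
            if self.first[t] < 0:
                raise ValueError(f"taxon {t!r}: negative bin index")

    @property
    def taxa(self) -> list[str]:
        return sorted(self.first)

    def __len__(self) -> int:
        return len(self.first)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, ts: Timescale | None = None) -> "StratRanges":
        """Build from a table with columns taxon, first_bin, last_bin.

        Bins may be integer indices or bin names (requires ``ts``).
        """
        first, last = {}, {}
        for _, r in df.iterrows():
            f, l = r["first_bin"], r["last_bin"]
            if ts is not None and (isinstance(f, str) or isinstance(l, str)):
                f = ts.index_of(str(f)) if isinstance(f, str) else int(f)
                l = ts.index_of(str(l)) if isinstance(l, str) else int(l)
            first[str(r["taxon"])] = int(f)
            last[str(r["taxon"])] = int(l)
        return cls(first, last)

    @classmethod
    def from_tsv(cls, path: str | Path, ts: Timescale | None = None) -> "StratRanges":
        return cls.from_frame(pd.read_csv(path, sep="\t"), ts)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "taxon": self.taxa,
                "first_bin": [self.first[t] for t in self.taxa],
                "last_bin": [self.last[t] for t in self.taxa],
            }
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)
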