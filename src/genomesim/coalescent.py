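"""Structured coalescent with recombination, demographics and serial sampling.

Genealogies are simulated backward in time under the (multispecies) coalescent:
within a deme holding ``k`` active lineages of effective size ``N(t)``, each
pair coalesces at rate ``1/(2N(t))`` per generation (ms-compatible diploid
convention, so the population recombination rate is ``rho = 4 N r (L-1)``);
lineages migrate between demes at backward per-generation rates ``m[i][j]``;
population-split events move all lineages of the child demes into the parent
deme, yielding the multispecies coalescent; samples taken at different times
enter the process at their sampling times (longitudinal sampling).  Epochs may
rescale deme sizes and exponential growth rates; within an epoch the size
follows ``N(t) = N_epoch * exp(-g * (t - epoch_start))`` backward in time, and
coalescence waiting times under growth are drawn exactly by inverting the
cumulative hazard.

With recombination the full Hudson ancestral recombination graph is simulated:
each lineage carries its ancestral material as a list of genome segments and
recombines at a rate equal to the recombination-map mass spanned by that
material (trapped non-ancestral material included, matching ms semantics);
breakpoints fall on nucleotide boundaries with probability proportional to the
local map intensity, so hotspots attract breakpoints in proportion to their
rate multiplier.  Marginal trees are extracted per breakpoint interval.
"""

from __future__ import annotations

import math
from bisect import bisect_right
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Demography",
    "Epoch",
    "PopulationStructure",
    "SampleConfig",
    "RecombinationMap",
    "Genealogy",
    "MarginalTreeSet",
    "simulate_genealogy",
    "simulate_arg",
    "tmrca",
    "total_branch_length",
    "load_user_tree",
    "CoalescentError",
]

#: multiple of the largest 2N allowed before declaring the configuration
#: non-coalescing (e.g. disconnected demes with zero migration)
GUARD_HORIZON_FACTOR = 1e4


class CoalescentError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# configuration types


@dataclass(frozen=True)
class Epoch:
    """Piece of piecewise demography on ``[start, end)`` generations ago."""

    start: float
    end: float
    sizes: dict  # deme -> N at epoch start
    growth: dict = field(default_factory=dict)  # deme -> g per generation

    def size(self, deme: str, t: float) -> float:
        n0 = self.sizes[deme]
        g = self.growth.get(deme, 0.0)
        if g == 0.0:
            return n0
        return n0 * math.exp(-g * (t - self.start))


@dataclass(frozen=True)
class Demography:
    epochs: tuple[Epoch, ...]

    def __post_init__(self) -> None:
        eps = self.epochs
        if not eps:
            raise ValueError("demography requires at least one epoch")
        if eps[0].start != 0.0 or not math.isinf(eps[-1].end):
            raise ValueError("epochs must tile [0, inf)")
        for a, b in zip(eps, eps[1:]):
            if a.end != b.start:
                raise ValueError("epochs must be contiguous and non-overlapping")
        for e in eps:
            if any(n <= 0 for n in e.sizes.values()):
                raise ValueError("effective sizes must be positive")

    @classmethod
    def constant(cls, N: float, demes: Iterable[str] = ("pop",)) -> "Demography":
        sizes = {d: float(N) for d in demes}
        return cls((Epoch(0.0, math.inf, sizes),))

    def epoch_at(self, t: float) -> Epoch:
        for e in self.epochs:
            if e.start <= t < e.end:
                return e
        return self.epochs[-1]

    def max_2N(self) -> float:
        return max(2 * n for e in self.epochs for n in e.sizes.values())


@dataclass(frozen=True)
class SplitEvent:
    """At ``time`` (backward), lineages in ``children`` demes move to ``parent``."""

    time: float
    children: tuple[str, ...]
    parent: str


@dataclass(frozen=True)
class PopulationStructure:
    demes: tuple[str, ...] = ("pop",)
    # list of (start_time, matrix) with matrix[i][j] = backward migration rate
    # from deme i to deme j per lineage per generation; epoch-piecewise constant
    migration: tuple[tuple[float, tuple[tuple[float, ...], ...]], ...] = ()
    splits: tuple[SplitEvent, ...] = ()

    def __post_init__(self) -> None:
        k = len(self.demes)
        for start, m in self.migration:
            arr = np.asarray(m, dtype=float)
            if arr.shape != (k, k):
                raise ValueError("migration matrix shape must match deme count")
            if (arr < 0).any() or np.diag(arr).any():
                raise ValueError("migration rates must be >=0 with zero diagonal")
        times = [s.time for s in self.splits]
        if times != sorted(times):
            raise ValueError("split events must be time-ordered")
        # every split must leave the deme set consistent and end in one deme
        alive = set(self.demes)
        for s in self.splits:
            missing = set(s.children) - alive
            if missing:
                raise ValueError(f"split at {s.time} references unknown demes {missing}")
            alive -= set(s.children)
            alive.add(s.parent)
        if len(alive) != 1 and len(self.demes) > 1 and not self._connected():
            raise ValueError(
                "structure must guarantee a single final deme "
                "(add splits or connecting migration)"
            )

    def _connected(self) -> bool:
        if not self.migration:
            return False
        m = np.asarray(self.migration[-1][1])
        adj = (m + m.T) > 0
        n = len(self.demes)
        seen = {0}
        stack = [0]
        while stack:
            i = stack.pop()
            for j in range(n):
                if adj[i, j] and j not in seen:
                    seen.add(j)
                    stack.append(j)
        return len(seen) == n

    @classmethod
    def panmictic(cls, deme: str = "pop") -> "PopulationStructure":
        return cls(demes=(deme,))

    @classmethod
    def island(cls, n_demes: int, rate: float) -> "PopulationStructure":
        """Symmetric island model: each lineage leaves its deme at total rate
        ``rate``, choosing the destination uniformly."""
        demes = tuple(f"deme{i}" for i in range(n_demes))
        per = rate / (n_demes - 1)
        m = tuple(
            tuple(0.0 if i == j else per for j in range(n_demes))
            for i in range(n_demes)
        )
        return cls(demes=demes, migration=((0.0, m),))

    def migration_at(self, t: float) -> np.ndarray | None:
        if not self.migration:
            return None
        idx = bisect_right([s for s, _ in self.migration], t) - 1
        if idx < 0:
            return None
        return np.asarray(self.migration[idx][1], dtype=float)


@dataclass(frozen=True)
class SampleConfig:
    """Sampling design: list of (deme, time generations before present, count)."""

    groups: tuple[tuple[str, float, int], ...]
    labels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if any(t < 0 for _, t, _ in self.groups):
            raise ValueError("sampling times must be >= 0")
        if self.n < 1:
            raise ValueError("at least one sample required")
        if self.labels is not None and len(self.labels) != self.n:
            raise ValueError("label count must equal total sample count")

    @property
    def n(self) -> int:
        return sum(c for _, _, c in self.groups)

    @classmethod
    def contemporaneous(cls, n: int, deme: str = "pop") -> "SampleConfig":
        return cls(groups=((deme, 0.0, n),))

    def sample_list(self) -> list[tuple[str, float, str]]:
        """Expand to per-sample (deme, time, label)."""
        out = []
        i = 0
        for deme, t, count in self.groups:
            for _ in range(count):
                label = self.labels[i] if self.labels else f"s{i}"
                out.append((deme, t, label))
                i += 1
        return out


@dataclass(frozen=True)
class RecombinationMap:
    """Per-site recombination rate with optional hotspot multipliers.

    ``hotspots`` are (start, end, multiplier) with 0-based half-open nucleotide
    coordinates; the local intensity is ``rate * multiplier`` inside a hotspot.
    """

    rate: float
    length: int
    hotspots: tuple[tuple[int, int, float], ...] = ()

    def __post_init__(self) -> None:
        if self.rate < 0:
            raise ValueError("recombination rate must be >= 0")
        for s, e, m in self.hotspots:
            if not (0 <= s < e <= self.length) or m < 0:
                raise ValueError(f"invalid hotspot ({s}, {e}, {m})")

    def link_cumulative(self) -> np.ndarray:
        """C[b] = total rate of breakpoints at positions 1..b (b in 0..L-1)."""
        L = self.length
        w = np.full(L, self.rate)  # weight of breakpoint position b = local rate
        for s, e, m in self.hotspots:
            w[s:e] *= m
        w[0] = 0.0  # breakpoints live at 1..L-1
        return np.cumsum(w)


# ---------------------------------------------------------------------------
# genealogy container


class Genealogy:
    """Rooted tree with node times (generations before the most recent sample)
    or branch lengths in expected substitutions per site (user-tree mode).

    Nodes are indexed 0..n_nodes-1; leaves carry labels; ``parent[root] = -1``.
    """

    def __init__(
        self,
        parent: Sequence[int],
        time: Sequence[float],
        labels: Sequence[str | None],
        branch_lengths: Sequence[float] | None = None,
        units: str = "generations",
    ) -> None:
        self.parent = np.asarray(parent, dtype=np.int64)
        self.time = np.asarray(time, dtype=float)
        self.labels = list(labels)
        self.units = units
        n = len(self.parent)
        if not (len(self.time) == len(self.labels) == n):
            raise ValueError("parent/time/labels length mismatch")
        roots = np.flatnonzero(self.parent < 0)
        if len(roots) != 1:
            raise ValueError(f"expected exactly one root, found {len(roots)}")
        self.root = int(roots[0])
        self.children: list[list[int]] = [[] for _ in range(n)]
        for i, p in enumerate(self.parent):
            if p >= 0:
                self.children[p].append(i)
        if branch_lengths is None:
            bl = np.zeros(n)
            ok = self.parent >= 0
            bl[ok] = self.time[self.parent[ok]] - self.time[ok]
            self.branch_lengths = bl
        else:
            self.branch_lengths = np.asarray(branch_lengths, dtype=float)
        if (self.branch_lengths[self.parent >= 0] < -1e-9).any():
            raise ValueError("negative branch length")

    # -- structure ----------------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @property
    def leaf_indices(self) -> list[int]:
        return [i for i in range(self.n_nodes) if not self.children[i]]

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_indices)

    @property
    def leaf_labels(self) -> list[str]:
        return [self.labels[i] for i in self.leaf_indices]

    def postorder(self) -> list[int]:
        order: list[int] = []
        stack = [self.root]
        while stack:
            v = stack.pop()
            order.append(v)
            stack.extend(self.children[v])
        order.reverse()
        return order

    # -- io ------------------------------------------------------------------

    def newick(self, precision: int = 10) -> str:
        def fmt(v: int) -> str:
            if self.children[v]:
                inner = ",".join(fmt(c) for c in self.children[v])
                name = self.labels[v] or ""
                s = f"({inner}){name}"
            else:
                s = self.labels[v] or f"n{v}"
            if v != self.root:
                s += f":{self.branch_lengths[v]:.{precision}g}"
            return s

        return fmt(self.root) + ";"

    @classmethod
    def from_newick(cls, text: str, units: str = "substitutions") -> "Genealogy":
        return load_user_tree(text, units=units)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Genealogy):
            return NotImplemented
        return self.newick() == other.newick()

    def __repr__(self) -> str:
        return f"<Genealogy n_leaves={self.n_leaves} units={self.units}>"


def tmrca(genealogy: Genealogy) -> float:
    """Time of the root, baseline 0 at the most recent sample (generations)."""
    return float(genealogy.time[genealogy.root])


def total_branch_length(genealogy: Genealogy) -> float:
    mask = genealogy.parent >= 0
    return float(genealogy.branch_lengths[mask].sum())


def load_user_tree(source: str, units: str = "substitutions") -> Genealogy:
    """Parse a rooted Newick tree; branch lengths are taken at face value
    (expected substitutions per site in phylogenetic mode).

    ``source`` is Newick text or a path to a Newick file.  Node times are
    reconstructed as heights: ``time(v) = max path length from v down to any
    leaf``, so the root time equals the tree height.
    """
    import dendropy

    text = source
    if "(" not in source:  # path, not newick text
        with open(source) as fh:
            text = fh.read()
    try:
        dtree = dendropy.Tree.get(
            data=text, schema="newick", suppress_internal_node_taxa=False
        )
    except Exception as e:  # dendropy raises several parse error types
        raise ValueError(f"malformed Newick input: {e}") from e

    dnodes = list(dtree.preorder_node_iter())
    index = {id(nd): i for i, nd in enumerate(dnodes)}
    parent, blen, labels = [], [], []
    for nd in dnodes:
        parent.append(-1 if nd.parent_node is None else index[id(nd.parent_node)])
        blen.append(float(nd.edge.length) if nd.edge.length is not None else 0.0)
        name = None
        if nd.taxon is not None:
            name = nd.taxon.label
        elif nd.label:
            name = nd.label
        labels.append(name)
    # heights from branch lengths
    n = len(dnodes)
    children: list[list[int]] = [[] for _ in range(n)]
    for i, p in enumerate(parent):
        if p >= 0:
            children[p].append(i)
    time = [0.0] * n
    for i in range(n - 1, -1, -1):  # preorder reversed = children before parents
        if children[i]:
            time[i] = max(time[c] + blen[c] for c in children[i])
    return Genealogy(parent, time, labels, branch_lengths=blen, units=units)


@dataclass
class MarginalTreeSet:
    """Ordered (half-open site interval -> genealogy) map for one region."""

    intervals: list[tuple[int, int]]
    trees: list[Genealogy]
    n_recombination_events: int
    #: one entry per recombination event (repeats possible); intervals are the
    #: deduplicated tiling induced by these positions
    breakpoint_positions: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        if len(self.intervals) != len(self.trees):
            raise ValueError("intervals and trees must align")
        for (a, b), (c, _) in zip(self.intervals, self.intervals[1:]):
            if b != c:
                raise ValueError("intervals must tile the region")

    @property
    def length(self) -> int:
        return self.intervals[-1][1]

    def tree_at(self, site: int) -> Genealogy:
        for (a, b), t in zip(self.intervals, self.trees):
            if a <= site < b:
                return t
        raise IndexError(site)


# ---------------------------------------------------------------------------
# simulation engine


class _Lineage:
    __slots__ = ("segs", "deme")

    def __init__(self, segs: list[tuple[int, int, int]], deme: str) -> None:
        self.segs = segs  # sorted (start, end, n_samples_below)
        self.deme = deme


def _merge_segments(
    a: list[tuple[int, int, int]], b: list[tuple[int, int, int]]
) -> list[tuple[int, int, int]]:
    """Union of two segment lists, adding subtended-sample counts on overlap."""
    points = sorted({p for s, e, _ in a + b for p in (s, e)})
    out: list[tuple[int, int, int]] = []
    ia = ib = 0
    for lo, hi in zip(points, points[1:]):
        c = 0
        for segs in (a, b):
            for s, e, cnt in segs:
                if s <= lo and hi <= e:
                    c += cnt
        if c > 0:
            if out and out[-1][1] == lo and out[-1][2] == c:
                out[-1] = (out[-1][0], hi, c)
            else:
                out.append((lo, hi, c))
    return out


def _split_segments(
    segs: list[tuple[int, int, int]], bp: int
) -> tuple[list[tuple[int, int, int]], list[tuple[int, int, int]]]:
    left, right = [], []
    for s, e, c in segs:
        if e <= bp:
            left.append((s, e, c))
        elif s >= bp:
            right.append((s, e, c))
        else:
            left.append((s, bp, c))
            right.append((bp, e, c))
    return left, right


def _exp_growth_wait(hazard0: float, g: float, u: float) -> float:
    """Waiting time for an inhomogeneous clock with hazard h(s)=hazard0*e^{g s},
    given a unit-exponential draw ``u``."""
    if hazard0 <= 0:
        return math.inf
    if g == 0.0:
        return u / hazard0
    arg = 1.0 + g * u / hazard0
    if arg <= 0:
        return math.inf  # declining hazard never accumulates enough mass
    return math.log(arg) / g


def simulate_arg(
    sample: SampleConfig,
    demography: Demography,
    structure: PopulationStructure | None = None,
    recmap: RecombinationMap | None = None,
    L: int = 1,
    rng: np.random.Generator | None = None,
) -> MarginalTreeSet:
    """Simulate an ancestral recombination graph and its marginal trees.

    With ``recmap=None`` (or rate 0) this reduces to a single-tree coalescent
    simulation over the interval ``[0, L)``.
    """
    if rng is None:
        rng = np.random.default_rng()
    if structure is None:
        structure = PopulationStructure.panmictic(deme=sample.groups[0][0])
    if recmap is not None and recmap.length != L:
        raise ValueError("recombination map length must equal L")
    if recmap is not None and recmap.rate > 0 and L < 2:
        raise ValueError("recombination requires L >= 2")

    cum_link = recmap.link_cumulative() if recmap is not None else None

    samples = sample.sample_list()
    n_total = len(samples)
    # pending activations sorted by time
    pending = sorted(
        ((t, deme, i, lab) for i, (deme, t, lab) in enumerate(samples)),
        key=lambda x: x[0],
    )
    split_queue = list(structure.splits)
    deme_of_lineage: dict[int, str] = {}

    lineages: dict[int, _Lineage] = {}
    next_node = n_total
    leaf_times = [t for _, t, _ in samples]
    labels: list[str | None] = [lab for _, _, lab in samples]

    events: list[tuple] = []  # ("coal"/"recomb", time, ...)
    n_recomb = 0
    t = 0.0
    guard = GUARD_HORIZON_FACTOR * demography.max_2N()

    def activate_due() -> None:
        nonlocal pending
        while pending and pending[0][0] <= t + 1e-12:
            at, deme, idx, _lab = pending.pop(0)
            if deme not in demography.epoch_at(max(at, t)).sizes:
                raise CoalescentError(f"sample deme {deme!r} has no size in demography")
            lineages[idx] = _Lineage([(0, L, 1)], deme)

    activate_due()

    if n_total == 1:  # degenerate sample: single-leaf tree, no events
        return _extract_marginal_trees([], 1, leaf_times, labels, L, 0)

    while lineages or pending:
        if not lineages:
            t = pending[0][0]
            activate_due()
            continue
        if t > guard:
            raise CoalescentError(
                "no coalescence within the guard horizon "
                f"({guard:.3g} generations); check migration/split configuration"
            )

        epoch = demography.epoch_at(t)
        mig = structure.migration_at(t)

        # group lineages by deme
        by_deme: dict[str, list[int]] = {}
        for lid, lin in lineages.items():
            by_deme.setdefault(lin.deme, []).append(lid)

        # next deterministic boundary
        boundary = epoch.end
        if split_queue:
            boundary = min(boundary, split_queue[0].time)
        if pending:
            boundary = min(boundary, pending[0][0])
        for start, _m in structure.migration:
            if start > t:
                boundary = min(boundary, start)
                break

        # candidate waiting times
        best_w = math.inf
        best_event: tuple | None = None
        for deme, lids in by_deme.items():
            k = len(lids)
            if k < 2:
                continue
            if deme not in epoch.sizes:
                raise CoalescentError(f"deme {deme!r} has no size in epoch at t={t}")
            n_now = epoch.size(deme, t)
            hazard0 = k * (k - 1) / 2.0 / (2.0 * n_now)
            w = _exp_growth_wait(hazard0, epoch.growth.get(deme, 0.0), rng.exponential())
            if w < best_w:
                best_w, best_event = w, ("coal", deme)
        if mig is not None:
            deme_idx = {d: i for i, d in enumerate(structure.demes)}
            rates = [
                (lid, mig[deme_idx[lin.deme]].sum()) for lid, lin in lineages.items()
            ]
            total_mig = sum(r for _, r in rates)
            if total_mig > 0:
                w = rng.exponential() / total_mig
                if w < best_w:
                    best_w, best_event = w, ("mig", rates, total_mig, deme_idx, mig)
        if cum_link is not None:
            rec_rates = []
            for lid, lin in lineages.items():
                if lin.segs:
                    lo = lin.segs[0][0]
                    hi = lin.segs[-1][1]
                    r = cum_link[hi - 1] - cum_link[lo]
                    if r > 0:
                        rec_rates.append((lid, r, lo, hi))
            total_rec = sum(r for _, r, _, _ in rec_rates)
            if total_rec > 0:
                w = rng.exponential() / total_rec
                if w < best_w:
                    best_w, best_event = w, ("rec", rec_rates, total_rec)

        if t + best_w >= boundary:
            if math.isinf(boundary):
                raise CoalescentError(
                    "configuration cannot coalesce: disconnected demes with "
                    "zero event rates"
                )
            t = boundary
            activate_due()
            while split_queue and split_queue[0].time <= t + 1e-12:
                sp = split_queue.pop(0)
                for lin in lineages.values():
                    if lin.deme in sp.children:
                        lin.deme = sp.parent
            continue

        t += best_w
        kind = best_event[0]
        if kind == "coal":
            deme = best_event[1]
            lids = [lid for lid, lin in lineages.items() if lin.deme == deme]
            i, j = rng.choice(len(lids), size=2, replace=False)
            a, b = lids[int(i)], lids[int(j)]
            merged = _merge_segments(lineages[a].segs, lineages[b].segs)
            events.append(("coal", t, a, b, next_node))
            # material that has reached its grand MRCA stops participating
            keep = [(s, e, c) for s, e, c in merged if c < n_total]
            del lineages[a], lineages[b]
            if keep:
                lineages[next_node] = _Lineage(keep, deme)
            next_node += 1
        elif kind == "mig":
            _, rates, total_mig, deme_idx, mig_m = best_event
            u = rng.uniform(0, total_mig)
            acc = 0.0
            for lid, r in rates:
                acc += r
                if u <= acc:
                    row = mig_m[deme_idx[lineages[lid].deme]]
                    dest = rng.choice(len(row), p=row / row.sum())
                    lineages[lid].deme = structure.demes[int(dest)]
                    break
        else:  # recombination
            _, rec_rates, total_rec = best_event
            u = rng.uniform(0, total_rec)
            acc = 0.0
            for lid, r, lo, hi in rec_rates:
                acc += r
                if u <= acc:
                    target = rng.uniform(0, r) + cum_link[lo]
                    bp = int(np.searchsorted(cum_link, target, side="left"))
                    bp = max(lo + 1, min(bp, hi - 1))
                    left, right = _split_segments(lineages[lid].segs, bp)
                    deme = lineages[lid].deme
                    del lineages[lid]
                    la, lb = next_node, next_node + 1
                    next_node += 2
                    lineages[la] = _Lineage(left, deme)
                    lineages[lb] = _Lineage(right, deme)
                    events.append(("recomb", t, lid, la, lb, bp))
                    n_recomb += 1
                    break

    return _extract_marginal_trees(
        events, n_total, leaf_times, labels, L, n_recomb
    )


def _extract_marginal_trees(
    events: list[tuple],
    n_total: int,
    leaf_times: list[float],
    labels: list[str | None],
    L: int,
    n_recomb: int,
) -> MarginalTreeSet:
    breakpoints = sorted({e[5] for e in events if e[0] == "recomb"})
    bounds = [0] + [b for b in breakpoints if 0 < b < L] + [L]
    intervals = list(zip(bounds, bounds[1:]))

    trees = []
    for a, b in intervals:
        x = a  # any point in [a, b) sees the same marginal history
        parent = [-1] * n_total
        time = list(leaf_times)
        labs: list[str | None] = list(labels)
        carrier: dict[int, int] = {i: i for i in range(n_total)}  # lineage -> node
        carried: dict[int, set[int]] = {i: {i} for i in range(n_total)}
        done = False
        for ev in events:
            if done:
                break
            if ev[0] == "coal":
                _, tt, u, v, new = ev
                cu, cv = carried.get(u), carried.get(v)
                if cu and cv:
                    node = len(parent)
                    parent.append(-1)
                    time.append(tt)
                    labs.append(None)
                    parent[carrier[u]] = node
                    parent[carrier[v]] = node
                    carrier[new] = node
                    carried[new] = cu | cv
                    if len(carried[new]) == n_total:
                        done = True
                elif cu or cv:
                    src = u if cu else v
                    carrier[new] = carrier[src]
                    carried[new] = carried[src]
            else:
                _, _tt, src, la, lb, bp = ev
                if src in carried:
                    dest = la if x < bp else lb
                    carrier[dest] = carrier[src]
                    carried[dest] = carried[src]
        trees.append(Genealogy(parent, time, labs, units="generations"))
    positions = tuple(e[5] for e in events if e[0] == "recomb")
    return MarginalTreeSet(intervals, trees, n_recomb, positions)


def simulate_genealogy(
    sample: SampleConfig,
    demography: Demography,
    structure: PopulationStructure | None = None,
    rng: np.random.Generator | None = None,
) -> Genealogy:
    """Simulate one genealogy (no recombination) under the structured
    coalescent with demography and longitudinal sampling."""
    mts = simulate_arg(sample, demography, structure, recmap=None, L=1, rng=rng)
    return mts.trees[0]
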