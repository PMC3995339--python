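"""Evolve sequences along genealogies under a normalized rate model.

Sites evolve independently down the tree using exact transition probabilities
``P(b * mu * rate_site) = exp(Q b mu rate_site)`` (coalescent mode, branch
lengths in generations scaled by the per-site substitution rate ``mu``; in
user-tree mode branch lengths are already expected substitutions and ``mu``
is ignored).  Root sequences are drawn at stationarity.  A Gillespie
jump-chain simulator of the same process is provided as an independent test
oracle; the transition-probability path is the production implementation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .coalescent import Genealogy, MarginalTreeSet
from .subst_models import (
    RateModel,
    SiteProfileSet,
    SiteRateProfile,
    build_gy94,
)

__all__ = [
    "RegionAlignment",
    "draw_root_sequence",
    "evolve_along_tree",
    "evolve_region",
    "per_branch_model_override",
    "gillespie_endpoint",
]


@dataclass
class RegionAlignment:
    """Gap-free alignment of one region: rows are samples, columns sites."""

    data_type: str  # nucleotide | codon | aminoacid
    names: list[str]
    codes: np.ndarray  # (n_samples, L) state indices into `states`
    states: tuple[str, ...]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes)
        if self.codes.ndim != 2 or self.codes.shape[0] != len(self.names):
            raise ValueError("codes must be (n_samples, L) aligned with names")

    @property
    def n_samples(self) -> int:
        return self.codes.shape[0]

    @property
    def length(self) -> int:
        return self.codes.shape[1]

    def sequence(self, name: str) -> str:
        i = self.names.index(name)
        return "".join(self.states[c] for c in self.codes[i])

    def sequences(self) -> dict[str, str]:
        return {n: self.sequence(n) for n in self.names}


def draw_root_sequence(
    model: RateModel,
    L: int,
    profiles: SiteProfileSet | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """i.i.d. stationary root states; with CAT profiles, each site draws from
    its own profile's frequencies."""
    if rng is None:
        rng = np.random.default_rng()
    if profiles is None:
        return _sample_rows(np.broadcast_to(model.pi, (L, model.n_states)), rng)
    if len(profiles.assignment) != L:
        raise ValueError("profile assignment length must equal L")
    return _sample_rows(profiles.profiles[profiles.assignment], rng)


def _sample_rows(probs: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    cdf = np.cumsum(probs, axis=1)
    u = rng.random(probs.shape[0]) * cdf[:, -1]
    return (cdf < u[:, None]).sum(axis=1).astype(np.int64)


def _branch_substitutions(genealogy: Genealogy, mu: float | None) -> np.ndarray:
    if genealogy.units == "generations":
        if mu is None or mu <= 0:
            raise ValueError(
                "mu (substitutions/site/generation) is required for "
                "genealogies in generations"
            )
        return genealogy.branch_lengths * mu
    return genealogy.branch_lengths.copy()


def _evolve_states(
    genealogy: Genealogy,
    model: RateModel,
    t_branch: np.ndarray,
    site_rates: np.ndarray,
    root_states: np.ndarray,
    rng: np.random.Generator,
    branch_models: Mapping[int, RateModel] | None = None,
) -> np.ndarray:
    """Propagate state indices from root to every node; returns (n_nodes, S)."""
    S = len(root_states)
    states = np.empty((genealogy.n_nodes, S), dtype=np.int64)
    states[genealogy.root] = root_states
    order = genealogy.postorder()[::-1]  # parents before children
    for v in order:
        if v == genealogy.root:
            continue
        m = branch_models.get(v, model) if branch_models else model
        parent_states = states[genealogy.parent[v]]
        t = t_branch[v] * site_rates
        out = parent_states.copy()
        active = t > 0
        if active.any():
            if (m.pi > 0).all():
                B, lam, Binv = m.eig()
                E = np.exp(np.outer(t[active], lam))
                probs = np.einsum(
                    "sk,sk,kj->sj", B[parent_states[active]], E, Binv
                )
                np.clip(probs, 0.0, None, out=probs)
                out[active] = _sample_rows(probs, rng)
            else:  # degenerate frequencies: group sites by branch length
                from .subst_models import transition_probabilities

                idx = np.flatnonzero(active)
                for tv in np.unique(t[idx]):
                    P = transition_probabilities(m, float(tv))
                    sel = idx[t[idx] == tv]
                    out[sel] = _sample_rows(P[parent_states[sel]], rng)
        states[v] = out
    return states


def evolve_along_tree(
    genealogy: Genealogy,
    model: RateModel,
    site_rates: SiteRateProfile | None = None,
    mu: float | None = None,
    rng: np.random.Generator | None = None,
    L: int | None = None,
    profiles: SiteProfileSet | None = None,
    data_type: str | None = None,
    provenance: dict | None = None,
) -> RegionAlignment:
    """Evolve one region along a single genealogy.

    The sequence length is taken from ``site_rates`` (or ``L``); the root is
    drawn at stationarity and each site evolves independently with per-site
    rate multipliers (invariable sites, rate 0, are copied unchanged).
    Per-branch dN/dS overrides installed by :func:`per_branch_model_override`
    are honoured.
    """
    if rng is None:
        rng = np.random.default_rng()
    if site_rates is None:
        if L is None:
            raise ValueError("either site_rates or L is required")
        site_rates = SiteRateProfile.homogeneous(L)
    Lx = len(site_rates.rates)
    t_branch = _branch_substitutions(genealogy, mu)
    _materialize_branch_models(genealogy, model)
    branch_models = getattr(genealogy, "branch_models", None)

    if profiles is None:
        root = draw_root_sequence(model, Lx, rng=rng)
        states = _evolve_states(
            genealogy, model, t_branch, site_rates.rates, root, rng, branch_models
        )
    else:
        # CAT-style: each profile class evolves under its own-frequency model
        states = np.empty((genealogy.n_nodes, Lx), dtype=np.int64)
        for k in range(len(profiles.profiles)):
            sel = np.flatnonzero(profiles.assignment == k)
            if not sel.size:
                continue
            sub = _with_frequencies(model, profiles.profiles[k])
            root = draw_root_sequence(sub, len(sel), rng=rng)
            states[:, sel] = _evolve_states(
                genealogy, sub, t_branch, site_rates.rates[sel], root, rng, None
            )

    leaves = genealogy.leaf_indices
    return RegionAlignment(
        data_type=data_type or _infer_data_type(model),
        names=[genealogy.labels[i] for i in leaves],
        codes=states[leaves],
        states=model.states,
        provenance=provenance or {},
    )


def _infer_data_type(model: RateModel) -> str:
    return {4: "nucleotide", 61: "codon", 20: "aminoacid"}[model.n_states]


def _with_frequencies(model: RateModel, pi: np.ndarray) -> RateModel:
    """Rebuild a reversible model with the same exchangeabilities but new
    equilibrium frequencies (used for CAT profile classes)."""
    from .subst_models import _finalize

    with np.errstate(divide="ignore", invalid="ignore"):
        S = np.where(model.pi[None, :] > 0, model.Q / model.pi[None, :], 0.0)
    np.fill_diagonal(S, 0.0)
    return _finalize(model.states, S * pi[None, :], pi, model.name + "+CAT")


def per_branch_model_override(
    genealogy: Genealogy, omega_multipliers: Mapping[int, float]
) -> Genealogy:
    """Annotate a genealogy so GY94 evolution uses per-branch effective
    dN/dS ``omega * multiplier`` on the flagged branches (keyed by child node
    index).  Returns the same genealogy object, annotated."""
    if any(m < 0 for m in omega_multipliers.values()):
        raise ValueError("omega multipliers must be >= 0")
    genealogy.pending_omega_multipliers = dict(omega_multipliers)
    return genealogy


def _materialize_branch_models(genealogy: Genealogy, model: RateModel) -> None:
    mult = getattr(genealogy, "pending_omega_multipliers", None)
    if not mult:
        return
    params = model.params
    if "omega" not in params:
        raise ValueError("per-branch omega overrides require a GY94 model")
    cache: dict[float, RateModel] = {}
    out = {}
    for branch, m in mult.items():
        if m not in cache:
            cache[m] = build_gy94(params["kappa"], params["omega"] * m, params["freqs"])
        out[branch] = cache[m]
    genealogy.branch_models = out


def evolve_region(
    marginal_trees: MarginalTreeSet,
    model: RateModel,
    site_rates: SiteRateProfile | None = None,
    mu: float | None = None,
    rng: np.random.Generator | None = None,
    data_type: str | None = None,
    strict_codon_boundaries: bool = False,
) -> RegionAlignment:
    """Evolve a region over its marginal-tree set.

    Each interval evolves on its own marginal tree with an independent
    stationary root (ancestral material beyond the grand MRCA is unlinked);
    columns are stitched in coordinate order.  For codon models the
    nucleotide-resolution breakpoints are mapped down to the containing codon
    start; with ``strict_codon_boundaries=True`` a breakpoint off a codon
    boundary raises instead.
    """
    if rng is None:
        rng = np.random.default_rng()
    dtype = data_type or _infer_data_type(model)
    intervals = list(marginal_trees.intervals)
    trees = list(marginal_trees.trees)
    L_nt = marginal_trees.length

    if dtype == "codon":
        if L_nt % 3:
            raise ValueError("codon region length must be a multiple of 3")
        if strict_codon_boundaries and any(a % 3 for a, _ in intervals):
            raise ValueError(
                "recombination breakpoint off a codon boundary; rerun with "
                "codon-boundary recombination (or strict_codon_boundaries=False "
                "to round breakpoints down to codon starts)"
            )
        merged: list[tuple[int, Genealogy]] = []
        for (a, _b), tree in zip(intervals, trees):
            ca = a // 3
            if merged and merged[-1][0] == ca:
                continue  # interval collapsed by rounding; keep the first tree
            merged.append((ca, tree))
        starts = [c for c, _ in merged] + [L_nt // 3]
        intervals = list(zip(starts, starts[1:]))
        trees = [t for _, t in merged]
        L_units = L_nt // 3
    else:
        L_units = L_nt

    if site_rates is None:
        site_rates = SiteRateProfile.homogeneous(L_units)
    if len(site_rates.rates) != L_units:
        raise ValueError("site rate profile length must match region length")

    names = [trees[0].labels[i] for i in trees[0].leaf_indices]
    codes = np.empty((len(names), L_units), dtype=np.int64)
    for (a, b), tree in zip(intervals, trees):
        sub_rates = SiteRateProfile(
            site_rates.p_inv, site_rates.gamma_shape, site_rates.rates[a:b]
        )
        aln = evolve_along_tree(
            tree, model, site_rates=sub_rates, mu=mu, rng=rng, data_type=dtype
        )
        for i, name in enumerate(names):
            codes[i, a:b] = aln.codes[aln.names.index(name)]
    return RegionAlignment(
        data_type=dtype,
        names=names,
        codes=codes,
        states=model.states,
        provenance={"n_intervals": len(intervals)},
    )


# ---------------------------------------------------------------------------
# event-simulation oracle


def gillespie_endpoint(
    model: RateModel,
    start: int,
    t: float,
    rng: np.random.Generator,
) -> tuple[int, int]:
    """Jump-chain simulation of the substitution process over time ``t``.

    Returns (end state, number of substitution events).  Used only as an
    independent oracle against exp(Qt) in tests.
    """
    state = int(start)
    n_events = 0
    elapsed = 0.0
    while True:
        rate = -model.Q[state, state]
        if rate <= 0:
            return state, n_events
        elapsed += rng.exponential(1.0 / rate)
        if elapsed >= t:
            return state, n_events
        probs = model.Q[state].copy()
        probs[state] = 0.0
        state = int(rng.choice(model.n_states, p=probs / probs.sum()))
        n_events += 1
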