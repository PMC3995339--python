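"""Normalized instantaneous rate matrices for nucleotide, codon and amino
acid evolution, plus among-site rate and frequency heterogeneity.

All models are time-reversible with ``Q_ij = s_ij * pi_j`` for some symmetric
exchangeability term, scaled so the expected substitution rate at stationarity
is one (``-sum_i pi_i Q_ii = 1``); branch lengths are therefore expected
substitutions per site (nucleotide, codon or residue, according to the
alphabet).  Codon models (GY94, MG94) act on the 61 sense codons of the
universal genetic code; stop codons are structurally excluded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Sequence

import numpy as np
from Bio.Data import CodonTable

__all__ = [
    "NUCLEOTIDES",
    "CODONS",
    "AMINO_ACIDS",
    "GENETIC_CODE",
    "RateModel",
    "CodonFrequencies",
    "SiteRateProfile",
    "SiteProfileSet",
    "build_gtr",
    "build_gy94",
    "build_mg94",
    "build_empirical",
    "load_empirical_matrix",
    "write_empirical_matrix",
    "draw_site_rates",
    "f3x4",
    "transition_probabilities",
    "is_transition",
]

NUCLEOTIDES = "ACGT"
#: PAML ordering of the amino acids, used by empirical ".dat" files
AMINO_ACIDS = "ARNDCQEGHILKMFPSTWYV"

_table = CodonTable.unambiguous_dna_by_id[1]  # the universal genetic code
STOP_CODONS = tuple(sorted(_table.stop_codons))
CODONS = tuple(
    sorted(c for c in (a + b + d for a in NUCLEOTIDES for b in NUCLEOTIDES for d in NUCLEOTIDES) if c not in STOP_CODONS)
)
GENETIC_CODE = {c: _table.forward_table[c] for c in CODONS}
CODON_INDEX = {c: i for i, c in enumerate(CODONS)}
NUC_INDEX = {n: i for i, n in enumerate(NUCLEOTIDES)}

_PURINES = {"A", "G"}


def is_transition(a: str, b: str) -> bool:
    """A<->G and C<->T changes are transitions; the rest are transversions."""
    return (a in _PURINES) == (b in _PURINES) and a != b


@lru_cache(maxsize=1)
def _codon_pair_tables() -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Precomputed classification of all 61x61 codon pairs.

    Returns boolean matrices (single-position difference, transition,
    nonsynonymous) and an integer matrix of the differing position (-1 when
    not exactly one).
    """
    n = len(CODONS)
    single = np.zeros((n, n), dtype=bool)
    ts = np.zeros((n, n), dtype=bool)
    nonsyn = np.zeros((n, n), dtype=bool)
    pos = np.full((n, n), -1, dtype=np.int8)
    for i, ci in enumerate(CODONS):
        for j, cj in enumerate(CODONS):
            if i == j:
                continue
            diff = [k for k in range(3) if ci[k] != cj[k]]
            if len(diff) != 1:
                continue
            k = diff[0]
            single[i, j] = True
            pos[i, j] = k
            ts[i, j] = is_transition(ci[k], cj[k])
            nonsyn[i, j] = GENETIC_CODE[ci] != GENETIC_CODE[cj]
    return single, ts, nonsyn, pos


# ---------------------------------------------------------------------------
# containers


@dataclass
class RateModel:
    """Normalized reversible rate matrix over an ordered state alphabet."""

    states: tuple[str, ...]
    Q: np.ndarray
    pi: np.ndarray
    name: str = "custom"
    params: dict = field(default_factory=dict, repr=False, compare=False)
    _eig: tuple | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        n = len(self.states)
        self.Q = np.asarray(self.Q, dtype=float)
        self.pi = np.asarray(self.pi, dtype=float)
        if self.Q.shape != (n, n) or self.pi.shape != (n,):
            raise ValueError("Q/pi shape inconsistent with state alphabet")

    @property
    def n_states(self) -> int:
        return len(self.states)

    def eig(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Spectral decomposition ``P(t) = B diag(e^{lambda t}) Binv`` via
        symmetrization by pi^(1/2) (exact for reversible Q, positive pi)."""
        if self._eig is None:
            d = np.sqrt(self.pi)
            S = (self.Q * d[:, None]) / d[None, :]
            S = (S + S.T) / 2.0  # enforce symmetry against round-off
            lam, U = np.linalg.eigh(S)
            B = U / d[:, None]
            Binv = U.T * d[None, :]
            self._eig = (B, lam, Binv)
        return self._eig


def _finalize(states, rates: np.ndarray, pi: np.ndarray, name: str) -> RateModel:
    """Fill the diagonal and normalize the mean rate at stationarity to 1."""
    pi = np.asarray(pi, dtype=float)
    if (pi < 0).any() or abs(pi.sum() - 1.0) > 1e-9:
        raise ValueError("invalid frequency vector")
    Q = np.array(rates, dtype=float)
    np.fill_diagonal(Q, 0.0)
    if not np.isfinite(Q).all() or (Q < 0).any():
        raise ValueError("off-diagonal rates must be finite and nonnegative")
    np.fill_diagonal(Q, -Q.sum(axis=1))
    scale = -float(pi @ np.diag(Q))
    if scale <= 0:
        raise ValueError("rate matrix has zero total rate; cannot normalize")
    return RateModel(tuple(states), Q / scale, pi, name=name)


@dataclass(frozen=True)
class CodonFrequencies:
    """Equilibrium codon frequencies: equal, F1x61 or F3x4."""

    mode: str  # equal | f1x61 | f3x4
    codon_freqs: np.ndarray
    position_freqs: np.ndarray | None = None  # 3x4, F3x4 only

    def __post_init__(self) -> None:
        f = np.asarray(self.codon_freqs, dtype=float)
        if f.shape != (len(CODONS),) or (f < 0).any() or abs(f.sum() - 1) > 1e-9:
            raise ValueError("codon_freqs must be a 61-state frequency vector")
        object.__setattr__(self, "codon_freqs", f)

    @classmethod
    def equal(cls) -> "CodonFrequencies":
        n = len(CODONS)
        return cls("equal", np.full(n, 1.0 / n))

    @classmethod
    def f1x61(cls, codon_freqs: Sequence[float]) -> "CodonFrequencies":
        return cls("f1x61", np.asarray(codon_freqs, dtype=float))


def f3x4(position_freqs: Sequence[Sequence[float]]) -> CodonFrequencies:
    """Codon frequencies proportional to the product of the nucleotide
    frequencies at the codon's three positions, stops removed, renormalized."""
    pf = np.asarray(position_freqs, dtype=float)
    if pf.shape != (3, 4) or (pf < 0).any():
        raise ValueError("position_freqs must be three nonnegative 4-vectors")
    if np.abs(pf.sum(axis=1) - 1).max() > 1e-9:
        raise ValueError("each position frequency vector must sum to 1")
    f = np.array(
        [pf[0, NUC_INDEX[c[0]]] * pf[1, NUC_INDEX[c[1]]] * pf[2, NUC_INDEX[c[2]]] for c in CODONS]
    )
    if f.sum() <= 0:
        raise ValueError("all sense codons have zero frequency under these positions")
    return CodonFrequencies("f3x4", f / f.sum(), position_freqs=pf)


@dataclass
class SiteRateProfile:
    """Realized per-site rate multipliers: invariable sites have rate 0,
    variable sites draw from Gamma(shape alpha, mean 1)."""

    p_inv: float
    gamma_shape: float | None
    rates: np.ndarray

    @classmethod
    def homogeneous(cls, L: int) -> "SiteRateProfile":
        return cls(0.0, None, np.ones(L))


@dataclass
class SiteProfileSet:
    """CAT-style site-heterogeneous equilibrium frequencies: a list of
    frequency profiles plus a per-site profile assignment."""

    profiles: np.ndarray  # (n_profiles, n_states)
    assignment: np.ndarray  # (L,) profile index per site

    def __post_init__(self) -> None:
        p = np.asarray(self.profiles, dtype=float)
        if (p < 0).any() or np.abs(p.sum(axis=1) - 1).max() > 1e-9:
            raise ValueError("each profile must be a frequency vector")
        self.profiles = p
        self.assignment = np.asarray(self.assignment, dtype=int)


# ---------------------------------------------------------------------------
# model builders


def build_gtr(exchangeabilities: Sequence[float], pi: Sequence[float]) -> RateModel:
    """General time-reversible nucleotide model.

    ``exchangeabilities`` are the six upper-triangle rates in the order
    (AC, AG, AT, CG, CT, GT); ``Q_ij = r_ij * pi_j``.
    """
    r = np.asarray(exchangeabilities, dtype=float)
    if r.shape != (6,) or (r < 0).any():
        raise ValueError("GTR needs 6 nonnegative exchangeabilities")
    if not r.any():
        raise ValueError("all exchangeabilities are zero")
    pi = np.asarray(pi, dtype=float)
    S = np.zeros((4, 4))
    iu = np.triu_indices(4, k=1)
    S[iu] = r
    S = S + S.T
    return _finalize(tuple(NUCLEOTIDES), S * pi[None, :], pi, "GTR")


def build_gy94(
    kappa: float, omega: float, codon_freqs: CodonFrequencies
) -> RateModel:
    """Goldman-Yang codon model (M0 with a single dN/dS class).

    For codon pairs differing at exactly one position the rate is
    ``pi_target * kappa^[transition] * omega^[nonsynonymous]``; multi-position
    changes have rate 0.
    """
    if kappa <= 0 or omega < 0:
        raise ValueError("require kappa > 0 and omega >= 0")
    single, ts, nonsyn, _ = _codon_pair_tables()
    fac = np.where(single, 1.0, 0.0)
    fac = fac * np.where(ts, kappa, 1.0) * np.where(nonsyn, omega, 1.0)
    rates = fac * codon_freqs.codon_freqs[None, :]
    model = _finalize(CODONS, rates, codon_freqs.codon_freqs, "GY94")
    model.params = {"kappa": kappa, "omega": omega, "freqs": codon_freqs}
    return model


def build_mg94(
    kappa: float, omega: float, position_freqs: Sequence[Sequence[float]]
) -> RateModel:
    """Muse-Gaut codon model: the rate uses the frequency of the *target
    nucleotide* at the changing codon position rather than the target codon."""
    if kappa <= 0 or omega < 0:
        raise ValueError("require kappa > 0 and omega >= 0")
    pf = np.asarray(position_freqs, dtype=float)
    if pf.shape != (3, 4):
        raise ValueError("MG94 needs three position-specific 4-vectors")
    single, ts, nonsyn, pos = _codon_pair_tables()
    n = len(CODONS)
    tgt = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if single[i, j]:
                k = pos[i, j]
                tgt[i, j] = pf[k, NUC_INDEX[CODONS[j][k]]]
    rates = tgt * np.where(ts, kappa, 1.0) * np.where(nonsyn, omega, 1.0)
    # stationary distribution of MG94 is the F3x4 product measure
    pi = f3x4(pf).codon_freqs
    return _finalize(CODONS, rates, pi, "MG94")


_ALPHABETS = {
    "nucleotide": tuple(NUCLEOTIDES),
    "codon": CODONS,
    "aminoacid": tuple(AMINO_ACIDS),
}


def build_empirical(
    exchangeabilities: np.ndarray,
    pi: Sequence[float],
    alphabet: str = "aminoacid",
    name: str = "empirical",
) -> RateModel:
    states = _ALPHABETS[alphabet]
    S = np.asarray(exchangeabilities, dtype=float)
    if S.shape != (len(states), len(states)):
        raise ValueError("exchangeability matrix shape mismatch")
    pi = np.asarray(pi, dtype=float)
    return _finalize(states, S * pi[None, :], pi, name)


def load_empirical_matrix(
    path: str, alphabet: str = "aminoacid", pi: Sequence[float] | None = None
) -> RateModel:
    """Load a PAML-style ".dat" empirical matrix.

    The file holds the strict lower triangle of the symmetric exchangeability
    matrix row by row (row i has i entries), followed optionally by a line (or
    lines) of equilibrium frequencies.  ``pi`` overrides the file's
    frequencies (the "+F" option); if neither is present, frequencies are
    uniform.
    """
    states = _ALPHABETS[alphabet]
    n = len(states)
    tokens: list[tuple[float, int]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.split("#")[0].split("//")[0]
            for tok in line.split():
                try:
                    tokens.append((float(tok), lineno))
                except ValueError as e:
                    raise ValueError(
                        f"{path}:{lineno}: non-numeric token {tok!r}"
                    ) from e
    need = n * (n - 1) // 2
    if len(tokens) < need:
        last = tokens[-1][1] if tokens else 1
        raise ValueError(
            f"{path}:{last}: exchangeability triangle for a {n}-state alphabet "
            f"needs {need} entries, found {len(tokens)}"
        )
    S = np.zeros((n, n))
    it = iter(tokens[:need])
    for i in range(1, n):
        for j in range(i):
            S[i, j] = S[j, i] = next(it)[0]
    rest = [v for v, _ in tokens[need:]]
    if pi is not None:
        freqs = np.asarray(pi, dtype=float)
    elif len(rest) >= n:
        freqs = np.asarray(rest[:n])
    elif rest:
        raise ValueError(
            f"{path}: trailing frequency block has {len(rest)} entries, expected {n}"
        )
    else:
        freqs = np.full(n, 1.0 / n)
    freqs = freqs / freqs.sum()
    return build_empirical(S, freqs, alphabet=alphabet, name="empirical")


def write_empirical_matrix(path: str, model: RateModel) -> None:
    """Write exchangeabilities + frequencies in the PAML lower-triangle layout."""
    n = model.n_states
    with np.errstate(divide="ignore", invalid="ignore"):
        S = model.Q / model.pi[None, :]
    with open(path, "w") as fh:
        for i in range(1, n):
            fh.write(" ".join(f"{S[i, j]:.6f}" for j in range(i)) + "\n")
        fh.write("\n" + " ".join(f"{p:.6f}" for p in model.pi) + "\n")


def draw_site_rates(
    L: int,
    alpha: float | None,
    p_inv: float,
    rng: np.random.Generator,
) -> SiteRateProfile:
    """Draw continuous per-site rate multipliers: invariable with probability
    ``p_inv`` (rate 0), otherwise Gamma(alpha, mean 1); ``alpha=None`` means
    no gamma variation (rate 1)."""
    if not 0 <= p_inv < 1:
        raise ValueError("p_inv must lie in [0, 1)")
    if alpha is not None and alpha <= 0:
        raise ValueError("gamma shape must be positive")
    rates = np.ones(L) if alpha is None else rng.gamma(alpha, 1.0 / alpha, L)
    if p_inv > 0:
        rates[rng.random(L) < p_inv] = 0.0
    return SiteRateProfile(p_inv, alpha, rates)


def transition_probabilities(model: RateModel, t: float) -> np.ndarray:
    """``P(t) = exp(Qt)``, by spectral decomposition for strictly positive pi
    and by scipy's expm otherwise; tiny negative round-off is clamped to 0."""
    if t < 0:
        raise ValueError("branch length must be >= 0")
    if not np.isfinite(model.Q).all():
        raise ValueError("non-finite rate matrix")
    if (model.pi > 0).all():
        B, lam, Binv = model.eig()
        P = (B * np.exp(lam * t)[None, :]) @ Binv
    else:
        from scipy.linalg import expm

        P = expm(model.Q * t)
    if P.min() < -1e-12 * max(1.0, t):
        raise FloatingPointError("transition matrix has significant negative entries")
    np.clip(P, 0.0, None, out=P)
    return P
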