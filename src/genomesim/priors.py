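"""Prior distributions governing per-region parameter heterogeneity.

Each genomic region of each replicate draws its own substitution-model
parameters (ti/tv ratio kappa, dN/dS omega, GTR exchangeabilities, state
frequencies, gamma shape alpha, proportion of invariable sites) independently
from user-specified priors.  Supported prior families: fixed, uniform,
exponential (parameterized by its mean), gamma (shape, scale), beta and
dirichlet, with optional truncation of scalar priors to an interval
implemented by rejection sampling.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "PriorSpec",
    "RegionParams",
    "PriorError",
    "parse_prior",
    "sample_scalar",
    "sample_simplex",
    "sample_region_params",
]

SCALAR_KINDS = frozenset({"fixed", "uniform", "exponential", "gamma", "beta"})
KINDS = SCALAR_KINDS | {"dirichlet"}

#: draws attempted before a truncated prior is declared to have ~zero mass
REJECTION_CAP = 10**6


class PriorError(ValueError):
    """Invalid prior specification or pathological truncation."""


@dataclass(frozen=True)
class PriorSpec:
    """One prior distribution, e.g. ``uniform(0.5, 15)`` or
    ``exponential(2.0) truncate(0.5, 5.0)``.

    Parameters
    ----------
    kind:
        One of ``fixed``, ``uniform``, ``exponential`` (mean), ``gamma``
        (shape, scale), ``beta`` (a, b), ``dirichlet`` (concentrations).
    params:
        Numeric parameter list for the family.
    truncation:
        Optional ``(low, high)`` applied to scalar kinds by rejection.
    """

    kind: str
    params: tuple[float, ...]
    truncation: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise PriorError(f"unknown prior kind {self.kind!r}")
        object.__setattr__(self, "params", tuple(float(p) for p in self.params))
        p = self.params
        if self.kind == "fixed" and len(p) != 1:
            raise PriorError("fixed prior takes exactly one value")
        if self.kind == "uniform":
            if len(p) != 2 or not p[0] < p[1]:
                raise PriorError(f"uniform requires low < high, got {p}")
        if self.kind == "exponential":
            if len(p) != 1 or p[0] <= 0:
                raise PriorError("exponential requires a positive mean")
        if self.kind == "gamma":
            if len(p) != 2 or p[0] <= 0 or p[1] <= 0:
                raise PriorError("gamma requires positive (shape, scale)")
        if self.kind == "beta":
            if len(p) != 2 or p[0] <= 0 or p[1] <= 0:
                raise PriorError("beta requires positive (a, b)")
        if self.kind == "dirichlet":
            if len(p) < 2 or any(a <= 0 for a in p):
                raise PriorError(
                    "dirichlet requires >=2 strictly positive concentrations"
                )
            if self.truncation is not None:
                raise PriorError("truncation does not apply to dirichlet priors")
        if self.truncation is not None:
            lo, hi = self.truncation
            if not lo < hi:
                raise PriorError(f"truncation requires low < high, got {self.truncation}")
            if self.kind == "fixed" and not lo <= p[0] <= hi:
                raise PriorError("fixed value lies outside its truncation bounds")
            if self.kind == "uniform" and (hi <= p[0] or lo >= p[1]):
                raise PriorError("truncation interval does not intersect uniform support")

    @property
    def is_scalar(self) -> bool:
        return self.kind in SCALAR_KINDS

    def __str__(self) -> str:  # config round-trip form
        s = f"{self.kind}({', '.join(repr(v) for v in self.params)})"
        if self.truncation is not None:
            s += f" truncate({self.truncation[0]!r}, {self.truncation[1]!r})"
        return s


_PRIOR_RE = re.compile(
    r"^\s*(?P<kind>[a-zA-Z_]+)\s*\(\s*(?P<args>[^)]*)\)\s*"
    r"(?:truncate\s*\(\s*(?P<tlo>[^,]+),\s*(?P<thi>[^)]+)\)\s*)?$"
)


def parse_prior(text: str) -> PriorSpec:
    """Parse the config syntax, e.g. ``dirichlet(6,16,2,8,20,4)`` or
    ``exponential(2.0) truncate(0.5, 5.0)``.  Bare numbers parse as fixed."""
    text = text.strip()
    try:
        return PriorSpec("fixed", (float(text),))
    except ValueError:
        pass
    m = _PRIOR_RE.match(text)
    if m is None:
        raise PriorError(f"cannot parse prior expression {text!r}")
    try:
        params = tuple(float(a) for a in m.group("args").split(",") if a.strip())
    except ValueError as e:
        raise PriorError(f"non-numeric prior parameter in {text!r}") from e
    trunc = None
    if m.group("tlo") is not None:
        try:
            trunc = (float(m.group("tlo")), float(m.group("thi")))
        except ValueError as e:
            raise PriorError(f"non-numeric truncation bound in {text!r}") from e
    return PriorSpec(m.group("kind").lower(), params, trunc)


def _draw_batch(prior: PriorSpec, rng: np.random.Generator, size: int) -> np.ndarray:
    p = prior.params
    if prior.kind == "fixed":
        return np.full(size, p[0])
    if prior.kind == "uniform":
        return rng.uniform(p[0], p[1], size)
    if prior.kind == "exponential":
        return rng.exponential(p[0], size)
    if prior.kind == "gamma":
        return rng.gamma(p[0], p[1], size)
    if prior.kind == "beta":
        return rng.beta(p[0], p[1], size)
    raise PriorError(f"{prior.kind} is not a scalar prior")


def sample_scalar(prior: PriorSpec, rng: np.random.Generator) -> float:
    """Draw one value from a scalar prior, honouring truncation by rejection.

    Rejection redraws until the value falls inside the truncation interval;
    after ``REJECTION_CAP`` failed draws the truncation region is deemed to
    carry essentially no prior mass and a :class:`PriorError` is raised.
    """
    if not prior.is_scalar:
        raise PriorError(f"sample_scalar called on {prior.kind} prior")
    if prior.truncation is None:
        return float(_draw_batch(prior, rng, 1)[0])
    lo, hi = prior.truncation
    drawn = 0
    batch = 64
    while drawn < REJECTION_CAP:
        x = _draw_batch(prior, rng, batch)
        ok = x[(x >= lo) & (x <= hi)]
        if ok.size:
            return float(ok[0])
        drawn += batch
        batch = min(batch * 4, 65536)
    raise PriorError(
        f"truncation {prior.truncation} of prior {prior} has ~zero mass "
        f"(no draw accepted in {REJECTION_CAP} attempts)"
    )


def sample_simplex(prior: PriorSpec, rng: np.random.Generator) -> np.ndarray:
    """Draw a frequency vector from a dirichlet prior (sums to 1)."""
    if prior.kind != "dirichlet":
        raise PriorError(f"sample_simplex requires a dirichlet prior, got {prior.kind}")
    # gamma-normalization construction
    g = rng.gamma(np.asarray(prior.params), 1.0)
    return g / g.sum()


def sample(prior: PriorSpec, rng: np.random.Generator) -> float | np.ndarray:
    """Dispatch on kind: scalar draw or simplex draw."""
    if prior.kind == "dirichlet":
        return sample_simplex(prior, rng)
    return sample_scalar(prior, rng)


@dataclass
class RegionParams:
    """Realized per-region model parameters for one replicate."""

    region_index: int
    label: str
    length: int
    data_type: str  # nucleotide | codon | aminoacid
    model: str  # gtr | gy94 | mg94 | empirical
    model_params: dict[str, object] = field(default_factory=dict)

    def flat_items(self) -> list[tuple[str, object]]:
        """Flatten vector-valued parameters for the tab-separated log."""
        out: list[tuple[str, object]] = []
        for name, val in sorted(self.model_params.items()):
            if isinstance(val, str):
                out.append((name, val))
                continue
            arr = np.asarray(val)
            if arr.ndim == 0:
                out.append((name, float(arr)))
            elif arr.ndim == 1:
                out.extend((f"{name}[{i}]", float(v)) for i, v in enumerate(arr))
            else:
                for i, row in enumerate(arr):
                    out.extend(
                        (f"{name}[{i}][{j}]", float(v)) for j, v in enumerate(row)
                    )
        return out


def _realize(name: str, spec: object, rng: np.random.Generator) -> object:
    if isinstance(spec, PriorSpec):
        value = sample(spec, rng)
    elif isinstance(spec, (int, float)):
        value = float(spec)
    elif isinstance(spec, str):
        return spec  # keyword values such as "equal" pass through unchanged
    elif isinstance(spec, (list, tuple, np.ndarray)):
        value = np.asarray(spec, dtype=float)
    else:
        raise PriorError(f"parameter {name!r}: cannot realize value of type {type(spec)}")
    if name == "exchangeabilities":
        value = np.asarray(value, dtype=float)
        if value[-1] <= 0:
            raise PriorError("last exchangeability is zero; cannot rescale")
        value = value / value[-1]  # scale so the last rate equals 1
    return value


def sample_region_params(
    regions: Sequence,
    replicate_index: int,
    seed: int,
) -> list[RegionParams]:
    """Realize per-region parameters for one replicate.

    ``regions`` is a sequence of region declarations (see
    :class:`genomesim.genome_io.RegionSpec`) carrying ``label``, ``length``,
    ``data_type``, ``model`` and a ``params`` mapping of parameter name to
    either a fixed numeric value, a vector, or a :class:`PriorSpec`.

    Every (replicate, region, parameter) triple draws from its own RNG
    substream, so draws are independent across regions and stable under
    addition of regions or replicates.
    """
    out: list[RegionParams] = []
    for r_idx, region in enumerate(regions):
        realized: dict[str, object] = {}
        for name, spec in region.params.items():
            rng = substream_for(seed, replicate_index, r_idx, name)
            if name == "position_freqs" and isinstance(spec, PriorSpec):
                # one independent dirichlet draw per codon position
                realized[name] = np.vstack([sample_simplex(spec, rng) for _ in range(3)])
            else:
                realized[name] = _realize(name, spec, rng)
        out.append(
            RegionParams(
                region_index=r_idx,
                label=region.label,
                length=region.length,
                data_type=region.data_type,
                model=region.model,
                model_params=realized,
            )
        )
    return out


def substream_for(seed: int, replicate: int, region: int, purpose: str):
    """Generator for one (replicate, region, purpose) stream."""
    from ._rng import substream

    return substream(seed, replicate, region, purpose)
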