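"""Configuration parsing, replicate orchestration and file formats.

A genome is an ordered set of regions, each with its own data type, length,
model family and parameter priors.  A plain-text sectioned config describes
the genome, the demography/structure/sampling and the replicate count; for
each replicate the pipeline samples per-region parameters from their priors,
simulates a genealogy (or marginal-tree set, with recombination) per region,
evolves sequences and assembles the concatenated genome alignment.  Outputs:
FASTA or relaxed-PHYLIP alignments, Newick trees, a tab-separated parameter
log, a BED-like region table and a checksummed manifest.

Config syntax (INI-style sections; ``#`` comments; values may be numbers,
prior expressions like ``uniform(0.5, 15)``, or keywords)::

    [genome]
    replicates = 100
    seed = 1
    mu = 2.5e-5            # substitutions per nucleotide site per generation

    [demography]
    N = 1000

    [sampling]
    n = 15

    [region gene1]
    type = codon
    length = 150           # codons
    model = gy94
    omega = 2.0
    kappa = uniform(0.5, 15)
    position_freqs = dirichlet(1, 1, 1, 1)
"""

from __future__ import annotations

import hashlib
import json
import math
import os
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from ._rng import substream
from .coalescent import (
    Demography,
    Genealogy,
    MarginalTreeSet,
    PopulationStructure,
    RecombinationMap,
    SampleConfig,
    simulate_arg,
    simulate_genealogy,
)
from .evolver import RegionAlignment, evolve_along_tree, evolve_region
from .priors import PriorSpec, RegionParams, parse_prior, sample_region_params
from .subst_models import (
    CodonFrequencies,
    RateModel,
    SiteRateProfile,
    build_gtr,
    build_gy94,
    build_mg94,
    draw_site_rates,
    f3x4,
    load_empirical_matrix,
)

__all__ = [
    "ConfigError",
    "RegionSpec",
    "GenomeSpec",
    "GenomeAlignment",
    "parse_config",
    "simulate_genome",
    "run_replicates",
    "write_alignment",
    "read_alignment",
]


class ConfigError(ValueError):
    pass


# ---------------------------------------------------------------------------
# specification types


_MODEL_PARAM_KEYS = {
    "gtr": {"exchangeabilities", "frequencies"},
    "gy94": {"kappa", "omega", "position_freqs", "codon_freqs"},
    "mg94": {"kappa", "omega", "position_freqs"},
    "empirical": {"matrix_file", "frequencies"},
}
_COMMON_PARAM_KEYS = {"gamma_shape", "p_inv"}
_DATA_TYPES = {"nucleotide", "codon", "aminoacid"}


@dataclass
class RegionSpec:
    """Declaration of one genomic region (lengths in alphabet units:
    nucleotides, codons or residues)."""

    label: str
    data_type: str
    length: int
    model: str
    params: dict = field(default_factory=dict)
    recombination_rate: float = 0.0
    hotspots: tuple[tuple[int, int, float], ...] = ()

    def __post_init__(self) -> None:
        if self.data_type not in _DATA_TYPES:
            raise ConfigError(f"region {self.label!r}: unknown type {self.data_type!r}")
        if self.length <= 0:
            raise ConfigError(f"region {self.label!r}: length must be positive")
        if self.model not in _MODEL_PARAM_KEYS:
            raise ConfigError(f"region {self.label!r}: unknown model {self.model!r}")

    @property
    def nt_length(self) -> int:
        return self.length * 3 if self.data_type == "codon" else self.length


@dataclass
class GenomeSpec:
    regions: list[RegionSpec]
    replicates: int = 1
    seed: int = 1
    mu: float = 2.5e-5  # substitutions per nucleotide site per generation
    demography: Demography = field(default_factory=lambda: Demography.constant(1000))
    structure: PopulationStructure | None = None
    sampling: SampleConfig = field(
        default_factory=lambda: SampleConfig.contemporaneous(15)
    )

    def __post_init__(self) -> None:
        labels = [r.label for r in self.regions]
        dupes = {l for l in labels if labels.count(l) > 1}
        if dupes:
            raise ConfigError(f"duplicate region label(s): {sorted(dupes)}")
        if not self.regions:
            raise ConfigError("a genome needs at least one region")
        if self.mu <= 0:
            raise ConfigError("mu must be positive")


@dataclass
class GenomeAlignment:
    """Concatenation of per-region alignments with a nucleotide-coordinate
    region map (0-based half-open; codon regions span length*3)."""

    names: list[str]
    regions: list[RegionAlignment]
    labels: list[str]

    @property
    def coordinate_map(self) -> list[tuple[str, int, int, str]]:
        out = []
        pos = 0
        for lab, aln in zip(self.labels, self.regions):
            nt = aln.length * 3 if aln.data_type == "codon" else aln.length
            out.append((lab, pos, pos + nt, aln.data_type))
            pos += nt
        return out

    @property
    def nt_length(self) -> int:
        return self.coordinate_map[-1][2]

    def sequences(self) -> dict[str, str]:
        return {
            name: "".join(r.sequence(name) for r in self.regions)
            for name in self.names
        }


# ---------------------------------------------------------------------------
# config parsing


def _parse_sections(path: str) -> list[tuple[str, int, list[tuple[str, str, int]]]]:
    """Minimal INI reader keeping line numbers: [(section, lineno, items)]."""
    sections: list[tuple[str, int, list[tuple[str, str, int]]]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if line.startswith("[") and line.endswith("]"):
                sections.append((line[1:-1].strip(), lineno, []))
            elif "=" in line:
                if not sections:
                    raise ConfigError(f"{path}:{lineno}: key outside any section")
                key, val = line.split("=", 1)
                sections[-1][2].append((key.strip().lower(), val.strip(), lineno))
            else:
                raise ConfigError(f"{path}:{lineno}: cannot parse line {line!r}")
    return sections


def _want(items: dict, key: str, default=None):
    return items.get(key, (default, None))[0]


def parse_config(path: str) -> GenomeSpec:
    """Parse and fully validate a genome configuration file."""
    sections = _parse_sections(path)
    by_name: dict[str, tuple[int, dict]] = {}
    regions: list[RegionSpec] = []
    for name, lineno, items in sections:
        d = {}
        for k, v, ln in items:
            if k in d:
                raise ConfigError(f"{path}:{ln}: duplicate key {k!r}")
            d[k] = (v, ln)
        if name.startswith("region"):
            regions.append(_parse_region(path, name, lineno, d))
        else:
            if name in by_name:
                raise ConfigError(f"{path}:{lineno}: duplicate section [{name}]")
            by_name[name] = (lineno, d)

    required = {"genome", "demography", "sampling"}
    missing = required - set(by_name)
    if missing or not regions:
        need = sorted(missing) + ([] if regions else ["at least one [region ...]"])
        raise ConfigError(f"{path}: missing required blocks: {', '.join(need)}")

    def section(name: str, allowed: set[str]) -> dict:
        lineno, d = by_name[name]
        for k, (_v, ln) in d.items():
            if k not in allowed:
                raise ConfigError(f"{path}:{ln}: unknown key {k!r} in [{name}]")
        return d

    g = section("genome", {"replicates", "seed", "mu"})
    dem = section("demography", {"n", "growth_rate"})
    samp = section("sampling", {"n", "groups"})

    try:
        replicates = int(_want(g, "replicates", "1"))
        seed = int(_want(g, "seed", "1"))
        mu = float(_want(g, "mu", "2.5e-5"))
        N = float(_want(dem, "n", "1000"))
        growth = float(_want(dem, "growth_rate", "0"))
    except ValueError as e:
        raise ConfigError(f"{path}: non-numeric global parameter: {e}") from e

    from .coalescent import Epoch

    demography = Demography(
        (Epoch(0.0, math.inf, {"pop": N}, {"pop": growth} if growth else {}),)
    )
    if "groups" in samp:
        groups = []
        for part in samp["groups"][0].split(";"):
            deme, t, c = (x.strip() for x in part.split(","))
            groups.append((deme, float(t), int(c)))
        sampling = SampleConfig(groups=tuple(groups))
    else:
        sampling = SampleConfig.contemporaneous(int(_want(samp, "n", "15")))

    # expand region copies after validation
    expanded: list[RegionSpec] = []
    for r in regions:
        copies = r.params.pop("__copies__", 1)
        if copies == 1:
            expanded.append(r)
        else:
            for i in range(1, copies + 1):
                expanded.append(
                    RegionSpec(
                        label=f"{r.label}_{i}",
                        data_type=r.data_type,
                        length=r.length,
                        model=r.model,
                        params=dict(r.params),
                        recombination_rate=r.recombination_rate,
                        hotspots=r.hotspots,
                    )
                )
    return GenomeSpec(
        regions=expanded,
        replicates=replicates,
        seed=seed,
        mu=mu,
        demography=demography,
        sampling=sampling,
    )


def _parse_region(path: str, header: str, lineno: int, items: dict) -> RegionSpec:
    parts = header.split(None, 1)
    if len(parts) != 2:
        raise ConfigError(f"{path}:{lineno}: region section needs a label: [region NAME]")
    label = parts[1].strip()

    def take(key, default=None):
        if key in items:
            return items.pop(key)[0]
        return default

    data_type = take("type", "nucleotide")
    model = take("model", "gtr")
    try:
        length = int(take("length", "0"))
        copies = int(take("copies", "1"))
        rec_rate = float(take("recombination_rate", "0"))
    except ValueError as e:
        raise ConfigError(f"{path}:{lineno}: region {label!r}: {e}") from e
    hotspots = ()
    if "hotspots" in items:
        hs = []
        for part in items.pop("hotspots")[0].split(";"):
            s, e, m = (x.strip() for x in part.split(","))
            hs.append((int(s), int(e), float(m)))
        hotspots = tuple(hs)

    allowed = _MODEL_PARAM_KEYS.get(model, set()) | _COMMON_PARAM_KEYS
    params: dict = {}
    for k, (v, ln) in items.items():
        if k not in allowed:
            raise ConfigError(
                f"{path}:{ln}: unknown key {k!r} for model {model!r} in region {label!r}"
            )
        params[k] = _parse_value(path, ln, v)
    params["__copies__"] = copies
    try:
        return RegionSpec(
            label=label,
            data_type=data_type,
            length=length,
            model=model,
            params=params,
            recombination_rate=rec_rate,
            hotspots=hotspots,
        )
    except ConfigError as e:
        raise ConfigError(f"{path}:{lineno}: {e}") from e


def _parse_value(path: str, lineno: int, text: str):
    text = text.strip()
    if text == "equal":
        return "equal"
    if "(" in text:
        try:
            return parse_prior(text)
        except Exception as e:
            raise ConfigError(f"{path}:{lineno}: {e}") from e
    toks = text.split()
    try:
        vals = [float(t) for t in toks]
    except ValueError:
        return text  # e.g. a matrix file path
    return vals[0] if len(vals) == 1 else np.asarray(vals)


# ---------------------------------------------------------------------------
# per-replicate simulation


def _build_model(region: RegionSpec, rp: RegionParams) -> tuple[RateModel, str]:
    p = rp.model_params
    if region.model == "gy94" or region.model == "mg94":
        kappa = float(np.asarray(p.get("kappa", 2.0)))
        omega = float(np.asarray(p.get("omega", 1.0)))
        pf = p.get("position_freqs", "equal")
        if region.model == "mg94":
            pfm = np.full((3, 4), 0.25) if isinstance(pf, str) else np.asarray(pf)
            return build_mg94(kappa, omega, pfm), "codon"
        if "codon_freqs" in p:
            freqs = CodonFrequencies.f1x61(np.asarray(p["codon_freqs"]))
        elif isinstance(pf, str) and pf == "equal":
            freqs = CodonFrequencies.equal()
        else:
            freqs = f3x4(np.asarray(pf))
        return build_gy94(kappa, omega, freqs), "codon"
    if region.model == "gtr":
        exch = np.asarray(p.get("exchangeabilities", np.ones(6)))
        fr = p.get("frequencies", "equal")
        pi = np.full(4, 0.25) if isinstance(fr, str) else np.asarray(fr)
        return build_gtr(exch, pi / pi.sum()), "nucleotide"
    if region.model == "empirical":
        mf = p.get("matrix_file")
        if mf is None:
            raise ConfigError(f"region {region.label!r}: empirical model needs matrix_file")
        fr = p.get("frequencies")
        model = load_empirical_matrix(
            str(mf), alphabet=region.data_type, pi=None if fr is None else np.asarray(fr)
        )
        return model, region.data_type
    raise ConfigError(f"unsupported model {region.model!r}")


def _site_rates_for(
    region: RegionSpec, rp: RegionParams, seed: int, replicate: int
) -> SiteRateProfile:
    p = rp.model_params
    alpha = p.get("gamma_shape")
    alpha = None if alpha is None else float(np.asarray(alpha))
    p_inv = float(np.asarray(p.get("p_inv", 0.0)))
    rng = substream(seed, replicate, rp.region_index, "site_rates")
    return draw_site_rates(region.length, alpha, p_inv, rng)


def simulate_genome(
    spec: GenomeSpec, replicate_index: int
) -> tuple[GenomeAlignment, list[RegionParams], list[Genealogy | MarginalTreeSet]]:
    """Simulate one replicate: parameter draws, genealogies, sequences."""
    region_params = sample_region_params(spec.regions, replicate_index, spec.seed)
    alns: list[RegionAlignment] = []
    trees: list[Genealogy | MarginalTreeSet] = []
    for region, rp in zip(spec.regions, region_params):
        model, dtype = _build_model(region, rp)
        if dtype != region.data_type:
            raise ConfigError(
                f"region {region.label!r}: model {region.model!r} produces "
                f"{dtype} data but region is declared {region.data_type!r}"
            )
        site_rates = _site_rates_for(region, rp, spec.seed, replicate_index)
        g_rng = substream(spec.seed, replicate_index, rp.region_index, "genealogy")
        s_rng = substream(spec.seed, replicate_index, rp.region_index, "sequence")
        # per-nucleotide-site substitution rate; codon branch lengths are per
        # codon, i.e. three nucleotide sites
        mu_unit = spec.mu * 3 if dtype == "codon" else spec.mu
        if region.recombination_rate > 0:
            recmap = RecombinationMap(
                rate=region.recombination_rate,
                length=region.nt_length,
                hotspots=region.hotspots,
            )
            mts = simulate_arg(
                spec.sampling,
                spec.demography,
                spec.structure,
                recmap=recmap,
                L=region.nt_length,
                rng=g_rng,
            )
            trees.append(mts)
            aln = evolve_region(
                mts, model, site_rates=site_rates, mu=mu_unit, rng=s_rng, data_type=dtype
            )
        else:
            tree = simulate_genealogy(
                spec.sampling, spec.demography, spec.structure, rng=g_rng
            )
            trees.append(tree)
            aln = evolve_along_tree(
                tree, model, site_rates=site_rates, mu=mu_unit, rng=s_rng, data_type=dtype
            )
        aln.provenance = {"replicate": replicate_index, "region": region.label}
        alns.append(aln)
    genome = GenomeAlignment(
        names=alns[0].names, regions=alns, labels=[r.label for r in spec.regions]
    )
    return genome, region_params, trees


# ---------------------------------------------------------------------------
# writers / readers


def write_alignment(alignment, path: str, fmt: str = "fasta") -> None:
    """Write a RegionAlignment or GenomeAlignment (FASTA or relaxed PHYLIP)."""
    from Bio.Align import MultipleSeqAlignment
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord
    from Bio import AlignIO

    seqs = alignment.sequences()
    if not seqs:
        raise ValueError("cannot write an empty alignment")
    msa = MultipleSeqAlignment(
        [SeqRecord(Seq(s), id=n, description="") for n, s in seqs.items()]
    )
    biofmt = {"fasta": "fasta", "phylip": "phylip-relaxed", "phylip-sequential": "phylip-relaxed"}[fmt]
    AlignIO.write(msa, path, biofmt)


def read_alignment(path: str, fmt: str = "fasta") -> dict[str, str]:
    """Read an alignment back as an ordered name -> sequence mapping."""
    from Bio import AlignIO

    biofmt = {"fasta": "fasta", "phylip": "phylip-relaxed", "phylip-sequential": "phylip-relaxed"}[fmt]
    msa = AlignIO.read(path, biofmt)
    if len(msa) == 0:
        raise ValueError(f"{path}: empty alignment")
    lengths = {len(r.seq) for r in msa}
    if len(lengths) > 1:
        raise ValueError(f"{path}: sequences have unequal lengths {sorted(lengths)}")
    return {r.id: str(r.seq) for r in msa}


def _write_param_log(path: str, all_params: list[list[RegionParams]]) -> None:
    cols: list[str] = []
    rows = []
    for rep, rps in enumerate(all_params):
        for rp in rps:
            items = rp.flat_items()
            for name, _ in items:
                if name not in cols:
                    cols.append(name)
            rows.append((rep, rp.label, dict(items)))
    with open(path, "w") as fh:
        fh.write("replicate\tregion\t" + "\t".join(cols) + "\n")
        for rep, label, d in rows:
            vals = "\t".join(
                (f"{d[c]:.10g}" if isinstance(d[c], float) else str(d[c]))
                if c in d
                else "NA"
                for c in cols
            )
            fh.write(f"{rep}\t{label}\t{vals}\n")


def _write_region_table(path: str, genome: GenomeAlignment) -> None:
    with open(path, "w") as fh:
        fh.write("region\tstart\tend\tdata_type\n")
        for lab, s, e, dt in genome.coordinate_map:
            fh.write(f"{lab}\t{s}\t{e}\t{dt}\n")


def _write_trees(path: str, labels: Sequence[str], trees: Sequence) -> None:
    with open(path, "w") as fh:
        for lab, t in zip(labels, trees):
            if isinstance(t, MarginalTreeSet):
                for (a, b), tree in zip(t.intervals, t.trees):
                    fh.write(f"[{lab} {a} {b}] {tree.newick()}\n")
            else:
                fh.write(f"[{lab}] {t.newick()}\n")


def _sha256(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_replicates(spec: GenomeSpec, out_dir: str, fmt: str = "fasta") -> dict:
    """Run every replicate, write all outputs, return the checksum manifest.

    A failing replicate is recorded in the manifest (with its error) and does
    not affect the others; replicates draw from independent seed substreams,
    so outputs are identical regardless of execution order.
    """
    os.makedirs(out_dir, exist_ok=True)
    manifest: dict = {"seed": spec.seed, "mu": spec.mu, "replicates": [], "files": {}}
    all_params: list[list[RegionParams]] = []
    ext = "fasta" if fmt == "fasta" else "phy"
    first_genome = None
    for rep in range(spec.replicates):
        try:
            genome, rps, trees = simulate_genome(spec, rep)
        except Exception as e:  # isolate per-replicate failures
            manifest["replicates"].append({"index": rep, "status": "failed", "error": str(e)})
            continue
        if first_genome is None:
            first_genome = genome
        aln_path = os.path.join(out_dir, f"genome_{rep:04d}.{ext}")
        write_alignment(genome, aln_path, fmt=fmt)
        tree_path = os.path.join(out_dir, f"trees_{rep:04d}.nwk")
        _write_trees(tree_path, genome.labels, trees)
        all_params.append(rps)
        manifest["replicates"].append({"index": rep, "status": "ok"})
        manifest["files"][os.path.basename(aln_path)] = None
        manifest["files"][os.path.basename(tree_path)] = None

    if first_genome is None:
        raise RuntimeError("all replicates failed")
    _write_param_log(os.path.join(out_dir, "parameters.tsv"), all_params)
    _write_region_table(os.path.join(out_dir, "regions.tsv"), first_genome)
    manifest["files"]["parameters.tsv"] = None
    manifest["files"]["regions.tsv"] = None
    for name in manifest["files"]:
        manifest["files"][name] = _sha256(os.path.join(out_dir, name))
    with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
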