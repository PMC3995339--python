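"""dN/dS estimators: counting oracle, likelihood oracle, recovery, summaries."""

import itertools
import math

import numpy as np
import pytest
from scipy.linalg import expm

from genomesim.coalescent import load_user_tree
from genomesim.dnds import (
    ExperimentSummary,
    _M0Engine,
    empirical_f3x4,
    experiment_spec,
    fit_m0,
    ng86_dnds,
    nj_topology,
)
from genomesim.evolver import RegionAlignment, evolve_along_tree
from genomesim.genome_io import simulate_genome
from genomesim.subst_models import (
    CODON_INDEX,
    CODONS,
    GENETIC_CODE,
    STOP_CODONS,
    CodonFrequencies,
    build_gy94,
)

NUCS = "ACGT"


def codon_alignment(names, seqs):
    codes = np.array(
        [[CODON_INDEX[s[i : i + 3]] for i in range(0, len(s), 3)] for s in seqs]
    )
    return RegionAlignment("codon", list(names), codes, CODONS)


class TestEmpiricalF3x4:
    def test_monomorphic_alignment(self):
        aln = codon_alignment(["a", "b"], ["AAAAAA", "AAAAAA"])
        cf = empirical_f3x4(aln)
        assert cf.codon_freqs[CODON_INDEX["AAA"]] > 0.999

    def test_matches_direct_tally(self, rng):
        m = build_gy94(2.0, 1.0, CodonFrequencies.equal())
        tree = load_user_tree("((a:0.2,b:0.2):0.1,c:0.3);")
        aln = evolve_along_tree(tree, m, L=200, rng=rng)
        cf = empirical_f3x4(aln)
        # independent tally
        counts = np.zeros((3, 4))
        for row in aln.codes:
            for c in row:
                for pos, nt in enumerate(CODONS[c]):
                    counts[pos, NUCS.index(nt)] += 1
        pf = counts / counts.sum(axis=1, keepdims=True)
        assert np.allclose(cf.position_freqs, pf, atol=2e-4)  # floor-level slack

    def test_uniform_alignment_matches_expected_position_freqs(self, rng):
        # codons uniform over the 61 sense codons; the F3x4 projection of that
        # distribution follows the exact per-position nucleotide frequencies
        # (slightly non-uniform because the three stops are all T--)
        from genomesim.subst_models import f3x4

        codes = rng.integers(0, 61, size=(4, 30_000))
        aln = RegionAlignment("codon", list("abcd"), codes, CODONS)
        cf = empirical_f3x4(aln)
        pf = np.zeros((3, 4))
        for c in CODONS:
            for pos, nt in enumerate(c):
                pf[pos, NUCS.index(nt)] += 1 / 61
        expect = f3x4(pf)
        assert np.abs(cf.codon_freqs - expect.codon_freqs).max() < 0.002
        # and each sense codon stays within ~20% of 1/61
        assert np.abs(cf.codon_freqs - 1 / 61).max() < 0.2 / 61 * 5


def hand_site_counts(codon):
    """Hand enumeration of the nine mutational neighbors (oracle)."""
    s = 0.0
    for pos in range(3):
        syn = tot = 0
        for nt in NUCS:
            if nt == codon[pos]:
                continue
            alt = codon[:pos] + nt + codon[pos + 1 :]
            if alt in STOP_CODONS:
                continue
            tot += 1
            syn += GENETIC_CODE[alt] == GENETIC_CODE[codon]
        if tot:
            s += syn / tot
    return s, 3 - s


class TestNG86:
    def test_identical_sequences_flagged_undefined(self):
        r = ng86_dnds("AAATTT", "AAATTT")
        assert r.Sd == r.Nd == 0
        assert r.omega is None and "dS_zero" in r.flags

    def test_lysine_codon_hand_enumeration(self):
        # AAA: pos1 non-stop neighbors CAA,GAA both nonsyn (TAA is a stop);
        # pos2 ACA,AGA,ATA nonsyn; pos3 AAG syn, AAC/AAT nonsyn -> S = 1/3
        s, n = hand_site_counts("AAA")
        assert s == pytest.approx(1 / 3)
        r = ng86_dnds("AAA", "AAG")
        assert (r.S, r.N) == (pytest.approx(s), pytest.approx(n))
        assert (r.Sd, r.Nd) == (1.0, 0.0)
        assert r.dN == 0.0

    def test_single_synonymous_difference_rates(self):
        # ten Lys codons, one synonymous difference: pS = 1/(10/3) = 0.3
        r = ng86_dnds("AAA" * 10, "AAG" + "AAA" * 9)
        pS = r.Sd / r.S
        assert pS == pytest.approx(0.3)
        assert r.dS == pytest.approx(-0.75 * math.log(1 - 4 * pS / 3))
        assert r.dN == 0.0

    def test_saturated_proportion_flagged(self):
        # a single codon with one synonymous difference has pS = 3 >= 3/4
        r = ng86_dnds("AAA", "AAG")
        assert r.dS is None and "saturated" in r.flags and r.omega is None

    def test_pathway_averaging_two_hit_codon(self):
        # TTT (Phe) vs GTA (Val): pathways TTT->GTT->GTA and TTT->TTA->GTA,
        # no stops involved; count syn/nonsyn steps by hand
        steps = []
        for order in itertools.permutations([0, 2]):
            cur = "TTT"
            syn = 0
            for k in order:
                nxt = cur[:k] + "GTA"[k] + cur[k + 1 :]
                syn += GENETIC_CODE[cur] == GENETIC_CODE[nxt]
                cur = nxt
            steps.append(syn)
        expect_sd = np.mean(steps)
        r = ng86_dnds("TTT", "GTA")
        assert r.Sd == pytest.approx(expect_sd)
        assert r.Nd == pytest.approx(2 - expect_sd)

    def test_stop_codon_rejected(self):
        with pytest.raises(ValueError, match="stop"):
            ng86_dnds("TAA", "AAA")

    def test_neutral_recovery(self):
        # long neutral sequences at modest divergence: omega ~ 1
        rng = np.random.default_rng(6)
        m = build_gy94(1.0, 1.0, CodonFrequencies.equal())
        tree = load_user_tree("(a:0.15,b:0.15);")
        oms = []
        for _ in range(10):
            aln = evolve_along_tree(tree, m, L=3000, rng=rng)
            r = ng86_dnds(aln.sequence("a"), aln.sequence("b"))
            oms.append(r.omega)
        assert np.mean(oms) == pytest.approx(1.0, abs=0.1)


class TestM0Likelihood:
    def _small_fit_inputs(self):
        rng = np.random.default_rng(17)
        m = build_gy94(3.0, 0.4, CodonFrequencies.equal())
        tree = load_user_tree("((a:0.2,b:0.3):0.1,(c:0.15,d:0.25):0.05);")
        aln = evolve_along_tree(tree, m, L=20, rng=rng)
        return tree, aln

    def test_engine_matches_independent_pruning(self):
        """Engine lnL vs a from-scratch recursive pruning using scipy expm."""
        tree, aln = self._small_fit_inputs()
        freqs = empirical_f3x4(aln)
        eng = _M0Engine(tree, aln.names, aln.codes, freqs)
        for kappa, omega in [(1.0, 1.0), (3.0, 0.4), (0.5, 2.5)]:
            eng.set_model(kappa, omega)
            got = eng.lnL()
            model = build_gy94(kappa, omega, freqs)
            P = {
                v: expm(model.Q * eng.blens[v])
                for v in range(tree.n_nodes)
                if v != tree.root
            }

            def partial(v, site):
                if not tree.children[v]:
                    e = np.zeros(61)
                    e[aln.codes[aln.names.index(tree.labels[v]), site]] = 1.0
                    return e
                out = np.ones(61)
                for c in tree.children[v]:
                    out = out * (P[c] @ partial(c, site))
                return out

            want = sum(
                math.log(freqs.codon_freqs @ partial(tree.root, s))
                for s in range(aln.length)
            )
            assert got == pytest.approx(want, abs=1e-6)

    def test_optimum_at_least_generating_likelihood(self):
        tree, aln = self._small_fit_inputs()
        fit = fit_m0(aln, topology=tree)
        eng = _M0Engine(tree, aln.names, aln.codes, empirical_f3x4(aln))
        eng.set_model(3.0, 0.4)  # generating parameters, generating tree
        assert fit.lnL >= eng.lnL() - 1e-6

    def test_omega_starts_agree(self):
        tree, aln = self._small_fit_inputs()
        a = fit_m0(aln, topology=tree, omega_starts=(0.5,))
        b = fit_m0(aln, topology=tree, omega_starts=(2.0,))
        assert a.lnL == pytest.approx(b.lnL, abs=0.5)
        assert a.omega == pytest.approx(b.omega, rel=0.1)

    def test_dn_ds_decomposition_consistent_with_omega(self):
        # for GY94 the normalization cancels in the flow ratio, so the
        # decomposed dN/dS must equal the fitted omega exactly
        from genomesim.dnds import dn_ds_from_fit

        tree, aln = self._small_fit_inputs()
        fit = fit_m0(aln, topology=tree)
        dN, dS = dn_ds_from_fit(fit)
        assert dN / dS == pytest.approx(fit.omega, rel=1e-9)
        assert dN >= 0 and dS > 0

    def test_requires_three_sequences(self):
        aln = codon_alignment(["a", "b"], ["AAATTT", "AAATTC"])
        with pytest.raises(ValueError, match="3 sequences"):
            fit_m0(aln)

    def test_recovery_on_homogeneous_region(self):
        spec = experiment_spec(
            "equal-frequencies", 0.5, 1, seed=23, kappa=2.0,
            n_regions=1, codons_per_region=800,
        )
        genome, _, _ = simulate_genome(spec, 0)
        fit = fit_m0(genome)
        assert fit.converged
        assert fit.omega == pytest.approx(0.5, abs=0.12)
        assert fit.kappa == pytest.approx(2.0, rel=0.3)

    def test_consistency_error_shrinks_with_length(self):
        errs = {}
        for L in (150, 1500):
            devs = []
            for rep in range(4):
                spec = experiment_spec(
                    "equal-frequencies", 1.0, 4, seed=31, kappa=2.0,
                    n_regions=1, codons_per_region=L,
                )
                genome, _, _ = simulate_genome(spec, rep)
                devs.append(fit_m0(genome).omega - 1.0)
            errs[L] = float(np.sqrt(np.mean(np.square(devs))))
        assert errs[1500] < errs[150]

    def test_ng86_and_m0_correlate(self):
        rng = np.random.default_rng(41)
        gl, ng = [], []
        for rep in range(6):
            omega = [0.2, 0.5, 1.0, 1.5, 2.0, 3.0][rep]
            m = build_gy94(2.0, omega, CodonFrequencies.equal())
            tree = load_user_tree("((a:0.15,b:0.15):0.05,(c:0.1,d:0.2):0.05);")
            aln = evolve_along_tree(tree, m, L=500, rng=rng)
            gl.append(fit_m0(aln, topology=tree).omega)
            rs = [
                ng86_dnds(aln.sequence(x), aln.sequence(y)).omega
                for x, y in itertools.combinations(aln.names, 2)
            ]
            ng.append(np.mean([r for r in rs if r is not None]))
        assert np.corrcoef(gl, ng)[0, 1] > 0.8


class TestTopology:
    def test_nj_recovers_clear_split(self, rng):
        m = build_gy94(2.0, 1.0, CodonFrequencies.equal())
        tree = load_user_tree("((a:0.02,b:0.02):0.3,(c:0.02,d:0.02):0.3);")
        aln = evolve_along_tree(tree, m, L=400, rng=rng)
        topo = nj_topology(aln)
        # a,b must be adjacent: their path shares no taxon with c,d's side
        newick = topo.newick()
        assert ("a" in newick and "b" in newick)
        parents = {
            topo.labels[v]: topo.parent[v] for v in topo.leaf_indices
        }
        assert parents["a"] == parents["b"] or parents["c"] == parents["d"]


class TestExperimentSummary:
    def test_single_replicate_se_absent(self):
        s = ExperimentSummary(
            scenario="equal-frequencies", omega_true=1.0, replicates=1,
            mu=2.5e-5, global_estimates=[0.97],
        )
        assert s.global_mean == pytest.approx(0.97)
        assert s.global_se is None and s.global_ci is None
        assert "SE undefined" in s.report()

    def test_ci_is_mean_pm_196_se(self):
        vals = [0.9, 1.0, 1.1, 1.05, 0.95]
        s = ExperimentSummary(
            scenario="equal-frequencies", omega_true=1.0, replicates=5,
            mu=2.5e-5, global_estimates=vals,
        )
        lo, hi = s.global_ci
        assert lo == pytest.approx(s.global_mean - 1.96 * s.global_se)
        assert hi == pytest.approx(s.global_mean + 1.96 * s.global_se)
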