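# Heterogeneous-genome design: dN/dS constant at 2.0 across the genome while
# ti/tv and codon frequencies vary region by region. 15 coding regions of 150
# codons, 15 sampled genomes from a constant-size population of N=1000.

[genome]
replicates = 100
seed = 1
mu = 2.5e-5            # substitutions per nucleotide site per generation

[demography]
N = 1000

[sampling]
n = 15

[region gene]
copies = 15
type = codon
length = 150           # codons
model = gy94
omega = 2.0
kappa = uniform(0.5, 15)
position_freqs = dirichlet(1, 1, 1, 1)
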