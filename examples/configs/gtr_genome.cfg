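# A mixed genome: two nucleotide regions under GTR with prior-drawn
# exchangeabilities and gamma rate variation, plus one codon region; one
# nucleotide region recombines with a hotspot.

[genome]
replicates = 2
seed = 7
mu = 2.5e-5

[demography]
N = 1000

[sampling]
n = 8

[region noncoding1]
type = nucleotide
length = 600
model = gtr
exchangeabilities = dirichlet(6, 16, 2, 8, 20, 4)
frequencies = dirichlet(5, 5, 5, 5)
gamma_shape = exponential(2.0) truncate(0.5, 5.0)

[region noncoding2]
type = nucleotide
length = 400
model = gtr
gamma_shape = 0.7
p_inv = 0.1
recombination_rate = 1e-6
hotspots = 100, 150, 10

[region coding]
type = codon
length = 200
model = gy94
omega = 0.3
kappa = 4.0
position_freqs = equal
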