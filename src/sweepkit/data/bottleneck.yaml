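# Bottleneck demography for a derived (European) D. melanogaster population.
#
# PLACEHOLDER VALUES, EXTERNALLY SOURCED: the crash timing, duration and
# severity must be taken from a published demographic fit for the population
# under study (multilocus bottleneck estimates exist for European
# D. melanogaster); edit before drawing scientific conclusions. The shape
# shipped here is a severe transient crash that reproduces the qualitative
# bottleneck signature (positive-D skew, broad variance of S) for testing.
#
# epochs: [start time in 4N0 units, N(t)/N0 ratio], first entry must start
# at 0; inheritance_factor 1 autosomal, 0.75 X-linked.
label: BN
inheritance_factor: 1.0
epochs:
  - [0.0, 1.0]
  - [0.02, 0.002]
  - [0.022, 1.0]
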