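# Example pipeline configuration.
#
# Generate the region files first:  sweepkit synth --outdir wk --seed 11
# Then run:                         sweepkit all --config examples/pipeline.yaml
regions:
  - fasta: wk/regionA.fasta
    gff: wk/regionA.gff3
    outgroup_id: outgroup
    inheritance_factor: 1.0
    rm: 0.063            # per-site population recombination rate, 2N units
    label: regionA
  - fasta: wk/regionB.fasta
    gff: wk/regionB.gff3
    outgroup_id: outgroup
    rm: 0.063
    label: regionB
  - fasta: wk/regionC.fasta
    gff: wk/regionC.gff3
    outgroup_id: outgroup
    inheritance_factor: 0.75   # X-linked
    rm: 0.047
    label: regionC
  - fasta: wk/regionD.fasta
    gff: wk/regionD.gff3
    outgroup_id: outgroup
    inheritance_factor: 0.75
    rm: 0.058
    label: regionD
# bottleneck: path to a demography YAML (see src/sweepkit/data/bottleneck.yaml)
bottleneck: src/sweepkit/data/bottleneck.yaml
reps: 1000        # fixed-S null replicates per test
gof_reps: 200
seed: 1
outdir: results/pipeline
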