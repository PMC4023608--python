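# Fully synthetic end-to-end run: generates the input bundle, calls and
# filters peaks, annotates, overlaps and applies the knockdown filter.
simulate: true
seed: 1
n_shuffles: 5
outdir: results/run
# constants: {}        # PipelineConfig overrides (threshold, windows, ...)
# simulation: {}       # SimulationParams overrides (rates, site counts, ...)
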