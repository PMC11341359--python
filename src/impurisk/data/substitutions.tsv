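# natural-analog substitutions for modified residues: tag<TAB>comma-separated analogs
# heuristic defaults; override with a project-specific table when available
acetyl-K	Q
oxidized-M	M
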