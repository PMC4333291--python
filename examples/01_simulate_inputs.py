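"""Generate a complete synthetic input bundle and show what it contains.

Writes the five input files every other stage consumes (PTM records,
protein lengths, STRING-style edge list, GAF-like GO annotations + OBO-lite
ontology, disease list) into ./example_inputs.
"""

from ptmnet import synthetic

cfg = synthetic.SimulationConfig(seed=42, n_proteins=1000)
paths = synthetic.write_all(cfg, "example_inputs")
for kind, path in paths.items():
    n_lines = sum(1 for _ in open(path))
    print(f"{kind:>8}: {path} ({n_lines} lines)")

# The record count exceeds the consolidated site count because several
# source databases report the same site (duplicate_rate controls this).
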