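"""End-to-end phenotypic profiling of a simulated disease state.

Simulates a four-condition experiment (two control replicates, two
replicates of a distal transport slow-down), runs detection, tracking,
morphology, mining and the displacement filter, assembles the
40-parameter Z-score signatures against the proximal Ctrl-Mock
baseline, and clusters them (Euclidean, average linkage).
"""

import tempfile

from ohp.benchmark import slowdown_experiment

with tempfile.TemporaryDirectory() as work:
    signatures, dendrogram = slowdown_experiment(work, seed=1, movies_per_condition=3)

for sig in signatures:
    distal = [e.z for e in sig.entries
              if e.parameter == "Track Mean Speed" and e.block.endswith("Distal")]
    proximal = [e.z for e in sig.entries
                if e.parameter == "Track Mean Speed" and e.block.endswith("Proximal")]
    n_sig = sum(e.significant() for e in sig.entries)
    print(f"{sig.label:8s}: distal mean-speed z = {min(distal):+6.2f}, "
          f"proximal = {max(proximal, key=abs):+6.2f}, "
          f"|z| >= 5 in {n_sig}/40 parameters")

print("dendrogram:", dendrogram.to_newick())
# The slowdown conditions cross the -5 significance band only at the
# distal readout and pair up in the dendrogram before joining the
# controls: a site-specific trafficking phenotype, cleanly separated.
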