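"""Summarise carbon-source assimilation phenotypes.

Uses the packaged fixtures for the nine clade strains: the 31 non-
hydrophobic substrates partition into universal / unused / variable sets,
and the hydrophobic drop-test matrix yields halo and toxicity calls.
"""

from lipidphys import halo_table, summarize_substrates, toxicity_flags
from lipidphys.reference import (
    hydrophobic_phenotype_matrix, nonhydrophobic_phenotype_matrix,
)

m = nonhydrophobic_phenotype_matrix()
s = summarize_substrates(m, medium="MMB")
print(f"universal ({len(s.universal)}): {', '.join(sorted(s.universal))}")
print(f"unused:   {len(s.unused)} substrates support no strain")
print(f"variable ({len(s.variable)}): {', '.join(sorted(s.variable))}")

h = hydrophobic_phenotype_matrix()
halo = halo_table(h, "tributyrin", "YP")
print(f"tributyrin halo (lipase/esterase secretion): {', '.join(sorted(halo))}")

tox = toxicity_flags(h, ["hexanoic acid"])["hexanoic acid"]
n_toxic = sum(1 for v in tox.values() if v == "toxic")
print(f"hexanoic acid toxic for {n_toxic}/{len(tox)} strains")
# Only glucose, fructose and glycerol feed every strain; the C6 fatty acid
# blocks growth even on rich medium, i.e. it is toxic rather than merely
# unusable as a carbon source.
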