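"""Simulate the four-group CDS panel the downstream analyses run on.

Writes the FASTA and group table under scratch/ (regenerable; everything is
seeded) and prints what was made: four groups emulating fish/bird/reptile/
mammal-like GC3 regimes of a single-gene ortholog set.
"""

import numpy as np

from common import PANEL_N_PER_GROUP, PANEL_SEED, SCRATCH
from cubscan.composition import profile
from cubscan.seqio import write_fasta
from cubscan.synthetic_data import GROUP_RECIPES, generate_regime_panel

panel = generate_regime_panel(n_per_group=PANEL_N_PER_GROUP, seed=PANEL_SEED)

SCRATCH.mkdir(parents=True, exist_ok=True)
write_fasta(panel.sequences, SCRATCH / "panel.fasta")
with open(SCRATCH / "groups.tsv", "wt") as fh:
    fh.write("seq_id\tgroup\n")
    for s in panel.sequences:
        fh.write(f"{s.seq_id}\t{s.group}\n")

print(f"simulated {len(panel.sequences)} CDS "
      f"({PANEL_N_PER_GROUP} per group, seed {PANEL_SEED}) -> {SCRATCH}")
for g, seqs in panel.by_group().items():
    gc3 = np.mean([profile(s).gc3 for s in seqs])
    nt = np.mean([s.length_nt for s in seqs])
    print(f"  {g:13s} target GC3 {GROUP_RECIPES[g][0]:.3f}  "
          f"realized {gc3:.3f}  mean length {nt:.0f} nt")
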