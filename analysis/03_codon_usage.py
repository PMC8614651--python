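"""Codon usage bias per group: ENC observed vs expected and the RSCU
preferred/over-represented codon inventory, split by ending base."""

import pandas as pd

from common import get_metrics, outdir
from cubscan.cub_metrics import count_codons, pool_counts, rscu

ds, metrics, rscu_df = get_metrics()
res = outdir("codon_usage")

metrics.reset_index()[["seq_id", "group", "enc", "enc_exp", "enc_ratio",
                       "gc3"]].to_csv(res / "cub.tsv", sep="\t", index=False,
                                      float_format="%.6g")
rscu_df.reset_index().to_csv(res / "rscu.tsv", sep="\t", index=False,
                             float_format="%.6g")

rows = []
print("pooled per-group RSCU (preferred = RSCU > 1, over = RSCU > 1.6):")
for g, seqs in ds.by_group().items():
    table = rscu(pool_counts(count_codons(s) for s in seqs))
    for codon, value in table.rscu.items():
        rows.append({"group": g, "codon": codon, "rscu": value,
                     "rscu_class": table.rscu_class[codon]})
    preferred = [c for c, v in table.rscu.items() if v > 1.0]
    over = [c for c, v in table.rscu.items() if v > 1.6]
    gc_end = sum(1 for c in preferred if c[2] in "GC")
    print(f"  {g:13s} preferred {len(preferred):2d} "
          f"(G/C-ending {gc_end}, A/T-ending {len(preferred) - gc_end}); "
          f"over-represented: {', '.join(sorted(over)) or 'none'}")
pd.DataFrame(rows).to_csv(res / "rscu_group_pooled.tsv", sep="\t",
                          index=False, float_format="%.6g")
print(f"wrote {res}")
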