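"""Per-sequence composition profiles and the group characteristics table
(mean +- SD of length, GC, positional GC, ENC, GRAVY, aromaticity)."""

import pandas as pd

from common import get_metrics, outdir
from cubscan.composition import SUMMARY_METRICS, summarize_group

ds, metrics, _ = get_metrics()
res = outdir("composition")

metrics.reset_index().to_csv(res / "composition.tsv", sep="\t", index=False,
                             float_format="%.6g")

rows = []
for g in sorted(ds.groups):
    summ = summarize_group(metrics[metrics.group == g], g)
    row = {"group": g, "n": summ.n}
    for m in SUMMARY_METRICS:
        row[f"{m}_mean"] = summ.mean[m]
        row[f"{m}_sd"] = summ.sd[m]
    rows.append(row)
table = pd.DataFrame(rows)
table.to_csv(res / "group_summary.tsv", sep="\t", index=False,
             float_format="%.6g")

print("group characteristics (mean +- SD):")
for _, r in table.iterrows():
    print(f"  {r.group:13s} GC% {r.gc_pct_mean:5.1f}+-{r.gc_pct_sd:4.2f}  "
          f"P3 {r.p3_mean:5.1f}+-{r.p3_sd:4.2f}  "
          f"ENC {r.enc_mean:5.2f}+-{r.enc_sd:4.2f}  "
          f"GRAVY {r.gravy_mean:6.3f}")
print(f"wrote {res / 'group_summary.tsv'}")
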