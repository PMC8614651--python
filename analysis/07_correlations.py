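"""Correlation battery per group: overall vs third-position base content,
ENC vs positional GC (Spearman throughout), and the RSCU-vs-GC3 heatmap."""

import pandas as pd

from common import get_metrics, outdir
from cubscan import stats

ds, metrics, rscu_df = get_metrics()
res = outdir("correlations")

matrices = {
    "overall_vs_third": stats.OVERALL_VS_THIRD_PAIRS,
    "enc_vs_position": stats.ENC_VS_POSITION_PAIRS,
    "gc_vs_position": stats.GC_VS_POSITION_PAIRS,
}
print("Spearman ENC vs P3 per group:")
for g in sorted(ds.groups):
    gm = metrics[metrics.group == g]
    for name, pairs in matrices.items():
        tab = stats.correlation_matrix(gm, pairs, "spearman")
        tab.to_csv(res / f"{g}_{name}.tsv", sep="\t", index=False,
                   float_format="%.6g")
    cell = stats.spearman(gm.enc, gm.p3)
    print(f"  {g:13s} r = {cell.r:6.3f}  ({cell.significance})")

heat_frames = []
for g in sorted(ds.groups):
    sub = rscu_df[rscu_df.group == g]
    hm = stats.rscu_gc3_heatmap(sub.drop(columns="group"),
                                metrics.loc[sub.index, "gc3"]).reset_index()
    hm.insert(0, "group", g)
    heat_frames.append(hm)
heat = pd.concat(heat_frames, ignore_index=True)
heat.to_csv(res / "rscu_gc3_heatmap.tsv", sep="\t", index=False,
            float_format="%.6g")

sig = heat[heat.significance.isin(["p<0.05", "p<0.01"])]
gc_pos = ((sig.codon.str[2].isin(list("GC"))) & (sig.r > 0)).sum()
at_neg = ((sig.codon.str[2].isin(list("AT"))) & (sig.r < 0)).sum()
print(f"heatmap: {len(sig)} significant codon-GC3 correlations; "
      f"{gc_pos} are G/C-ending positive and {at_neg} A/T-ending negative")
print(f"wrote {res}")
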