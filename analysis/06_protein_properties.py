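"""Protein-level view: amino-acid usage per group (which residues dominate),
GRAVY and aromaticity."""

from common import get_metrics, outdir

ds, metrics, _ = get_metrics()
res = outdir("protein")

metrics.reset_index()[["seq_id", "group", "gravy", "aromaticity"]].to_csv(
    res / "protein.tsv", sep="\t", index=False, float_format="%.6g")

aa_cols = [c for c in metrics.columns if c.startswith("aa_")]
usage = metrics.groupby("group")[aa_cols].mean()
usage.reset_index().to_csv(res / "aa_usage.tsv", sep="\t", index=False,
                           float_format="%.6g")

print("per-group protein properties:")
for g, row in usage.iterrows():
    top = row.sort_values(ascending=False).head(3)
    top_str = ", ".join(f"{aa.removeprefix('aa_')}={v:.3f}"
                        for aa, v in top.items())
    gm = metrics[metrics.group == g]
    print(f"  {g:13s} top residues: {top_str}  "
          f"GRAVY {gm.gravy.mean():.3f}  aromaticity "
          f"{gm.aromaticity.mean():.3f}")
print(f"wrote {res}")
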