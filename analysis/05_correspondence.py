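"""Correspondence analysis of the RSCU table, one ordination per group:
how much codon-usage variation the first two axes carry."""

import pandas as pd

from common import get_metrics, outdir
from cubscan.coa import correspondence_analysis, project_groups

ds, metrics, rscu_df = get_metrics()
res = outdir("coa")

inertia_rows, row_frames = [], []
print("per-group CA of the 59-codon RSCU matrix:")
for g in sorted(ds.groups):
    sub = rscu_df[rscu_df.group == g].drop(columns="group")
    result = correspondence_analysis(sub)
    f1, f2 = result.inertias[0], (result.inertias[1]
                                  if len(result.inertias) > 1 else 0.0)
    inertia_rows.extend(
        {"group": g, "axis": f"f{i + 1}", "singular_value": sv,
         "inertia_fraction": frac, "total_inertia": result.total_inertia}
        for i, (sv, frac) in enumerate(zip(result.singular_values,
                                           result.inertias)))
    rc = result.row_coords.reset_index()
    rc.insert(0, "group", g)
    row_frames.append(rc)
    print(f"  {g:13s} total inertia {result.total_inertia:.4f}  "
          f"f1 {100 * f1:.1f}%  f2 {100 * f2:.1f}%")

pd.DataFrame(inertia_rows).to_csv(res / "coa_inertia.tsv", sep="\t",
                                  index=False, float_format="%.6g")
pd.concat(row_frames, ignore_index=True).to_csv(
    res / "coa_rows.tsv", sep="\t", index=False, float_format="%.6g")

# joint ordination with group centroids for cross-group comparison
joint = correspondence_analysis(rscu_df.drop(columns="group"))
centroids = project_groups(joint, rscu_df.group)
centroids.rename_axis("group").reset_index().to_csv(
    res / "coa_joint_centroids.tsv", sep="\t", index=False,
    float_format="%.6g")
print("joint-CA group centroids on f1:",
      ", ".join(f"{g}={v:.3f}" for g, v in centroids.f1.items()))
print(f"wrote {res}")
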