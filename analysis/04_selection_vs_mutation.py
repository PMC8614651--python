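"""Evolutionary-force diagnostics: PR2 bias, neutrality regression per
group, and the distribution of the (ENCexp - ENCobs)/ENCexp ratio."""

import pandas as pd

from common import get_metrics, outdir
from cubscan.force_analysis import enc_ratio_histogram, neutrality_fit

ds, metrics, _ = get_metrics()
res = outdir("forces")

metrics.reset_index()[["seq_id", "group", "pr2_at_bias", "pr2_gc_bias"]] \
    .to_csv(res / "pr2.tsv", sep="\t", index=False, float_format="%.6g")

rows = []
print("neutrality regressions (P12 on P3) per group:")
for g in sorted(ds.groups):
    gm = metrics[metrics.group == g]
    fit = neutrality_fit(list(zip(gm.p3, gm.p12)))
    rows.append({"group": g, "slope": fit.slope, "intercept": fit.intercept,
                 "r": fit.r, "p_value": fit.p_value, "n": fit.n})
    verdict = ("mutation pressure dominant" if fit.slope > 0.5
               else "selection constrains P12")
    print(f"  {g:13s} slope {fit.slope:6.3f}  r {fit.r:6.3f}  -> {verdict}")
pd.DataFrame(rows).to_csv(res / "neutrality.tsv", sep="\t", index=False,
                          float_format="%.6g")

hist = enc_ratio_histogram(metrics.enc_ratio, bin_width=0.05)
pd.DataFrame({"bin_left": hist.bin_edges[:-1], "bin_right": hist.bin_edges[1:],
              "count": hist.bin_counts}).to_csv(
    res / "enc_ratio_hist.tsv", sep="\t", index=False, float_format="%.6g")
share_near_zero = sum(c for left, c in zip(hist.bin_edges, hist.bin_counts)
                      if -0.05 <= left < 0.10) / hist.n
print(f"ENC ratio: {100 * share_near_zero:.0f}% of sequences within "
      f"[-0.05, 0.10) of the mutation-pressure expectation")
print(f"wrote {res}")
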