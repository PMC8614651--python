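"""End-to-end pipeline: load -> validate -> per-sequence metrics -> per-group
analyses -> TSV reports plus a checksummed run manifest.

All tables are TSV (UTF-8, '.' decimal, floats at 6 significant digits)
with fixed column order, so two runs on the same inputs produce identical
manifests.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, asdict, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import coa, composition, cub_metrics, force_analysis, protein_props, stats
from .genetic_code import SYNONYMOUS_CODONS
from .seqio import GroupedDataset, load_dataset, write_rejections

logger = logging.getLogger("cubscan")

_FLOAT_FMT = "%.6g"


@dataclass
class RunConfig:
    fasta: str
    groups: str
    outdir: str
    correlation_method: str = "spearman"     # spearman | pearson
    pr2_mode: str = "all_codons"             # all_codons | fourfold_only
    coa_input: str = "rscu"                  # rscu | counts
    coa_scope: str = "per_group"             # per_group | joint
    enc_ratio_bin_width: float = 0.05
    seed: int = 0
    make_plots: bool = False

    _CHOICES = {
        "correlation_method": ("spearman", "pearson"),
        "pr2_mode": ("all_codons", "fourfold_only"),
        "coa_input": ("rscu", "counts"),
        "coa_scope": ("per_group", "joint"),
    }

    def validate(self) -> None:
        for name, choices in self._CHOICES.items():
            if getattr(self, name) not in choices:
                raise ValueError(f"{name} must be one of {choices}, "
                                 f"got {getattr(self, name)!r}")
        if self.enc_ratio_bin_width <= 0:
            raise ValueError("enc_ratio_bin_width must be positive")


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format=_FLOAT_FMT)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def per_sequence_metrics(ds: GroupedDataset) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Compute the per-sequence metrics table and the sequences x 59-codon
    RSCU matrix for a validated dataset."""
    rows, rscu_rows = [], []
    for s in ds.sequences:
        prof = composition.profile(s)
        counts = cub_metrics.count_codons(s)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            enc = cub_metrics.enc_observed(counts)
        enc_exp = cub_metrics.enc_expected(prof.gc3)
        rscu_t = cub_metrics.rscu(counts)
        prot = protein_props.profile_cds(s)
        pr2 = force_analysis.pr2_point(prof)
        row = {"seq_id": s.seq_id, "group": s.group, "length_nt": s.length_nt}
        row.update(prof.as_dict())
        row.update({
            "enc": enc, "enc_exp": enc_exp,
            "enc_ratio": cub_metrics.enc_ratio(enc, enc_exp),
            "pr2_at_bias": pr2.at_bias, "pr2_gc_bias": pr2.gc_bias,
            "gravy": prot.gravy, "aromaticity": prot.aromaticity,
        })
        row.update({f"aa_{aa}": f for aa, f in prot.aa_freq.items()})
        rows.append(row)
        rscu_rows.append({"seq_id": s.seq_id, "group": s.group,
                          **rscu_t.rscu})
    metrics = pd.DataFrame(rows).set_index("seq_id")
    rscu_df = pd.DataFrame(rscu_rows).set_index("seq_id")
    return metrics, rscu_df


_COMPOSITION_COLS = ["group", "length_nt", "a_pct", "t_pct", "g_pct", "c_pct",
                     "gc_pct", "p1", "p2", "p3", "p12",
                     "a3", "t3", "g3", "c3", "gc3"]


def run_pipeline(config: RunConfig) -> dict:
    """Run the full analysis; returns the manifest (also written to disk)."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "correlations").mkdir(exist_ok=True)

    log_path = outdir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)

    try:
        ds = load_dataset(config.fasta, config.groups)
        for g, seqs in ds.by_group().items():
            logger.info("group %s: %d accepted", g, len(seqs))
        logger.info("rejected: %d", len(ds.rejected))
        write_rejections(ds, outdir / "rejected.tsv")

        metrics, rscu_df = per_sequence_metrics(ds)
        _write_tsv(metrics[_COMPOSITION_COLS].reset_index(),
                   outdir / "composition.tsv")
        _write_tsv(metrics.reset_index()[
            ["seq_id", "group", "enc", "enc_exp", "enc_ratio", "gc3"]],
            outdir / "cub.tsv")
        _write_tsv(rscu_df.reset_index(), outdir / "rscu.tsv")

        # group characteristics (mean +- SD table)
        summaries = []
        for g in sorted(ds.groups):
            gm = metrics[metrics.group == g]
            summ = composition.summarize_group(gm, g)
            row = {"group": g, "n": summ.n}
            for m in composition.SUMMARY_METRICS:
                if m in summ.mean:
                    row[f"{m}_mean"] = summ.mean[m]
                    row[f"{m}_sd"] = summ.sd[m]
            summaries.append(row)
        _write_tsv(pd.DataFrame(summaries), outdir / "group_summary.tsv")

        # per-group codon classification: group-mean RSCU + majority class
        class_rows = []
        for g in sorted(ds.groups):
            sub = rscu_df[rscu_df.group == g]
            for codon in SYNONYMOUS_CODONS:
                vals = sub[codon].astype(float)
                classes = vals.map(cub_metrics.classify_rscu)
                class_rows.append({
                    "group": g, "codon": codon,
                    "mean_rscu": float(vals.mean()),
                    "majority_class": classes.mode().iloc[0],
                })
        _write_tsv(pd.DataFrame(class_rows), outdir / "rscu_class.tsv")

        # PR2
        if config.pr2_mode == "fourfold_only":
            pr2_pts = [force_analysis.pr2_point_fourfold(s)
                       for s in ds.sequences]
            pr2_df = pd.DataFrame({
                "seq_id": [s.seq_id for s in ds.sequences],
                "group": [s.group for s in ds.sequences],
                "at_bias": [p.at_bias for p in pr2_pts],
                "gc_bias": [p.gc_bias for p in pr2_pts],
            })
        else:
            pr2_df = metrics.reset_index()[
                ["seq_id", "group", "pr2_at_bias", "pr2_gc_bias"]].rename(
                columns={"pr2_at_bias": "at_bias", "pr2_gc_bias": "gc_bias"})
        _write_tsv(pr2_df, outdir / "pr2.tsv")

        # neutrality regression per group
        neut_rows = []
        for g in sorted(ds.groups):
            gm = metrics[metrics.group == g]
            if len(gm) < 3 or np.ptp(gm.p3.values) == 0:
                logger.warning("group %s: neutrality fit skipped", g)
                continue
            fit = force_analysis.neutrality_fit(
                list(zip(gm.p3, gm.p12)))
            neut_rows.append({"group": g, "slope": fit.slope,
                              "intercept": fit.intercept, "r": fit.r,
                              "p_value": fit.p_value, "n": fit.n})
        _write_tsv(pd.DataFrame(neut_rows), outdir / "neutrality.tsv")

        # ENC ratio histogram (pooled over all sequences)
        hist = force_analysis.enc_ratio_histogram(
            metrics.enc_ratio.dropna(), config.enc_ratio_bin_width)
        hist_df = pd.DataFrame({
            "bin_left": hist.bin_edges[:-1],
            "bin_right": hist.bin_edges[1:],
            "count": hist.bin_counts,
        })
        _write_tsv(hist_df, outdir / "enc_ratio_hist.tsv")

        # correspondence analysis
        ca_input = rscu_df if config.coa_input == "rscu" else None
        if config.coa_input == "counts":
            count_rows = []
            for s in ds.sequences:
                t = cub_metrics.count_codons(s)
                count_rows.append({"seq_id": s.seq_id, "group": s.group,
                                   **{c: t.counts.get(c, 0)
                                      for c in SYNONYMOUS_CODONS}})
            ca_input = pd.DataFrame(count_rows).set_index("seq_id")
        scopes = ([("joint", ca_input)] if config.coa_scope == "joint"
                  else [(g, ca_input[ca_input.group == g])
                        for g in sorted(ds.groups)])
        row_frames, col_frames, inertia_frames = [], [], []
        for scope, sub in scopes:
            table = sub.drop(columns="group")
            if len(table) < 2:
                logger.warning("CA scope %s skipped: <2 rows", scope)
                continue
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = coa.correspondence_analysis(table)
            rc = res.row_coords.reset_index()
            rc.insert(0, "scope", scope)
            row_frames.append(rc)
            cc = res.col_coords.reset_index().rename(columns={"index": "codon"})
            cc.insert(0, "scope", scope)
            col_frames.append(cc)
            inertia_frames.append(pd.DataFrame({
                "scope": scope,
                "axis": [f"f{i+1}" for i in range(len(res.inertias))],
                "singular_value": res.singular_values,
                "inertia_fraction": res.inertias,
                "total_inertia": res.total_inertia,
            }))
        for frames, name in ((row_frames, "coa_rows.tsv"),
                             (col_frames, "coa_cols.tsv"),
                             (inertia_frames, "coa_inertia.tsv")):
            _write_tsv(pd.concat(frames, ignore_index=True)
                       if frames else pd.DataFrame(), outdir / name)

        # protein properties
        _write_tsv(metrics.reset_index()[
            ["seq_id", "group", "gravy", "aromaticity"]],
            outdir / "protein.tsv")
        aa_cols = [c for c in metrics.columns if c.startswith("aa_")]
        aa_usage = metrics.groupby("group")[aa_cols].mean().reset_index()
        _write_tsv(aa_usage, outdir / "aa_usage.tsv")

        # correlation battery
        matrices = {
            "overall_vs_third": stats.OVERALL_VS_THIRD_PAIRS,
            "enc_vs_position": stats.ENC_VS_POSITION_PAIRS,
            "gc_vs_position": stats.GC_VS_POSITION_PAIRS,
        }
        for g in sorted(ds.groups):
            gm = metrics[metrics.group == g]
            if len(gm) < 3:
                logger.warning("group %s: correlations skipped (n<3)", g)
                continue
            for name, pairs in matrices.items():
                tab = stats.correlation_matrix(gm, pairs,
                                               config.correlation_method)
                _write_tsv(tab, outdir / "correlations" / f"{g}_{name}.tsv")

        # RSCU vs GC3 heatmap (per group, long format)
        heat_frames = []
        for g in sorted(ds.groups):
            sub = rscu_df[rscu_df.group == g]
            if len(sub) < 3:
                continue
            hm = stats.rscu_gc3_heatmap(
                sub.drop(columns="group"),
                metrics.loc[sub.index, "gc3"],
                config.correlation_method)
            hm = hm.reset_index()
            hm.insert(0, "group", g)
            heat_frames.append(hm)
        _write_tsv(pd.concat(heat_frames, ignore_index=True)
                   if heat_frames else pd.DataFrame(),
                   outdir / "rscu_gc3_heatmap.tsv")

        if config.make_plots:
            _make_plots(metrics, hist, outdir)

        manifest = {
            "config": asdict(config),
            "n_accepted": len(ds.sequences),
            "n_rejected": len(ds.rejected),
            "groups": sorted(ds.groups),
            "outputs": {},
        }
        for p in sorted(outdir.rglob("*.tsv")):
            manifest["outputs"][str(p.relative_to(outdir))] = _sha256(p)
        (outdir / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True))
        logger.info("wrote %d output tables", len(manifest["outputs"]))
        return manifest
    finally:
        logger.removeHandler(handler)
        handler.close()


def _make_plots(metrics: pd.DataFrame, hist, outdir: Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots()
    widths = np.diff(hist.bin_edges)
    ax.bar(hist.bin_edges[:-1], hist.bin_counts, width=widths, align="edge",
           edgecolor="black")
    ax.set_xlabel("(ENCexp - ENCobs) / ENCexp")
    ax.set_ylabel("frequency")
    fig.savefig(outdir / "enc_ratio_hist.png", dpi=120)
    plt.close(fig)

    fig, ax = plt.subplots()
    for g, gm in metrics.groupby("group"):
        ax.scatter(gm.pr2_gc_bias, gm.pr2_at_bias, label=g, s=14)
    ax.axhline(0.5, ls="--", c="grey")
    ax.axvline(0.5, ls="--", c="grey")
    ax.set_xlabel("G3/(G3+C3)")
    ax.set_ylabel("A3/(A3+T3)")
    ax.legend()
    fig.savefig(outdir / "pr2.png", dpi=120)
    plt.close(fig)

    fig, ax = plt.subplots()
    for g, gm in metrics.groupby("group"):
        ax.scatter(gm.p3, gm.p12, label=g, s=14)
    ax.set_xlabel("P3")
    ax.set_ylabel("P12")
    ax.legend()
    fig.savefig(outdir / "neutrality.png", dpi=120)
    plt.close(fig)
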