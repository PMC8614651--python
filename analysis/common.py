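"""Shared plumbing for the analysis drivers: locate the simulated panel
(written by 01_simulate.py) or regenerate it deterministically, and compute
the per-sequence metrics table once per script."""

from pathlib import Path

from cubscan.pipeline import per_sequence_metrics
from cubscan.seqio import load_dataset
from cubscan.synthetic_data import generate_regime_panel

ROOT = Path(__file__).resolve().parent.parent
SCRATCH = ROOT / "scratch" / "panel"
RESULTS = ROOT / "results"

PANEL_N_PER_GROUP = 20
PANEL_SEED = 1


def get_panel():
    fasta = SCRATCH / "panel.fasta"
    groups = SCRATCH / "groups.tsv"
    if fasta.exists() and groups.exists():
        return load_dataset(fasta, groups)
    return generate_regime_panel(n_per_group=PANEL_N_PER_GROUP,
                                 seed=PANEL_SEED)


def get_metrics():
    ds = get_panel()
    metrics, rscu_df = per_sequence_metrics(ds)
    return ds, metrics, rscu_df


def outdir(name: str) -> Path:
    d = RESULTS / name
    d.mkdir(parents=True, exist_ok=True)
    return d
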