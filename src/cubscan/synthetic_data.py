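"""Synthetic CDS generator with controllable codon-usage structure.

The generator emulates the statistical shape of a vertebrate single-gene
ortholog set (a FoxP2-like gene family): CDS of roughly 2,100-2,300 nt, ATG
start, single terminal stop, no ambiguous bases, amino-acid usage enriched
in Leu/Gln/Ser, and group-specific GC3 regimes (a GC3-high fish-like group
around 0.63; bird/reptile/mammal-like groups around 0.43-0.49).

Within-family codon choice combines three seeded components:

* a global third-position GC tilt ``beta`` solved numerically so the
  expected GC3 of each sequence hits its target exactly;
* a per-family tilt correlated with amino-acid usage (abundant residues
  lean GC-ward, scarce ones AT-ward), emulating translational selection
  acting hardest on high-usage families — this is what makes preferred
  codons heterogeneous in their ending base, as real single-gene data are;
* codon-level preference noise scaled by ``bias_strength`` (0 = uniform
  synonymous usage, large = one codon per family).

Six-fold families (Leu/Ser/Arg) are split into their natural sub-blocks
(TTR/CTN, TCN/AGY, CGN/AGR) whose relative use is independent of the GC3
tilt, so first/second-position composition (P12) is decoupled from GC3.
The *selection* regime therefore holds P12 constant in expectation while
GC3 varies (neutrality slope near 0); the *mutation* regime mixes the
amino-acid weights toward GC12-rich or GC12-poor residues so that expected
P12 tracks the per-sequence GC3 target (slope near 1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import brentq
from scipy.special import ndtri

from .genetic_code import (
    AA_TO_CODONS,
    AMINO_ACIDS,
    FAMILY_SIZE,
    SENSE_CODONS,
    STOP_CODONS,
)
from .seqio import CodingSequence, GroupedDataset, validate_cds

#: Sub-blocks of the six-fold families; every other family is one block.
_BLOCKS: dict[str, tuple[tuple[str, ...], ...]] = {}
for _aa, _fam in AA_TO_CODONS.items():
    if _aa == "L":
        _BLOCKS[_aa] = (("TTA", "TTG"), ("CTA", "CTC", "CTG", "CTT"))
    elif _aa == "S":
        _BLOCKS[_aa] = (("AGC", "AGT"), ("TCA", "TCC", "TCG", "TCT"))
    elif _aa == "R":
        _BLOCKS[_aa] = (("AGA", "AGG"), ("CGA", "CGC", "CGG", "CGT"))
    else:
        _BLOCKS[_aa] = (_fam,)

#: Default amino-acid usage, enriched in Leu/Gln/Ser like a FoxP2 protein.
DEFAULT_AA_WEIGHTS: dict[str, float] = {
    "L": 0.100, "Q": 0.095, "S": 0.095,
    "A": 0.065, "E": 0.065, "T": 0.060, "V": 0.060,
    "G": 0.050, "K": 0.050, "P": 0.050,
    "N": 0.045, "R": 0.045, "D": 0.050, "I": 0.040,
    "F": 0.030, "Y": 0.030, "H": 0.025, "M": 0.020,
    "C": 0.015, "W": 0.010,
}
assert abs(sum(DEFAULT_AA_WEIGHTS.values()) - 1.0) < 1e-9

#: Residues whose first+second codon positions are all-GC / all-AT; mixing
#: toward them moves P12 up / down without touching third-position freedom.
_GC12_RICH = ("A", "P", "G")
_GC12_POOR = ("K", "N", "I", "F", "Y")


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs of one synthetic dataset (one group).

    gc3_target: scalar target, (lo, hi) uniform range, or None for no
    steering; gc3_sd spreads a scalar target per sequence (normal, clipped).
    length_codons counts sense codons including the initial Met; a terminal
    stop is appended on top.  bias_strength scales all within-family
    preference components; aa_usage_tilt and family_tilt_sd shape the
    per-family tilt described in the module docstring (both act relative to
    bias_strength, so bias_strength = 0 means uniform synonymous usage).
    """

    n_sequences: int = 20
    length_codons: int = 710
    length_sd_codons: float = 15.0
    gc3_target: float | tuple[float, float] | None = 0.50
    gc3_sd: float = 0.0
    regime: str = "selection"            # "selection" | "mutation"
    bias_strength: float = 0.45
    aa_usage_tilt: float = 0.6
    family_tilt_sd: float = 0.55
    aa_weights: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_AA_WEIGHTS))
    group_label: str = "synthetic"
    seed: int = 0

    def __post_init__(self):
        if self.regime not in ("selection", "mutation"):
            raise ValueError(f"unknown regime {self.regime!r}")
        total = sum(self.aa_weights.values())
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ValueError(f"aa_weights must sum to 1, got {total}")
        if isinstance(self.gc3_target, (int, float)):
            if not 0.0 < float(self.gc3_target) < 1.0:
                raise ValueError("gc3_target must lie strictly inside (0, 1)")


# --------------------------------------------------------------------------
# per-dataset randomized codon-preference parameters

class _DatasetParams:
    """Seeded per-dataset draws shared by every sequence of the dataset."""

    def __init__(self, cfg: GeneratorConfig, rng: np.random.Generator):
        b = cfg.bias_strength
        self.codon_z = {c: b * rng.normal() for c in SENSE_CODONS}
        self.block_z = {
            (aa, i): b * rng.normal()
            for aa in AMINO_ACIDS for i in range(len(_BLOCKS[aa]))
        }
        logw = {aa: math.log(max(cfg.aa_weights.get(aa, 0.0), 1e-6))
                for aa in AMINO_ACIDS}
        mean_logw = float(np.mean(list(logw.values())))
        self.family_delta = {
            aa: b * (cfg.aa_usage_tilt * (logw[aa] - mean_logw)
                     + cfg.family_tilt_sd * rng.normal())
            for aa in AMINO_ACIDS
        }

    def block_probs(self, aa: str) -> np.ndarray:
        blocks = _BLOCKS[aa]
        logits = np.array([
            math.log(len(blk)) + self.block_z[(aa, i)]
            for i, blk in enumerate(blocks)
        ])
        logits -= logits.max()
        w = np.exp(logits)
        return w / w.sum()

    def codon_dist(self, aa: str, beta: float) -> dict[str, float]:
        """P(codon | aa) under GC3 tilt beta + this dataset's preferences."""
        out: dict[str, float] = {}
        bp = self.block_probs(aa)
        tilt = beta + self.family_delta[aa]
        for p_blk, blk in zip(bp, _BLOCKS[aa]):
            logits = np.array([
                self.codon_z[c] + tilt * (1.0 if c[2] in "GC" else 0.0)
                for c in blk
            ])
            logits -= logits.max()
            w = np.exp(logits)
            w /= w.sum()
            for c, p in zip(blk, w):
                out[c] = p_blk * p
        return out

    def expected_gc3(self, aa_weights: dict[str, float], beta: float) -> float:
        total = 0.0
        for aa, w in aa_weights.items():
            dist = self.codon_dist(aa, beta)
            total += w * sum(p for c, p in dist.items() if c[2] in "GC")
        return total

    def expected_p12(self, aa_weights: dict[str, float]) -> float:
        # block identity fixes positions 1-2, so P12 is beta-free
        total = 0.0
        for aa, w in aa_weights.items():
            bp = self.block_probs(aa)
            for p_blk, blk in zip(bp, _BLOCKS[aa]):
                gc12 = sum(base in "GC" for base in blk[0][:2]) / 2.0
                total += w * p_blk * gc12
        return total


_BETA_MAX = 20.0


def _solve_beta(params: _DatasetParams, aa_weights: dict[str, float],
                target: float) -> float:
    lo = params.expected_gc3(aa_weights, -_BETA_MAX)
    hi = params.expected_gc3(aa_weights, _BETA_MAX)
    if not lo < target < hi:
        raise ValueError(
            f"gc3_target {target:.3f} infeasible for these amino-acid "
            f"weights: achievable GC3 range is ({lo:.3f}, {hi:.3f}) "
            "(fixed-third-base residues such as Met/Trp bound it)")
    return brentq(lambda b: params.expected_gc3(aa_weights, b) - target,
                  -_BETA_MAX, _BETA_MAX, xtol=1e-10)


def _mix_aa_weights(base: dict[str, float], p12_base: float,
                    target_p12: float) -> dict[str, float]:
    """Linear mix of the base amino-acid weights toward an all-GC12 or
    all-AT12 residue set so the expected P12 equals target_p12."""
    if target_p12 >= p12_base:
        shift_set, p12_shift = _GC12_RICH, 1.0
    else:
        shift_set, p12_shift = _GC12_POOR, 0.0
    lam = (target_p12 - p12_base) / (p12_shift - p12_base)
    lam = min(lam, 0.95)
    shift = {aa: 1.0 / len(shift_set) for aa in shift_set}
    return {aa: (1.0 - lam) * base.get(aa, 0.0) + lam * shift.get(aa, 0.0)
            for aa in AMINO_ACIDS}


# --------------------------------------------------------------------------

def _draw_targets(cfg: GeneratorConfig, rng: np.random.Generator) -> np.ndarray:
    """Per-sequence GC3 targets; NaN means unsteered (beta = 0)."""
    n = cfg.n_sequences
    if cfg.gc3_target is None:
        return np.full(n, np.nan)
    if isinstance(cfg.gc3_target, tuple):
        lo, hi = cfg.gc3_target
        return rng.uniform(lo, hi, size=n)
    t = float(cfg.gc3_target)
    if cfg.gc3_sd > 0:
        # stratified normal draws: same marginal spread, but the sample
        # mean stays pinned to the target even at modest n
        q = (np.arange(n) + rng.uniform(size=n)) / n
        draws = t + cfg.gc3_sd * ndtri(q)
        return np.clip(rng.permutation(draws), 0.05, 0.95)
    # both regimes are defined by GC3 varying between genes; a scalar target
    # without an explicit spread gets a +-0.15 uniform band around it
    return rng.uniform(max(t - 0.15, 0.05), min(t + 0.15, 0.95), size=n)


def _balanced_counts(n: int, probs: np.ndarray,
                     rng: np.random.Generator) -> np.ndarray:
    """Allocate n draws to categories close to n * probs: deterministic
    floors plus a weighted draw of the leftover units.  This keeps realized
    within-family codon (and hence GC3) composition tight around its
    expectation at gene-sized n."""
    exact = n * probs
    base = np.floor(exact).astype(int)
    frac = exact - base
    rem = n - int(base.sum())
    if rem > 0:
        p = frac / frac.sum()
        idx = rng.choice(len(probs), size=rem, replace=False, p=p)
        base[idx] += 1
    return base


def generate_dataset(cfg: GeneratorConfig) -> GroupedDataset:
    """Generate one group of valid CDS under the configured regime."""
    rng = np.random.default_rng(cfg.seed)
    params = _DatasetParams(cfg, rng)
    targets = _draw_targets(cfg, rng)
    p12_base = params.expected_p12(cfg.aa_weights)
    aa_order = list(AMINO_ACIDS)

    ds = GroupedDataset(groups={cfg.group_label})
    for i in range(cfg.n_sequences):
        length = max(int(round(rng.normal(cfg.length_codons,
                                          cfg.length_sd_codons))), 50)
        t = targets[i]
        if cfg.regime == "mutation" and not np.isnan(t):
            aa_w = _mix_aa_weights(cfg.aa_weights, p12_base, t)
        else:
            aa_w = cfg.aa_weights
        beta = 0.0 if np.isnan(t) else _solve_beta(params, aa_w, t)

        aa_probs = np.array([aa_w.get(aa, 0.0) for aa in aa_order])
        aa_counts = rng.multinomial(length - 1, aa_probs / aa_probs.sum())
        body: list[str] = []
        for aa, n_aa in zip(aa_order, aa_counts):
            if n_aa == 0:
                continue
            dist = params.codon_dist(aa, beta)
            fam = list(dist)
            counts = _balanced_counts(n_aa, np.array([dist[c] for c in fam]),
                                      rng)
            for codon, k in zip(fam, counts):
                body.extend([codon] * int(k))
        order = rng.permutation(len(body))
        codons = ["ATG"] + [body[j] for j in order]
        codons.append(STOP_CODONS[rng.integers(len(STOP_CODONS))])
        seq_id = f"{cfg.group_label}_{i:03d}"
        cds = validate_cds(seq_id, "".join(codons), cfg.group_label)
        assert isinstance(cds, CodingSequence), cds
        ds.sequences.append(cds)
    return ds


#: Group recipes emulating a four-taxon vertebrate ortholog panel:
#: (GC3 mean, GC3 SD, sense-codon length mean, length SD).
GROUP_RECIPES: dict[str, tuple[float, float, int, float]] = {
    "fish_like": (0.632, 0.090, 742, 34.0),
    "bird_like": (0.453, 0.009, 706, 9.0),
    "reptile_like": (0.434, 0.021, 718, 14.0),
    "mammal_like": (0.490, 0.049, 711, 12.0),
}


def generate_regime_panel(n_per_group: int = 20, seed: int = 0,
                          **overrides) -> GroupedDataset:
    """Four-group panel (fish/bird/reptile/mammal-like GC3 regimes) under
    the selection regime, with group-specific lengths and GC3 spreads."""
    if n_per_group < 3:
        raise ValueError("n_per_group must be >= 3")
    children = np.random.SeedSequence(seed).spawn(len(GROUP_RECIPES))
    panel = GroupedDataset()
    for child, (label, (gc3, gc3_sd, length, length_sd)) in zip(
            children, GROUP_RECIPES.items()):
        cfg = GeneratorConfig(
            n_sequences=n_per_group,
            length_codons=length,
            length_sd_codons=length_sd,
            gc3_target=gc3,
            gc3_sd=gc3_sd,
            regime="selection",
            group_label=label,
            seed=int(child.generate_state(1)[0] % (2 ** 31)),
        )
        cfg = replace(cfg, **overrides) if overrides else cfg
        part = generate_dataset(cfg)
        panel.sequences.extend(part.sequences)
        panel.groups.add(label)
    return panel
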