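"""Ordering statistic for altered (accelerated) differentiation.

For genes upregulated at least alpha-fold from ES cells to a given embryoid
body (EB) stage in the control genotype, the statistic is the fraction of
those genes whose knockdown EB value falls strictly between the ES and the
control EB value — genes that "lag behind" during knockdown
differentiation:

    EB(control) > EB(knockdown) > ESC        (strict; ties fail)

The observed fraction gets a bootstrap standard error (genes resampled with
replacement) and is compared against a shuffle null: the three expression
vectors are independently permuted over all genes, the alpha selection is
re-applied to the shuffled control values, and the fraction recomputed;
many shuffles give the expected mean and SD. A symmetric variant handles
downregulated genes (ESC > EB ordering).
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd

from ._stats import substream
from .errors import ValidationError
from .expression import ExpressionMatrix, TimeCourseDesign, compute_rpkm


@dataclass
class OrderingInput:
    """Aligned per-gene expression values for one stage comparison."""

    esc: np.ndarray  # control ES-cell expression (RPKM)
    eb_ctrl: np.ndarray  # control EB expression at the stage
    eb_kd: np.ndarray  # knockdown EB expression at the stage
    stage: str = ""

    def __post_init__(self):
        self.esc = np.asarray(self.esc, dtype=float)
        self.eb_ctrl = np.asarray(self.eb_ctrl, dtype=float)
        self.eb_kd = np.asarray(self.eb_kd, dtype=float)
        if not (self.esc.shape == self.eb_ctrl.shape == self.eb_kd.shape):
            raise ValidationError("the three expression vectors must be aligned")
        if (self.esc < 0).any() or (self.eb_ctrl < 0).any() or (self.eb_kd < 0).any():
            raise ValidationError("expression values must be non-negative")

    @property
    def n_genes(self) -> int:
        return self.esc.size


@dataclass
class ShuffleNull:
    expected_mean: float
    expected_sd: float
    fractions: np.ndarray  # per-replicate fractions (for the empirical p)
    n_dropped: int = 0


@dataclass
class OrderingResult:
    stage: str
    direction: str
    alpha: float
    n_genes: int
    observed_fraction: float
    bootstrap_se: float
    expected_mean: float
    expected_sd: float
    z_score: float
    empirical_p: float
    verdict: str


def select_genes(
    esc: np.ndarray,
    eb_ctrl: np.ndarray,
    alpha: float,
    direction: str = "up",
    pseudocount: float = 0.1,
) -> np.ndarray:
    """Indices of genes changed >= alpha-fold from ESC to EB in control.

    "up": (eb_ctrl + eps) / (esc + eps) >= alpha; "down" is the mirror
    ratio. The pseudocount (default 0.1 RPKM) keeps zero-expression genes
    finite.
    """
    if alpha < 1:
        raise ValidationError("alpha must be >= 1")
    if direction not in ("up", "down"):
        raise ValidationError("direction must be 'up' or 'down'")
    esc = np.asarray(esc, dtype=float)
    eb_ctrl = np.asarray(eb_ctrl, dtype=float)
    if direction == "up":
        ratio = (eb_ctrl + pseudocount) / (esc + pseudocount)
    else:
        ratio = (esc + pseudocount) / (eb_ctrl + pseudocount)
    return np.flatnonzero(ratio >= alpha)


def select_upregulated_genes(
    esc: np.ndarray, eb_ctrl: np.ndarray, alpha: float, pseudocount: float = 0.1
) -> np.ndarray:
    return select_genes(esc, eb_ctrl, alpha, "up", pseudocount)


def _ordering_indicator(inp: OrderingInput, genes: np.ndarray, direction: str) -> np.ndarray:
    ctrl, kd, esc = inp.eb_ctrl[genes], inp.eb_kd[genes], inp.esc[genes]
    if direction == "up":
        return (ctrl > kd) & (kd > esc)
    return (ctrl < kd) & (kd < esc)


def ordering_fraction(genes: np.ndarray, inp: OrderingInput, direction: str = "up") -> float:
    """Fraction of selected genes satisfying the strict lag ordering
    EB(control) > EB(knockdown) > ESC (reversed for "down"). Ties fail."""
    genes = np.asarray(genes, dtype=np.int64)
    if genes.size == 0:
        raise ValidationError("ordering_fraction undefined for an empty gene set")
    return float(_ordering_indicator(inp, genes, direction).mean())


def bootstrap_se(
    genes: np.ndarray,
    inp: OrderingInput,
    n_boot: int = 1000,
    seed: int = 0,
    direction: str = "up",
) -> float:
    """Bootstrap SE of the ordering fraction: genes resampled with
    replacement; SD of the resampled fractions."""
    genes = np.asarray(genes, dtype=np.int64)
    if genes.size < 2:
        raise ValidationError("bootstrap needs >= 2 genes")
    if n_boot < 2:
        raise ValidationError("n_boot must be >= 2")
    indicator = _ordering_indicator(inp, genes, direction).astype(float)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, genes.size, size=(n_boot, genes.size))
    fractions = indicator[idx].mean(axis=1)
    return float(np.std(fractions, ddof=1))


def shuffle_null(
    inp: OrderingInput,
    alpha: float,
    n_shuffles: int = 1000,
    seed: int = 0,
    direction: str = "up",
    pseudocount: float = 0.1,
    reselect: bool = True,
    preselected: Optional[np.ndarray] = None,
) -> ShuffleNull:
    """Shuffle null for the ordering fraction.

    Each replicate independently permutes the three expression vectors over
    all genes, re-applies the alpha selection on the shuffled control
    values, and recomputes the fraction. With ``reselect=False`` the
    permutation is instead confined to a fixed pre-selected gene set (the
    alternative reading; requires ``preselected``). Replicates whose
    selection is empty are dropped; more than 50% dropped is an error.
    """
    if n_shuffles < 2:
        raise ValidationError("n_shuffles must be >= 2")
    rng = np.random.default_rng(seed)
    if not reselect:
        if preselected is None:
            raise ValidationError("reselect=False requires a preselected gene set")
        base = np.asarray(preselected, dtype=np.int64)
        if base.size == 0:
            raise ValidationError("preselected gene set is empty")
    fractions = []
    n_dropped = 0
    for _ in range(n_shuffles):
        if reselect:
            esc = rng.permutation(inp.esc)
            ctrl = rng.permutation(inp.eb_ctrl)
            kd = rng.permutation(inp.eb_kd)
            sel = select_genes(esc, ctrl, alpha, direction, pseudocount)
        else:
            esc = inp.esc[base][rng.permutation(base.size)]
            ctrl = inp.eb_ctrl[base][rng.permutation(base.size)]
            kd = inp.eb_kd[base][rng.permutation(base.size)]
            sel = np.arange(base.size)
        if sel.size == 0:
            n_dropped += 1
            continue
        if direction == "up":
            frac = float(((ctrl[sel] > kd[sel]) & (kd[sel] > esc[sel])).mean())
        else:
            frac = float(((ctrl[sel] < kd[sel]) & (kd[sel] < esc[sel])).mean())
        fractions.append(frac)
    if n_dropped > n_shuffles / 2:
        raise ValidationError(
            f"{n_dropped}/{n_shuffles} shuffle replicates had an empty selection"
        )
    fractions = np.asarray(fractions)
    return ShuffleNull(
        expected_mean=float(fractions.mean()),
        expected_sd=float(fractions.std(ddof=1)),
        fractions=fractions,
        n_dropped=n_dropped,
    )


def acceleration_test(observed_fraction: float, null: ShuffleNull):
    """z-score, empirical two-sided p, and verdict for an observed fraction
    against its shuffle null.

    Verdict at |z| >= 2: fewer lagging genes than expected (observed below
    the null mean) indicates knockdown cells running ahead of — or
    otherwise departing from — the control trajectory.
    """
    if null.expected_sd == 0:
        raise ValidationError("shuffle null has zero SD; z-score undefined")
    z = (observed_fraction - null.expected_mean) / null.expected_sd
    dev = np.abs(null.fractions - null.expected_mean)
    p = (1 + int(np.sum(dev >= abs(observed_fraction - null.expected_mean)))) / (
        null.fractions.size + 1
    )
    if z <= -2:
        verdict = "lagging_fewer_than_expected"
    elif z >= 2:
        verdict = "lagging_more_than_expected"
    else:
        verdict = "consistent_with_chance"
    return float(z), float(p), verdict


def ordering_input_from_rpkm(
    rpkm: pd.DataFrame, design: TimeCourseDesign, stage: str
) -> OrderingInput:
    """Build the three aligned vectors from an RPKM matrix and a design.

    Replicate samples within a condition are averaged; the ES-cell vector
    comes from the control genotype at the earliest stage.
    """
    esc_samples = design.samples(genotype="control", stage=design.stage_order[0])
    ctrl_samples = design.samples(genotype="control", stage=stage)
    kd_samples = design.samples(genotype="knockdown", stage=stage)
    for label, samples in (("ESC control", esc_samples), ("EB control", ctrl_samples),
                           ("EB knockdown", kd_samples)):
        if not samples:
            raise ValidationError(f"no {label} samples for stage {stage!r}")
    return OrderingInput(
        esc=rpkm[esc_samples].mean(axis=1).to_numpy(),
        eb_ctrl=rpkm[ctrl_samples].mean(axis=1).to_numpy(),
        eb_kd=rpkm[kd_samples].mean(axis=1).to_numpy(),
        stage=stage,
    )


def run_ordering_analysis(
    rpkm: pd.DataFrame,
    design: TimeCourseDesign,
    stage: str,
    alphas: Sequence[float] = (1.5, 2.0, 3.0, 4.0),
    direction: str = "up",
    n_boot: int = 1000,
    n_shuffles: int = 1000,
    seed: int = 0,
) -> List[OrderingResult]:
    """Full ordering analysis at one stage over a grid of alpha thresholds."""
    inp = ordering_input_from_rpkm(rpkm, design, stage)
    results = []
    for alpha in alphas:
        genes = select_genes(inp.esc, inp.eb_ctrl, alpha, direction)
        if genes.size < 2:
            raise ValidationError(f"fewer than 2 genes selected at alpha={alpha}")
        observed = ordering_fraction(genes, inp, direction)
        boot_seed = int(substream(seed, f"boot/{stage}/{direction}/{alpha}").integers(2**31))
        shuf_seed = int(substream(seed, f"shuffle/{stage}/{direction}/{alpha}").integers(2**31))
        se = bootstrap_se(genes, inp, n_boot=n_boot, seed=boot_seed, direction=direction)
        null = shuffle_null(
            inp, alpha, n_shuffles=n_shuffles, seed=shuf_seed, direction=direction
        )
        z, p, verdict = acceleration_test(observed, null)
        results.append(
            OrderingResult(
                stage=stage,
                direction=direction,
                alpha=float(alpha),
                n_genes=int(genes.size),
                observed_fraction=observed,
                bootstrap_se=se,
                expected_mean=null.expected_mean,
                expected_sd=null.expected_sd,
                z_score=z,
                empirical_p=p,
                verdict=verdict,
            )
        )
    return results


def ordering_results_table(results: List[OrderingResult]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results])
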