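"""Count-level simulator for time-course differential expression studies.

Counts are drawn from the generative model itself: for each gene, exon
random effects b_k ~ N(0, sigma_b^2) are drawn once, the linear predictor is
zeta = log(beta) + eta(t, g) + z_k b_k with beta = 1 at generation time, and
Y ~ NegBin(nu, p) with p = logistic(zeta) (mean nu (1-p)/p).  Effective
library sizes are *estimated* from the simulated counts (TMM) at analysis
time, not injected.

Three mean-surface settings for differentially expressed genes:

    linear       eta(t, g) = C ((0.9 - 2 t) I[g=2] + t)
    exponential  eta(t, g) = exp(1e4 F1^11 F2^6 + 1e2 F1^3 F2^9 + C_g)
    cyclic       eta(t, g) = sin(2.5 pi ((0.9 - 2 t) I[g=2] + t)) + 2

on the grid t_i = i/10, i = 1..8, two conditions, exon lengths
z = (0.1, 0.25, 0.4) kb, nu = 1000, sigma_b = 1, C = 2, C_1 = C_2 = 1.
NDE genes re-use the g = 1 branch for every condition (scenario 1) or a flat
profile at the time-average of that branch (scenario 2).  Scenario 1 has
25 DE + 25 NDE genes; scenario 2 has 25 DE + 225 flat NDE genes.

A separate helper emulates, at the count level only, a read-simulator
experiment: per-transcript expected counts v follow a linear crossing design
on t_i = 1 + 3(i-1)/7 or a cyclic design, with reference expression
r = 20 iota / upsilon for transcript length iota and read length upsilon=100;
counts are drawn from NegBin with mean v.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .io_counts import ExonCountDataset, GeneSetCollection

__all__ = [
    "SimulationDesign",
    "SimulatedDataset",
    "eta_mean",
    "flat_level",
    "polyester_mean",
    "reference_expression",
    "simulate_gene",
    "simulate_dataset",
    "simulate_gene_set_study",
    "score_calls",
]

SETTINGS = ("linear", "exponential", "cyclic")
SETTING_BY_NUMBER = {1: "linear", 2: "exponential", 3: "cyclic"}


@dataclass(frozen=True)
class SimulationDesign:
    """Study conditions for the single-gene simulations (defaults = paper-scale)."""

    setting: str = "linear"
    scenario: int = 1
    replicates: int = 3
    C: float = 2.0
    C_g: tuple[float, float] = (1.0, 1.0)
    nu: float = 1000.0
    z: tuple[float, ...] = (0.1, 0.25, 0.4)
    sigma_b: float = 1.0
    times: tuple[float, ...] = tuple(i / 10 for i in range(1, 9))
    n_genes_de: int = 25
    n_genes_nde: int | None = None  # scenario default: 25 (1) or 225 (2)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.setting not in SETTINGS:
            raise ValueError(f"unknown setting {self.setting!r}")
        if self.scenario not in (1, 2):
            raise ValueError("scenario must be 1 or 2")

    @property
    def n_nde(self) -> int:
        if self.n_genes_nde is not None:
            return self.n_genes_nde
        return 25 if self.scenario == 1 else 225


@dataclass
class SimulatedDataset:
    datasets: list[ExonCountDataset]
    truth: pd.DataFrame  # gene_id, is_de, pattern
    design: SimulationDesign


def eta_mean(setting: str, t, g: int, C: float = 2.0, C_g=(1.0, 1.0),
             de: bool = True) -> np.ndarray:
    """Mean surface eta(t, g) of the chosen setting.

    For NDE genes (``de=False``) the g = 1 branch is used for every
    condition, giving identical profiles across conditions.
    """
    t = np.asarray(t, dtype=float)
    g_eff = g if de else 1
    i2 = 1.0 if g_eff == 2 else 0.0
    i1 = 1.0 if g_eff == 1 else 0.0
    if setting == "linear":
        return C * ((0.9 - 2.0 * t) * i2 + t)
    if setting == "exponential":
        f1 = (0.9 - 2.0 * t) * i2 + t
        f2 = 0.1 * i2 + i1 + (1.0 - 2.0 * i1) * t
        return np.exp(1e4 * f1 ** 11 * f2 ** 6 + 1e2 * f1 ** 3 * f2 ** 9 + C_g[g_eff - 1])
    if setting == "cyclic":
        return np.sin(2.5 * math.pi * ((0.9 - 2.0 * t) * i2 + t)) + 2.0
    raise ValueError(f"unknown setting {setting!r}")


def flat_level(setting: str, design: SimulationDesign) -> float:
    """Flat NDE profile level: time-average of the setting's g=1 curve."""
    t = np.asarray(design.times)
    return float(np.mean(eta_mean(setting, t, 1, design.C, design.C_g)))


def reference_expression(transcript_length: float, read_length: float = 100.0) -> float:
    """Reference expected count r = 20 iota / upsilon."""
    if transcript_length <= 0:
        raise ValueError("transcript length must be positive")
    return 20.0 * transcript_length / read_length


def polyester_mean(pattern: str, t, g: int, r: float, de: bool = True) -> np.ndarray:
    """Expected per-transcript count of the read-simulator emulation."""
    t = np.asarray(t, dtype=float)
    g_eff = g if de else 1
    i2 = 1.0 if g_eff == 2 else 0.0
    if pattern == "linear":
        # crossing design on t in [1, 4]: rising r t in condition 1, falling
        # r (5 - t) in condition 2
        return r * ((5.0 - 2.0 * t) * i2 + t)
    if pattern == "cyclic":
        return r * (np.sin(2.5 * math.pi * ((0.9 - 2.0 * t) * i2 + t)) + 2.0)
    raise ValueError(f"unknown pattern {pattern!r}")


def _sample_layout(design: SimulationDesign) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    times, conds, reps = [], [], []
    for g in (1, 2):
        for t in design.times:
            for r in range(1, design.replicates + 1):
                times.append(t)
                conds.append(g)
                reps.append(r)
    return np.array(times), np.array(conds, dtype=int), np.array(reps, dtype=int)


def simulate_gene(
    eta_fn,
    design: SimulationDesign,
    rng: np.random.Generator,
    gene_id: str = "gene",
) -> ExonCountDataset:
    """Draw one gene's exon counts from the generative model.

    ``eta_fn(t, g)`` supplies the mean surface on the link scale.  Exon
    random effects are drawn once per gene; replicates at the same (t, g) are
    independent NegBin draws sharing the same linear predictor.
    """
    times, conds, reps = _sample_layout(design)
    z = np.asarray(design.z)
    b = rng.normal(0.0, design.sigma_b, size=z.shape[0])
    eta_vals = np.array([eta_fn(t, g) for t, g in zip(times, conds)])
    zeta = eta_vals[:, None] + (z * b)[None, :]  # log(beta)=0 at generation
    p = expit(zeta)
    counts = rng.negative_binomial(design.nu, p)
    return ExonCountDataset(
        gene_id=gene_id,
        counts=counts,
        times=times,
        conditions=conds,
        replicates=reps,
        exon_lengths=z,
    )


def _gene_rngs(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def simulate_dataset(design: SimulationDesign) -> SimulatedDataset:
    """Simulate one scenario: DE genes first, then NDE genes, with truth table."""
    n_de, n_nde = design.n_genes_de, design.n_nde
    rngs = _gene_rngs(design.seed, n_de + n_nde)
    width = len(str(n_de + n_nde))
    datasets, rows = [], []
    flat = flat_level(design.setting, design) if design.scenario == 2 else None
    for j in range(n_de + n_nde):
        gid = f"gene_{j + 1:0{width}d}"
        is_de = j < n_de
        if is_de:
            fn = lambda t, g: eta_mean(design.setting, t, g, design.C, design.C_g)
            pattern = design.setting
        elif design.scenario == 1:
            fn = lambda t, g: eta_mean(design.setting, t, g, design.C, design.C_g, de=False)
            pattern = f"{design.setting}_nde"
        else:
            fn = lambda t, g, lv=flat: lv
            pattern = "flat"
        datasets.append(simulate_gene(fn, design, rngs[j], gid))
        rows.append((gid, is_de, pattern))
    truth = pd.DataFrame(rows, columns=["gene_id", "is_de", "pattern"])
    return SimulatedDataset(datasets=datasets, truth=truth, design=design)


def simulate_gene_set_study(
    seed: int = 0,
    n_sets: int = 30,
    n_enriched: int = 10,
    genes_per_set: int = 10,
    design: SimulationDesign | None = None,
) -> tuple[SimulatedDataset, GeneSetCollection]:
    """Disjoint gene sets for the enrichment study.

    Default geometry: 30 sets of 10 genes; all genes of the first 10 sets
    are NPDE genes from the linear setting (C = 2, nu = 1000); the remaining
    sets hold NDE genes with the same mean for both conditions.
    """
    if design is None:
        design = SimulationDesign(setting="linear", scenario=1, seed=seed)
    n_genes = n_sets * genes_per_set
    n_de = n_enriched * genes_per_set
    rngs = _gene_rngs(seed, n_genes)
    width = len(str(n_genes))
    datasets, rows = [], []
    for j in range(n_genes):
        gid = f"gene_{j + 1:0{width}d}"
        is_de = j < n_de
        fn = lambda t, g, de=is_de: eta_mean(
            design.setting, t, g, design.C, design.C_g, de=de
        )
        datasets.append(simulate_gene(fn, design, rngs[j], gid))
        rows.append((gid, is_de, design.setting if is_de else f"{design.setting}_nde"))
    truth = pd.DataFrame(rows, columns=["gene_id", "is_de", "pattern"])

    sets = {
        f"set_{s + 1:02d}": [datasets[s * genes_per_set + i].gene_id
                             for i in range(genes_per_set)]
        for s in range(n_sets)
    }
    desc = {
        sid: ("enriched" if s < n_enriched else "null")
        for s, sid in enumerate(sets)
    }
    return (
        SimulatedDataset(datasets=datasets, truth=truth, design=design),
        GeneSetCollection(sets, desc),
    )


def score_calls(truth, labels, positive_label="DE") -> tuple[float, float]:
    """FDR and FNR of a set of calls against ground truth.

    truth: boolean per gene (truly DE); labels: boolean or label per gene
    (called positive when equal to ``positive_label`` for string labels).
    FDR = FP / (FP + TP), NaN when nothing is called; FNR = FN / (FN + TN),
    0 when everything is called.
    """
    truth = np.asarray(truth, dtype=bool)
    labels = np.asarray(labels)
    if labels.dtype.kind in "UOS":
        called = labels == positive_label
    else:
        called = labels.astype(bool)
    if truth.shape != called.shape:
        raise ValueError("truth and labels must have equal length")
    tp = int(np.sum(called & truth))
    fp = int(np.sum(called & ~truth))
    fn = int(np.sum(~called & truth))
    tn = int(np.sum(~called & ~truth))
    fdr = float("nan") if (tp + fp) == 0 else fp / (tp + fp)
    fnr = 0.0 if (fn + tn) == 0 else fn / (fn + tn)
    return fdr, fnr
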