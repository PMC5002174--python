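"""Significance testing for individual genes.

The test statistic is a Kullback-Leibler distance ratio

    KLR = KL(eta_F, eta_R) / KL(eta_F, eta_C),

where F is the full model for the hypothesis under test, R the reduced model
without the tested term, and C a constant-mean fit normalising the statistic.
The KL distance between two fits sharing the dispersion nu is the average,
over observations, of the exact NegBin Kullback-Leibler divergence

    KL = (1/N) sum  nu / p * log((1 - p)/(1 - p_hat)) + nu (zeta - zeta_hat),

with (p, zeta) from the full fit and (p_hat, zeta_hat) from the other fit.

P-values come from a permutation procedure: the time labels of the gene are
shuffled (within condition by default, so the treatment composition of the
design is preserved), the whole fitting pipeline is re-run, and the p-value
is the fraction of permuted statistics strictly exceeding the observed one.
Genes are classified in two stages: first NPDE (significant time x treatment
interaction), then, among the remainder, PDE (significant treatment main
effect, parallel profiles); everything else is NDE.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace as _dc_replace

import numpy as np
import pandas as pd
from joblib import Parallel, delayed

from .fanova import FanovaSpec, additive_spec, constant_spec, full_spec, time_only_spec
from .io_counts import ExonCountDataset
from .nbmm import FitOptions, FittedNBMM, fit_nbmm

logger = logging.getLogger(__name__)

__all__ = [
    "KLRResult",
    "GeneTestResult",
    "kl_distance",
    "klr_statistic",
    "permute_time_labels",
    "permute_condition_labels",
    "permutation_pvalue",
    "classify_genes",
    "bh_adjust",
    "results_to_frame",
]

NPDE = "NPDE"
PDE = "PDE"
NDE = "NDE"

#: Below this KL(F, C) the gene is flat and the ratio is reported as 0.
DEGENERATE_KL = 1e-12


@dataclass
class KLRResult:
    """KL distance ratio for one gene and hypothesis."""

    klr: float
    kl_full_reduced: float
    kl_full_const: float
    hypothesis: str
    degenerate: bool = False
    full_fit: FittedNBMM | None = None
    reduced_fit: FittedNBMM | None = None
    const_fit: FittedNBMM | None = None


@dataclass
class GeneTestResult:
    """Per-gene outcome of the two-stage NPDE/PDE/NDE classification."""

    gene_id: str
    label: str
    klr_npde: float = float("nan")
    pvalue_npde: float = float("nan")
    pvalue_npde_adj: float = float("nan")
    klr_pde: float = float("nan")
    pvalue_pde: float = float("nan")
    pvalue_pde_adj: float = float("nan")
    B: int = 0
    flags: str = ""


def strict_greater_pvalue(null_draws, observed: float) -> float:
    """Permutation p-value #{T*_b > T} / B with strictly-greater counting.

    Values land on the grid {0, 1/B, ..., 1}; a p-value of 0 means the
    observed statistic exceeded every permuted draw (interpret as p < 1/B).
    """
    draws = np.asarray(null_draws, dtype=float)
    if draws.size == 0:
        raise ValueError("need at least one permutation draw")
    return float(np.sum(draws > observed)) / draws.size


def kl_distance(
    model_full: FittedNBMM, model_other: FittedNBMM, dataset: ExonCountDataset
) -> float:
    """Average NegBin KL divergence from the full fit to another fit.

    Both fits must be to the same dataset and share nu; offsets cancel in the
    linear-predictor difference, so the distance is invariant to a common
    rescaling of the library sizes.
    """
    if model_full.n_obs != dataset.N or model_other.n_obs != dataset.N:
        raise ValueError("models were not fitted to this dataset")
    if abs(model_full.nu - model_other.nu) > 1e-8 * (1.0 + model_full.nu):
        raise ValueError("KL distance requires a shared nu between fits")
    nu = model_full.nu
    p = model_full.fitted_p
    zeta = model_full.fitted_zeta
    p_hat = model_other.fitted_p
    zeta_hat = model_other.fitted_zeta
    terms = nu / p * (np.log1p(-p) - np.log1p(-p_hat)) + nu * (zeta - zeta_hat)
    return float(terms.mean())


def _hypothesis_specs(hypothesis: str, G: int) -> tuple[FanovaSpec, FanovaSpec]:
    if hypothesis == NPDE:
        return full_spec(G), additive_spec(G)
    if hypothesis == PDE:
        return additive_spec(G), time_only_spec(G)
    raise ValueError(f"unknown hypothesis {hypothesis!r}; use 'NPDE' or 'PDE'")


def klr_statistic(
    dataset: ExonCountDataset,
    hypothesis: str = NPDE,
    fit_options: FitOptions = FitOptions(),
    keep_fits: bool = False,
) -> KLRResult:
    """Fit full, reduced and constant models and form the KL distance ratio.

    nu is estimated with the full model and held fixed when fitting the
    reduced and constant models, so the shared-nu KL distance is well
    defined.
    """
    if dataset.G < 2:
        raise ValueError("differential expression testing requires G >= 2")
    spec_f, spec_r = _hypothesis_specs(hypothesis, dataset.G)
    fit_f = fit_nbmm(dataset, spec_f, fit_options)
    # nu and the smoothing hyperparameters are selected on the full model and
    # shared by the reduced and constant fits: the three fits then differ only
    # in the mean-model terms they may use, which is what the ratio compares.
    opts_fixed = _dc_replace(
        fit_options,
        fix_nu=fit_f.nu,
        fix_hyper=(fit_f.lambda_, fit_f.thetas[1], fit_f.sigma2),
    )
    fit_r = fit_nbmm(dataset, spec_r, opts_fixed)
    fit_c = fit_nbmm(dataset, constant_spec(dataset.G), opts_fixed)

    kl_fr = kl_distance(fit_f, fit_r, dataset)
    kl_fc = kl_distance(fit_f, fit_c, dataset)
    degenerate = kl_fc <= DEGENERATE_KL
    klr = 0.0 if degenerate else kl_fr / kl_fc
    return KLRResult(
        klr=klr,
        kl_full_reduced=kl_fr,
        kl_full_const=kl_fc,
        hypothesis=hypothesis,
        degenerate=degenerate,
        full_fit=fit_f if keep_fits else None,
        reduced_fit=fit_r if keep_fits else None,
        const_fit=fit_c if keep_fits else None,
    )


def permute_time_labels(
    dataset: ExonCountDataset,
    rng: np.random.Generator,
    within_condition: bool = True,
) -> ExonCountDataset:
    """Shuffle the time labels of the samples; counts stay attached.

    All exons of a sample move together (times are a per-sample attribute).
    By default times are re-assigned only among samples of the same
    condition, preserving the multiset of (condition, time) pairs.
    """
    times = dataset.times.copy()
    if within_condition:
        for g in np.unique(dataset.conditions):
            idx = np.flatnonzero(dataset.conditions == g)
            times[idx] = times[idx[rng.permutation(idx.size)]]
    else:
        times = times[rng.permutation(times.size)]
    return dataset.with_times(times)


def permute_condition_labels(
    dataset: ExonCountDataset, rng: np.random.Generator
) -> ExonCountDataset:
    """Shuffle condition labels among the samples of each time point.

    The null for a treatment main effect: time structure is preserved while
    the assignment of samples to conditions is randomized.  The per-time
    condition composition (and hence the design balance) is unchanged.
    """
    conds = dataset.conditions.copy()
    for t in np.unique(dataset.times):
        idx = np.flatnonzero(dataset.times == t)
        conds[idx] = conds[idx[rng.permutation(idx.size)]]
    return dataset.with_conditions(conds)


def permutation_pvalue(
    dataset: ExonCountDataset,
    hypothesis: str = NPDE,
    B: int = 100,
    seed: int | np.random.SeedSequence = 0,
    fit_options: FitOptions = FitOptions(),
    refit_nu_in_permutations: bool = True,
    within_condition: bool = True,
) -> tuple[float, float, np.ndarray]:
    """Observed KLR, its permutation p-value, and the null draws.

    The whole fitting pipeline (smoothing selection and, by default, the
    dispersion estimate) is re-run on every shuffled dataset.  The per-gene
    normaliser KL(F, C) is a constant of the gene, so it is held at its
    observed value: permuted statistics are KL(F*, R*)/KL(F, C), and the
    p-value is the strictly-greater count #{KLR*_b > KLR} / B, living on the
    grid {0, 1/B, ..., 1}.  (Comparing ratios with the common denominator is
    the same test as comparing the tested-term distances themselves.)

    The shuffle matches the tested term: NPDE (time x treatment interaction)
    shuffles time labels within condition, which destroys smooth time
    structure; PDE (treatment main effect) shuffles condition labels within
    each time point, which destroys the between-condition offset while
    leaving time profiles intact.  A permutation whose fit fails is retried
    up to three times with a fresh shuffle, then dropped (B is decremented).
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    rng = np.random.default_rng(seed)
    observed = klr_statistic(dataset, hypothesis, fit_options, keep_fits=True)
    perm_options = fit_options
    if not refit_nu_in_permutations:
        perm_options = _dc_replace(fit_options, fix_nu=observed.full_fit.nu)

    draws_kl = []
    for _ in range(B):
        for attempt in range(3):
            if hypothesis == PDE:
                perm = permute_condition_labels(dataset, rng)
            else:
                perm = permute_time_labels(dataset, rng, within_condition)
            try:
                draws_kl.append(
                    klr_statistic(perm, hypothesis, perm_options).kl_full_reduced
                )
                break
            except Exception as exc:  # noqa: BLE001 - per-draw fit failure
                logger.warning(
                    "gene %s: permutation fit failed (attempt %d): %s",
                    dataset.gene_id, attempt + 1, exc,
                )
        # else: draw dropped, B effectively decremented
    draws_kl = np.asarray(draws_kl)
    if draws_kl.size == 0:
        raise RuntimeError(f"gene {dataset.gene_id}: all permutation fits failed")
    pvalue = strict_greater_pvalue(draws_kl, observed.kl_full_reduced)
    if observed.degenerate:
        draws = draws_kl  # raw distances; the gene itself is flat
    else:
        draws = draws_kl / observed.kl_full_const
    return observed.klr, pvalue, draws


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(p < 0) or np.any(p > 1) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(n)
    out[order] = adjusted
    return out


def _test_one_gene(dataset, hypothesis, B, seed, fit_options):
    try:
        klr, pvalue, _ = permutation_pvalue(
            dataset, hypothesis, B=B, seed=seed, fit_options=fit_options
        )
        return klr, pvalue, ""
    except Exception as exc:  # noqa: BLE001 - per-gene failure is not fatal
        logger.warning("gene %s: %s test failed: %s", dataset.gene_id, hypothesis, exc)
        return float("nan"), float("nan"), f"{hypothesis}_fit_failed"


def classify_genes(
    datasets: list[ExonCountDataset],
    alpha: float = 0.05,
    B: int = 100,
    seed: int = 0,
    fit_options: FitOptions = FitOptions(),
    n_jobs: int = 1,
    stages: tuple[str, ...] = (NPDE, PDE),
) -> list[GeneTestResult]:
    """Two-stage classification of genes into NPDE, PDE and NDE.

    Stage 1 computes NPDE permutation p-values for every gene and applies BH;
    genes with adjusted p below ``alpha`` are NPDE.  Stage 2 tests the
    remaining genes for a treatment main effect (PDE), with BH applied within
    that subset.  Random substreams are pre-assigned per gene and stage, so
    results do not depend on ``n_jobs``.
    """
    if not datasets:
        raise ValueError("no genes to classify")
    root = np.random.SeedSequence(seed)
    seeds = root.spawn(2 * len(datasets))

    stage1 = Parallel(n_jobs=n_jobs)(
        delayed(_test_one_gene)(ds, NPDE, B, seeds[i], fit_options)
        for i, ds in enumerate(datasets)
    )
    results = {}
    p1 = np.array([r[1] for r in stage1])
    ok1 = ~np.isnan(p1)
    adj1 = np.full_like(p1, np.nan)
    if ok1.any():
        adj1[ok1] = bh_adjust(p1[ok1])
    for ds, (klr, p, flag), padj in zip(datasets, stage1, adj1):
        res = GeneTestResult(
            gene_id=ds.gene_id, label=NDE, klr_npde=klr, pvalue_npde=p,
            pvalue_npde_adj=padj, B=B, flags=flag,
        )
        if not np.isnan(padj) and padj < alpha:
            res.label = NPDE
        results[ds.gene_id] = res

    stage2_sets = [
        (i, ds) for i, ds in enumerate(datasets) if results[ds.gene_id].label != NPDE
    ]
    if PDE not in stages:
        stage2_sets = []
    if stage2_sets:
        stage2 = Parallel(n_jobs=n_jobs)(
            delayed(_test_one_gene)(ds, PDE, B, seeds[len(datasets) + i], fit_options)
            for i, ds in stage2_sets
        )
        p2 = np.array([r[1] for r in stage2])
        ok2 = ~np.isnan(p2)
        adj2 = np.full_like(p2, np.nan)
        if ok2.any():
            adj2[ok2] = bh_adjust(p2[ok2])
        for (_, ds), (klr, p, flag), padj in zip(stage2_sets, stage2, adj2):
            res = results[ds.gene_id]
            res.klr_pde, res.pvalue_pde, res.pvalue_pde_adj = klr, p, padj
            if flag:
                res.flags = (res.flags + ";" + flag).strip(";")
            if not np.isnan(padj) and padj < alpha:
                res.label = PDE

    return [results[ds.gene_id] for ds in datasets]


def results_to_frame(results: list[GeneTestResult]) -> pd.DataFrame:
    """Tabulate per-gene results, ordered by gene id."""
    df = pd.DataFrame(
        {
            "gene_id": [r.gene_id for r in results],
            "klr_npde": [r.klr_npde for r in results],
            "pvalue_npde": [r.pvalue_npde for r in results],
            "pvalue_npde_adj": [r.pvalue_npde_adj for r in results],
            "klr_pde": [r.klr_pde for r in results],
            "pvalue_pde": [r.pvalue_pde for r in results],
            "pvalue_pde_adj": [r.pvalue_pde_adj for r in results],
            "label": [r.label for r in results],
            "B": [r.B for r in results],
            "flags": [r.flags for r in results],
        }
    )
    return df.sort_values("gene_id", kind="stable").reset_index(drop=True)
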