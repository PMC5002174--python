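"""Reading, writing and normalising exon-level count data.

The central container is :class:`ExonCountDataset`: the exon x sample read
counts for one gene, together with the sample times, condition labels,
replicate labels, exon lengths and effective library sizes.  Counts are stored
dense, one row per sample and one column per exon; every (sample, exon) cell
must be present.

Effective library sizes follow the TMM (trimmed mean of M-values)
construction used by edgeR: per-sample scaling factors computed from
gene-level totals, normalised to geometric mean one, times the raw totals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "ExonCountDataset",
    "GeneSetCollection",
    "read_counts_table",
    "write_counts_table",
    "tmm_normalization_factors",
    "tmm_effective_library_sizes",
    "filter_genes",
    "read_gene_sets",
    "write_gene_sets",
]

DEFAULT_COLUMNS = {
    "gene": "gene",
    "exon": "exon",
    "exon_length": "exon_length",
    "condition": "condition",
    "time": "time",
    "replicate": "replicate",
    "count": "count",
}


@dataclass
class ExonCountDataset:
    """Exon-level counts for a single gene.

    Attributes
    ----------
    gene_id:
        Gene identifier.
    counts:
        Integer array of shape ``(n_samples, K)``; ``counts[i, k]`` is the
        number of reads mapped to exon ``k`` in sample ``i``.
    times:
        Per-sample observation times (units of the experiment).
    conditions:
        Per-sample condition labels, integers ``1..G``.
    replicates:
        Per-sample replicate labels.
    exon_lengths:
        Exon lengths ``z_k`` (kilobases after ingest conversion), strictly
        positive.
    lib_sizes:
        Per-sample effective library sizes (strictly positive).  Defaults to
        all ones, meaning the offset ``log(beta)`` vanishes.
    exon_ids:
        Exon identifiers, one per column.
    """

    gene_id: str
    counts: np.ndarray
    times: np.ndarray
    conditions: np.ndarray
    replicates: np.ndarray
    exon_lengths: np.ndarray
    lib_sizes: np.ndarray | None = None
    exon_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.times = np.asarray(self.times, dtype=float)
        self.conditions = np.asarray(self.conditions, dtype=int)
        self.replicates = np.asarray(self.replicates, dtype=int)
        self.exon_lengths = np.asarray(self.exon_lengths, dtype=float)
        if self.lib_sizes is None:
            self.lib_sizes = np.ones(self.counts.shape[0])
        self.lib_sizes = np.asarray(self.lib_sizes, dtype=float)
        if not self.exon_ids:
            self.exon_ids = [f"exon_{k + 1}" for k in range(self.K)]
        self._validate()

    def _validate(self) -> None:
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D (samples x exons) array")
        n, k = self.counts.shape
        if np.any(self.counts < 0):
            raise ValueError(f"gene {self.gene_id}: negative counts present")
        if not np.all(np.equal(np.mod(self.counts, 1), 0)):
            raise ValueError(f"gene {self.gene_id}: counts must be integers")
        for name, arr, length in [
            ("times", self.times, n),
            ("conditions", self.conditions, n),
            ("replicates", self.replicates, n),
            ("lib_sizes", self.lib_sizes, n),
            ("exon_lengths", self.exon_lengths, k),
        ]:
            if arr.shape != (length,):
                raise ValueError(f"gene {self.gene_id}: {name} has wrong shape")
        if np.any(self.exon_lengths <= 0):
            raise ValueError(f"gene {self.gene_id}: exon lengths must be positive")
        if np.any(self.lib_sizes <= 0):
            raise ValueError(f"gene {self.gene_id}: library sizes must be positive")
        if np.any(self.conditions < 1):
            raise ValueError(f"gene {self.gene_id}: condition labels must be >= 1")

    # -- shape bookkeeping ------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def K(self) -> int:
        """Number of exons."""
        return self.counts.shape[1]

    @property
    def G(self) -> int:
        """Number of conditions."""
        return int(self.conditions.max())

    @property
    def N(self) -> int:
        """Total number of observations (samples x exons)."""
        return self.counts.size

    @property
    def n_per_condition(self) -> np.ndarray:
        return np.bincount(self.conditions, minlength=self.G + 1)[1:]

    def total_counts(self) -> np.ndarray:
        """Per-sample totals summed over exons."""
        return self.counts.sum(axis=1)

    def with_lib_sizes(self, lib_sizes: np.ndarray) -> "ExonCountDataset":
        return replace(self, lib_sizes=np.asarray(lib_sizes, dtype=float))

    def with_times(self, times: np.ndarray) -> "ExonCountDataset":
        return replace(self, times=np.asarray(times, dtype=float))

    def with_conditions(self, conditions: np.ndarray) -> "ExonCountDataset":
        return replace(self, conditions=np.asarray(conditions, dtype=int))


@dataclass
class GeneSetCollection:
    """Named gene sets (e.g. pathways), as read from a GMT file."""

    sets: dict[str, list[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    @property
    def sizes(self) -> dict[str, int]:
        return {k: len(v) for k, v in self.sets.items()}

    def __len__(self) -> int:
        return len(self.sets)

    def filter_by_size(
        self,
        expressed_genes: set[str] | None = None,
        min_size: int = 0,
        max_size: int | None = None,
        min_present: int = 0,
    ) -> "GeneSetCollection":
        """Keep sets by total size and by member overlap with the data."""
        kept: dict[str, list[str]] = {}
        for sid, genes in self.sets.items():
            if len(genes) < min_size:
                continue
            if max_size is not None and len(genes) > max_size:
                continue
            if expressed_genes is not None:
                present = sum(g in expressed_genes for g in genes)
                if present < min_present:
                    continue
            kept[sid] = list(genes)
        return GeneSetCollection(
            kept, {k: self.descriptions.get(k, "") for k in kept}
        )


def read_counts_table(
    path, dialect: dict[str, str] | None = None, sep: str = "\t"
) -> list[ExonCountDataset]:
    """Read a long-format exon count table into one dataset per gene.

    The file must contain (under the default or remapped names) the columns
    gene, exon, exon_length, condition, time, replicate, count.  Exon lengths
    are converted to kilobases on ingest when they look like base-pair values
    (>= 10), so that the length-scaled random effect ``z_k b_k`` lives on the
    sub-unit scale.

    Samples are ordered by (condition, time, replicate) and exons by exon id.
    """
    cols = dict(DEFAULT_COLUMNS)
    if dialect:
        cols.update(dialect)
    df = pd.read_csv(path, sep=sep, comment="#")
    missing = [c for c in cols.values() if c not in df.columns]
    if missing:
        raise ValueError(f"count table is missing required column(s): {missing}")
    df = df.rename(columns={v: k for k, v in cols.items()})

    bad = df.index[df["count"] < 0]
    if len(bad):
        raise ValueError(f"negative count at row {int(bad[0]) + 2} of {path}")

    datasets = []
    for gene_id, sub in df.groupby("gene", sort=True):
        exon_ids = sorted(sub["exon"].astype(str).unique())
        exon_idx = {e: k for k, e in enumerate(exon_ids)}
        lengths = np.zeros(len(exon_ids))
        for e, ln in zip(sub["exon"].astype(str), sub["exon_length"]):
            lengths[exon_idx[e]] = ln
        # bp -> kb when lengths are clearly on the base-pair scale
        if np.all(lengths >= 10):
            lengths = lengths / 1000.0

        sample_key = (
            sub[["condition", "time", "replicate"]]
            .drop_duplicates()
            .sort_values(["condition", "time", "replicate"])
            .reset_index(drop=True)
        )
        sidx = {
            (row.condition, row.time, row.replicate): i
            for i, row in sample_key.iterrows()
        }
        counts = np.zeros((len(sample_key), len(exon_ids)), dtype=np.int64)
        filled = np.zeros_like(counts, dtype=bool)
        for cond, tt, rep, exon, cnt in zip(
            sub["condition"], sub["time"], sub["replicate"], sub["exon"], sub["count"]
        ):
            i = sidx[(cond, tt, rep)]
            k = exon_idx[str(exon)]
            counts[i, k] = cnt
            filled[i, k] = True
        if not filled.all():
            raise ValueError(
                f"gene {gene_id}: missing (sample, exon) cells; the table must be dense"
            )
        datasets.append(
            ExonCountDataset(
                gene_id=str(gene_id),
                counts=counts,
                times=sample_key["time"].to_numpy(float),
                conditions=sample_key["condition"].to_numpy(int),
                replicates=sample_key["replicate"].to_numpy(int),
                exon_lengths=lengths,
                exon_ids=exon_ids,
            )
        )
    return datasets


def write_counts_table(datasets: list[ExonCountDataset], path, sep: str = "\t") -> None:
    """Write datasets back to the long TSV format read by `read_counts_table`.

    Exon lengths are written in base pairs (kb x 1000) so that a write/read
    round trip is exact.
    """
    rows = []
    for ds in datasets:
        for i in range(ds.n_samples):
            for k in range(ds.K):
                rows.append(
                    (
                        ds.gene_id,
                        ds.exon_ids[k],
                        ds.exon_lengths[k] * 1000.0,
                        ds.conditions[i],
                        ds.times[i],
                        ds.replicates[i],
                        int(ds.counts[i, k]),
                    )
                )
    pd.DataFrame(
        rows,
        columns=["gene", "exon", "exon_length", "condition", "time", "replicate", "count"],
    ).to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# TMM normalisation
# ---------------------------------------------------------------------------

def _gene_by_sample_matrix(datasets: list[ExonCountDataset]) -> np.ndarray:
    mats = [ds.total_counts() for ds in datasets]
    n = {m.shape[0] for m in mats}
    if len(n) != 1:
        raise ValueError("all genes must share the same samples for TMM")
    return np.vstack(mats).astype(float)


def _tmm_factor_pair(
    obs: np.ndarray, ref: np.ndarray, trim_M: float, trim_A: float
) -> float:
    """TMM factor of `obs` against `ref` (gene totals), log2 scale internally."""
    n_obs = obs.sum()
    n_ref = ref.sum()
    keep = (obs > 0) & (ref > 0)
    if not keep.any():
        return 1.0
    obs = obs[keep]
    ref = ref[keep]
    m = np.log2((obs / n_obs) / (ref / n_ref))
    a = 0.5 * np.log2((obs / n_obs) * (ref / n_ref))
    # delta-method precision weights (binomial approximation), as in edgeR
    w = (n_obs - obs) / (n_obs * obs) + (n_ref - ref) / (n_ref * ref)
    finite = np.isfinite(m) & np.isfinite(a) & np.isfinite(w)
    m, a, w = m[finite], a[finite], w[finite]
    if m.size == 0:
        return 1.0
    if np.max(np.abs(m)) < 1e-6:
        return 1.0
    n = m.size
    lo_m = np.floor(n * trim_M) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * trim_A) + 1
    hi_a = n + 1 - lo_a
    rank_m = pd.Series(m).rank().to_numpy()
    rank_a = pd.Series(a).rank().to_numpy()
    keep2 = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep2.any():
        return 1.0
    f = np.sum(m[keep2] / w[keep2]) / np.sum(1.0 / w[keep2])
    if not np.isfinite(f):
        return 1.0
    return float(2.0 ** f)


def tmm_normalization_factors(
    datasets: list[ExonCountDataset], trim_M: float = 0.30, trim_A: float = 0.05
) -> np.ndarray:
    """Per-sample TMM normalisation factors with geometric mean one."""
    mat = _gene_by_sample_matrix(datasets)
    totals = mat.sum(axis=0)
    if np.any(totals <= 0):
        bad = int(np.argmin(totals))
        raise ValueError(f"sample {bad} has zero total count; cannot normalise")
    if mat.shape[1] < 2:
        raise ValueError("TMM needs at least two samples")
    # reference: sample whose upper quartile of scaled counts is closest to
    # the mean upper quartile
    uq = np.array(
        [np.quantile(mat[:, j] / totals[j], 0.75) for j in range(mat.shape[1])]
    )
    ref_idx = int(np.argmin(np.abs(uq - uq.mean())))
    factors = np.array(
        [
            _tmm_factor_pair(mat[:, j], mat[:, ref_idx], trim_M, trim_A)
            for j in range(mat.shape[1])
        ]
    )
    factors = factors / np.exp(np.mean(np.log(factors)))
    return factors


def tmm_effective_library_sizes(
    datasets: list[ExonCountDataset], trim_M: float = 0.30, trim_A: float = 0.05
) -> np.ndarray:
    """Effective library sizes: raw per-sample totals times TMM factors."""
    mat = _gene_by_sample_matrix(datasets)
    totals = mat.sum(axis=0)
    factors = tmm_normalization_factors(datasets, trim_M=trim_M, trim_A=trim_A)
    return totals * factors


def attach_library_sizes(
    datasets: list[ExonCountDataset],
    lib_sizes: np.ndarray | None = None,
    mode: str = "factors",
) -> list[ExonCountDataset]:
    """Attach shared per-sample scale estimates as the model offset beta.

    ``mode="factors"`` (default) uses the TMM normalization factors alone
    (geometric mean one): samples are treated as sequenced to a common depth
    and only composition drift is corrected.  ``mode="effective"`` uses the
    full effective library sizes (raw totals x factor), appropriate when
    sample depths genuinely differ; note that with coordinated expression
    changes the raw totals carry biology, not depth.  Explicit ``lib_sizes``
    override both.  Whatever the source, values are rescaled to geometric
    mean one so the offset log(beta) is centred.
    """
    if lib_sizes is None:
        if mode == "factors":
            lib_sizes = tmm_normalization_factors(datasets)
        elif mode == "effective":
            lib_sizes = tmm_effective_library_sizes(datasets)
        else:
            raise ValueError(f"unknown mode {mode!r}")
    lib_sizes = np.asarray(lib_sizes, dtype=float)
    lib_sizes = lib_sizes / np.exp(np.mean(np.log(lib_sizes)))
    return [ds.with_lib_sizes(lib_sizes) for ds in datasets]


def filter_genes(
    datasets: list[ExonCountDataset],
    min_count: int = 10,
    min_samples: int = 2,
) -> list[ExonCountDataset]:
    """Screen out weakly expressed genes.

    A gene is kept when its count-per-million (gene total over exons, scaled
    by the per-sample grand totals) exceeds the CPM value implied by
    ``min_count`` at the median library size, in at least ``min_samples``
    samples.  ``min_samples=0`` keeps everything.
    """
    if not datasets or min_samples == 0:
        return list(datasets)
    mat = _gene_by_sample_matrix(datasets)
    totals = mat.sum(axis=0)
    cpm = mat / totals * 1e6
    cpm_threshold = min_count * 1e6 / np.median(totals)
    keep = (cpm > cpm_threshold).sum(axis=1) >= min_samples
    return [ds for ds, k in zip(datasets, keep) if k]


# ---------------------------------------------------------------------------
# GMT gene sets
# ---------------------------------------------------------------------------

def read_gene_sets(path) -> GeneSetCollection:
    """Read gene sets from a GMT file (set id, description, member genes)."""
    sets: dict[str, list[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                logger.warning("%s:%d: skipping empty line", path, lineno)
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                logger.warning(
                    "%s:%d: set %r has no genes; dropped", path, lineno, parts[0]
                )
                continue
            sid, desc, *genes = parts
            # de-duplicate, preserving order
            seen: dict[str, None] = {}
            for g in genes:
                if g:
                    seen.setdefault(g, None)
            if not seen:
                logger.warning(
                    "%s:%d: set %r has no genes; dropped", path, lineno, sid
                )
                continue
            sets[sid] = list(seen)
            descriptions[sid] = desc
    return GeneSetCollection(sets, descriptions)


def write_gene_sets(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for sid, genes in collection.sets.items():
            desc = collection.descriptions.get(sid, "")
            fh.write("\t".join([sid, desc, *genes]) + "\n")
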