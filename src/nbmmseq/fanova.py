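"""Functional ANOVA machinery on [0,1] x {1..G} with cubic-spline smoothness.

The mean expression surface is decomposed as

    eta(t, g) = eta_0 + eta_1(t) + eta_2(g) + eta_12(t, g)

with the identifiability side conditions: integral of eta_1 over [0,1] is 0,
sum of eta_2 over conditions is 0, and eta_12 integrates to 0 in t for every g
and sums to 0 over g for every t.

The time component carries a cubic-spline roughness penalty (integrated
squared second derivative).  Its reproducing kernel on [0,1] is the classical
Bernoulli-polynomial construction

    R(s, t) = k2(s) k2(t) - k4(|s - t|),

with k1(x) = x - 1/2, k2 = (k1^2 - 1/12)/2, k4 = (k1^4 - k1^2/2 + 7/240)/24.
The unpenalised null space holds the constant and linear-in-time functions,
zero-sum treatment contrasts, and (when the interaction is modelled) the
linear-time x contrast products.  The penalised interaction kernel is the
tensor product of the cubic time kernel with the zero-mean discrete treatment
kernel I[g1 == g2] - 1/G.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "FanovaSpec",
    "EtaRepresentation",
    "DesignMatrices",
    "map_times_to_unit",
    "cubic_time_kernel",
    "treatment_kernel",
    "interaction_kernel",
    "null_space_basis",
    "assemble_model_matrices",
    "evaluate_eta",
    "decompose_eta",
    "FULL_SPEC",
    "additive_spec",
    "time_only_spec",
    "constant_spec",
]


@dataclass(frozen=True)
class FanovaSpec:
    """Which functional-ANOVA terms a model includes."""

    include_time: bool = True
    include_treatment: bool = True
    include_interaction: bool = True
    G: int = 2

    def __post_init__(self) -> None:
        if self.include_interaction and not (
            self.include_time and self.include_treatment
        ):
            raise ValueError("interaction requires both main effects")
        if self.G < 1:
            raise ValueError("G must be >= 1")

    @property
    def has_kernel(self) -> bool:
        return self.include_time or self.include_interaction


def full_spec(G: int = 2) -> FanovaSpec:
    return FanovaSpec(True, True, True, G)


def additive_spec(G: int = 2) -> FanovaSpec:
    return FanovaSpec(True, True, False, G)


def time_only_spec(G: int = 2) -> FanovaSpec:
    return FanovaSpec(True, False, False, G)


def constant_spec(G: int = 2) -> FanovaSpec:
    return FanovaSpec(False, False, False, G)


FULL_SPEC = full_spec()


def map_times_to_unit(times: np.ndarray) -> tuple[np.ndarray, tuple[float, float]]:
    """Affinely map times onto [0,1]; returns the scaled vector and (lo, hi).

    A constant time vector maps to 0.5 everywhere (degenerate design).
    """
    times = np.asarray(times, dtype=float)
    if times.size == 0:
        raise ValueError("empty time vector")
    lo, hi = float(times.min()), float(times.max())
    if hi == lo:
        return np.full_like(times, 0.5), (lo, hi)
    return (times - lo) / (hi - lo), (lo, hi)


# ---------------------------------------------------------------------------
# Kernels
# ---------------------------------------------------------------------------

def _k1(x):
    return x - 0.5


def _k2(x):
    return (_k1(x) ** 2 - 1.0 / 12.0) / 2.0


def _k4(x):
    k1 = _k1(x)
    return (k1 ** 4 - k1 ** 2 / 2.0 + 7.0 / 240.0) / 24.0


def cubic_time_kernel(s, t):
    """Cubic-spline reproducing kernel on [0,1] (broadcasts over arrays)."""
    s = np.asarray(s, dtype=float)
    t = np.asarray(t, dtype=float)
    if np.any(s < -1e-12) or np.any(s > 1 + 1e-12) or np.any(t < -1e-12) or np.any(t > 1 + 1e-12):
        raise ValueError("cubic_time_kernel arguments must lie in [0,1]")
    return _k2(s) * _k2(t) - _k4(np.abs(s - t))


def treatment_kernel(g1, g2, G: int):
    """Zero-mean discrete kernel on condition labels: I[g1==g2] - 1/G."""
    g1 = np.asarray(g1, dtype=int)
    g2 = np.asarray(g2, dtype=int)
    if np.any(g1 < 1) or np.any(g1 > G) or np.any(g2 < 1) or np.any(g2 > G):
        raise ValueError(f"condition labels must lie in 1..{G}")
    return (g1 == g2).astype(float) - 1.0 / G


def interaction_kernel(s, g1, t, g2, G: int):
    """Tensor-product kernel for the smooth time x treatment interaction."""
    return cubic_time_kernel(s, t) * treatment_kernel(g1, g2, G)


# ---------------------------------------------------------------------------
# Basis and gram assembly
# ---------------------------------------------------------------------------

def _contrast_columns(g: np.ndarray, G: int) -> np.ndarray:
    """Zero-sum treatment contrasts e_j(g) = I[g==j] - 1/G, j = 1..G-1."""
    cols = [((g == j).astype(float) - 1.0 / G) for j in range(1, G)]
    return np.column_stack(cols) if cols else np.zeros((g.shape[0], 0))


def null_space_basis(
    t: np.ndarray, g: np.ndarray, spec: FanovaSpec
) -> tuple[np.ndarray, list[str]]:
    """Unpenalised basis columns evaluated at (t, g), with component labels.

    Labels are one of {"const", "time", "treat", "interaction"}; they drive
    the component attribution in :func:`decompose_eta`.
    """
    t = np.asarray(t, dtype=float)
    g = np.asarray(g, dtype=int)
    cols = [np.ones_like(t)]
    labels = ["const"]
    if spec.include_time:
        cols.append(_k1(t))
        labels.append("time")
    if spec.include_treatment:
        if spec.G < 2:
            raise ValueError("treatment effect requested but G < 2 (confounded)")
        con = _contrast_columns(g, spec.G)
        for j in range(con.shape[1]):
            cols.append(con[:, j])
            labels.append("treat")
    if spec.include_interaction:
        con = _contrast_columns(g, spec.G)
        for j in range(con.shape[1]):
            cols.append(_k1(t) * con[:, j])
            labels.append("interaction")
    return np.column_stack(cols), labels


@dataclass
class DesignMatrices:
    """Precomputed design for a penalized fit at fixed anchors.

    ``S`` is the null-space basis at the observation rows; ``Rc_cross`` /
    ``Rt_cross`` the cubic and treatment kernel evaluations between
    observation design points and anchors (combined per theta at solve time);
    ``Rc_gram`` / ``Rt_gram`` the corresponding anchor grams.  ``Z`` carries
    the exon-length columns for the random effects.
    """

    S: np.ndarray
    labels: list[str]
    Rc_cross: np.ndarray
    Rt_cross: np.ndarray
    Rc_gram: np.ndarray
    Rt_gram: np.ndarray
    Z: np.ndarray
    anchors_t: np.ndarray
    anchors_g: np.ndarray
    spec: FanovaSpec
    point_of_row: np.ndarray | None = None  # design-point id per observation
    n_points: int = 0
    point_rows: list[np.ndarray] | None = None  # observation rows per point

    @property
    def n_null(self) -> int:
        return self.S.shape[1]

    @property
    def n_anchor(self) -> int:
        return self.anchors_t.shape[0]

    def cross(self, thetas: tuple[float, float]) -> np.ndarray:
        """Observation x anchor matrix of theta-weighted kernel values."""
        theta1, theta12 = thetas
        out = np.zeros_like(self.Rc_cross)
        if self.spec.include_time:
            out += theta1 * self.Rc_cross
        if self.spec.include_interaction:
            out += theta12 * self.Rc_cross * self.Rt_cross
        return out

    def gram(self, thetas: tuple[float, float]) -> np.ndarray:
        """Anchor gram Q with J(eta) = c' Q c."""
        theta1, theta12 = thetas
        out = np.zeros_like(self.Rc_gram)
        if self.spec.include_time:
            out += theta1 * self.Rc_gram
        if self.spec.include_interaction:
            out += theta12 * self.Rc_gram * self.Rt_gram
        return out


def assemble_model_matrices(
    t_scaled: np.ndarray,
    g: np.ndarray,
    exon_lengths: np.ndarray,
    spec: FanovaSpec,
) -> DesignMatrices:
    """Build design matrices for samples at scaled times ``t_scaled`` with
    condition labels ``g`` and ``K = len(exon_lengths)`` exons per sample.

    Observation rows are ordered sample-major: row = sample * K + exon.
    Representer anchors sit at the distinct (t, g) design points, so
    replicates share an anchor.
    """
    t_scaled = np.asarray(t_scaled, dtype=float)
    g = np.asarray(g, dtype=int)
    z = np.asarray(exon_lengths, dtype=float)
    n, K = t_scaled.shape[0], z.shape[0]

    pairs, point_of_sample = np.unique(
        np.column_stack([t_scaled, g.astype(float)]), axis=0, return_inverse=True
    )
    at, ag = pairs[:, 0], pairs[:, 1].astype(int)

    S_samp, labels = null_space_basis(t_scaled, g, spec)
    rank = np.linalg.matrix_rank(S_samp)
    if rank < S_samp.shape[1]:
        raise ValueError(
            "null-space basis is rank deficient for this design "
            f"(rank {rank} < {S_samp.shape[1]}); drop a confounded term"
        )

    if spec.has_kernel:
        Rc_cross_s = cubic_time_kernel(t_scaled[:, None], at[None, :])
        Rt_cross_s = treatment_kernel(g[:, None], ag[None, :], spec.G)
        Rc_gram = cubic_time_kernel(at[:, None], at[None, :])
        Rt_gram = treatment_kernel(ag[:, None], ag[None, :], spec.G)
    else:
        at = np.zeros(0)
        ag = np.zeros(0, dtype=int)
        Rc_cross_s = np.zeros((n, 0))
        Rt_cross_s = np.zeros((n, 0))
        Rc_gram = np.zeros((0, 0))
        Rt_gram = np.zeros((0, 0))

    # expand sample-level rows to observation rows (sample-major, K exons)
    rep = np.repeat(np.arange(n), K)
    S = S_samp[rep]
    Rc_cross = Rc_cross_s[rep]
    Rt_cross = Rt_cross_s[rep]
    Z = np.tile(np.diag(z), (n, 1))

    return DesignMatrices(
        S=S,
        labels=labels,
        Rc_cross=Rc_cross,
        Rt_cross=Rt_cross,
        Rc_gram=Rc_gram,
        Rt_gram=Rt_gram,
        Z=Z,
        anchors_t=at,
        anchors_g=ag,
        spec=spec,
        point_of_row=point_of_sample.ravel()[rep],
        n_points=pairs.shape[0],
        point_rows=[
            np.flatnonzero(point_of_sample.ravel()[rep] == j)
            for j in range(pairs.shape[0])
        ],
    )


# ---------------------------------------------------------------------------
# Fitted-eta representation
# ---------------------------------------------------------------------------

@dataclass
class EtaRepresentation:
    """Fitted eta as null-space coefficients plus representer coefficients."""

    d: np.ndarray
    c: np.ndarray
    labels: list[str]
    anchors_t: np.ndarray
    anchors_g: np.ndarray
    thetas: tuple[float, float]
    spec: FanovaSpec
    time_range: tuple[float, float] = (0.0, 1.0)

    def scale_time(self, t) -> np.ndarray:
        lo, hi = self.time_range
        t = np.asarray(t, dtype=float)
        if hi == lo:
            return np.full_like(t, 0.5)
        return (t - lo) / (hi - lo)


def _kernel_row(rep: EtaRepresentation, s: np.ndarray, g: np.ndarray) -> np.ndarray:
    theta1, theta12 = rep.thetas
    Rc = cubic_time_kernel(s[:, None], rep.anchors_t[None, :])
    out = np.zeros_like(Rc)
    if rep.spec.include_time:
        out += theta1 * Rc
    if rep.spec.include_interaction:
        Rt = treatment_kernel(g[:, None], rep.anchors_g[None, :], rep.spec.G)
        out += theta12 * Rc * Rt
    return out


def evaluate_eta(rep: EtaRepresentation, t, g, scaled: bool = True) -> np.ndarray:
    """Evaluate eta(t, g).  ``scaled=False`` maps t from original time units."""
    t = np.atleast_1d(np.asarray(t, dtype=float))
    g = np.broadcast_to(np.atleast_1d(np.asarray(g, dtype=int)), t.shape)
    s = t if scaled else rep.scale_time(t)
    if np.any(s < -1e-9) or np.any(s > 1 + 1e-9):
        raise ValueError("evaluation time outside the fitted [0,1] domain")
    S, _ = null_space_basis(s, g, rep.spec)
    val = S @ rep.d
    if rep.c.size:
        val = val + _kernel_row(rep, s, g) @ rep.c
    return val


def decompose_eta(rep: EtaRepresentation, grid: np.ndarray) -> dict:
    """Split eta into its ANOVA components on a scaled time grid.

    Returns a dict with ``eta0`` (scalar), ``eta1`` (len(grid),),
    ``eta2`` (G,), and ``eta12`` (len(grid), G).  Components sum to
    ``evaluate_eta`` pointwise and each satisfies its side condition by
    construction of the basis and kernels.
    """
    grid = np.asarray(grid, dtype=float)
    G = rep.spec.G
    d, labels = rep.d, rep.labels

    eta0 = 0.0
    eta1 = np.zeros(grid.shape[0])
    eta2 = np.zeros(G)
    eta12 = np.zeros((grid.shape[0], G))

    gs = np.arange(1, G + 1)
    treat_j = 0
    inter_j = 0
    for coef, lab in zip(d, labels):
        if lab == "const":
            eta0 += coef
        elif lab == "time":
            eta1 += coef * _k1(grid)
        elif lab == "treat":
            treat_j += 1
            eta2 += coef * ((gs == treat_j).astype(float) - 1.0 / G)
        elif lab == "interaction":
            inter_j += 1
            con = (gs == inter_j).astype(float) - 1.0 / G
            eta12 += coef * np.outer(_k1(grid), con)

    if rep.c.size:
        theta1, theta12 = rep.thetas
        Rc = cubic_time_kernel(grid[:, None], rep.anchors_t[None, :])
        if rep.spec.include_time:
            eta1 = eta1 + theta1 * (Rc @ rep.c)
        if rep.spec.include_interaction:
            for gi, gval in enumerate(gs):
                Rt = treatment_kernel(
                    np.full_like(rep.anchors_g, gval), rep.anchors_g, G
                )
                eta12[:, gi] += theta12 * ((Rc * Rt[None, :]) @ rep.c)

    return {"eta0": float(eta0), "eta1": eta1, "eta2": eta2, "eta12": eta12}
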