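"""Per-marker Gaussian-mixture gating and cell-type labeling.

Marker positivity is called without manual thresholds by fitting a
K-component univariate Gaussian mixture

    f(x) = sum_k pi_k N(x | mu_k, sigma_k^2)

to the log2 intensities of each marker by expectation-maximization, then
declaring a cell positive when its posterior mass is highest for the
component with the largest mean (the foreground population sits at the high
end of the histogram). Basal-marker (p63, CK5) calls are combined by logical
OR: an epithelial cell positive for at least one basal marker is
non-cancerous epithelium (N-CE); a double-negative epithelial cell is
cancerous epithelium (CE).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_qc import BASAL_MARKERS, CellTable, SchemaError

_LOG_2PI = float(np.log(2.0 * np.pi))


class FitError(ValueError):
    """The mixture cannot be identified on the given data."""


@dataclass
class EMConfig:
    """EM settings: convergence on relative log-likelihood change < ``eps``
    (default 1e-8) with at most ``max_iter`` (default 1000) iterations."""

    K: int = 2
    eps: float = 1e-8
    max_iter: int = 1000
    init: str = "quantile"  # "quantile" (deterministic) or "kmeans"
    variance_floor_frac: float = 1e-6  # floor as a fraction of total variance
    seed: int | None = 0

    def __post_init__(self) -> None:
        if self.eps <= 0:
            raise ValueError("eps must be positive")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.K < 1:
            raise ValueError("K must be >= 1")


@dataclass
class MixtureFit:
    """A fitted univariate Gaussian mixture: weights, means, variances, and
    the log-likelihood trace of the EM run."""

    K: int
    weights: np.ndarray
    means: np.ndarray
    variances: np.ndarray
    loglik_trace: list[float] = field(default_factory=list)
    n_iterations: int = 0
    converged: bool = False

    def __post_init__(self) -> None:
        assert abs(self.weights.sum() - 1.0) < 1e-10
        assert (self.variances > 0).all()

    @property
    def foreground_component(self) -> int:
        """Index of the component with the largest mean (the positive side)."""
        return int(np.argmax(self.means))

    def to_dict(self) -> dict:
        return {
            "K": self.K,
            "weights": self.weights.tolist(),
            "means": self.means.tolist(),
            "variances": self.variances.tolist(),
            "n_iterations": self.n_iterations,
            "converged": self.converged,
            "loglik": self.loglik_trace[-1] if self.loglik_trace else None,
        }


def _log_normal_pdf(x: np.ndarray, mean: float, var: float) -> np.ndarray:
    return -0.5 * (_LOG_2PI + np.log(var) + (x - mean) ** 2 / var)


def posterior_responsibilities(values: np.ndarray, weights: np.ndarray,
                               means: np.ndarray, variances: np.ndarray
                               ) -> tuple[np.ndarray, float]:
    """E-step: posterior gamma_ik and the total log-likelihood.

    gamma_ik = pi_k N(x_i|mu_k,sigma_k^2) / sum_j pi_j N(x_i|mu_j,sigma_j^2),
    computed in log space for stability. Rows of gamma sum to 1.
    """
    x = np.asarray(values, dtype=float)[:, None]
    log_comp = np.log(weights)[None, :] + _log_normal_pdf(x, means[None, :],
                                                          variances[None, :])
    m = log_comp.max(axis=1, keepdims=True)
    lse = m[:, 0] + np.log(np.exp(log_comp - m).sum(axis=1))
    gamma = np.exp(log_comp - lse[:, None])
    return gamma, float(lse.sum())


def _init_params(x: np.ndarray, cfg: EMConfig) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    K = cfg.K
    if cfg.init == "quantile":
        # means at the (2k-1)/(2K) quantiles, equal weights, pooled variance
        qs = (2 * np.arange(1, K + 1) - 1) / (2 * K)
        means = np.quantile(x, qs)
    elif cfg.init == "kmeans":
        from sklearn.cluster import KMeans
        km = KMeans(n_clusters=K, n_init=5, random_state=cfg.seed).fit(x[:, None])
        means = np.sort(km.cluster_centers_.ravel())
    else:
        raise ValueError(f"unknown init strategy {cfg.init!r}")
    weights = np.full(K, 1.0 / K)
    variances = np.full(K, max(x.var(), 1e-12))
    return weights, means, variances


def fit_gmm_em(values, cfg: EMConfig | None = None) -> MixtureFit:
    """Fit a K-component univariate Gaussian mixture by EM.

    The E-step computes posterior responsibilities gamma_ik; the M-step
    updates pi_k = mean_i gamma_ik, mu_k = weighted mean, sigma_k^2 =
    weighted variance about the new mean. Iteration stops when the relative
    log-likelihood change drops below ``cfg.eps`` or ``cfg.max_iter`` is
    reached. The log-likelihood is non-decreasing (asserted each iteration).
    Deterministic given the init strategy and seed.
    """
    cfg = cfg or EMConfig()
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if len(np.unique(x)) < 2 * cfg.K:
        raise FitError(
            f"need at least {2 * cfg.K} distinct finite values to fit a "
            f"{cfg.K}-component mixture, got {len(np.unique(x))}")

    if cfg.K == 1:
        mu = float(x.mean())
        var = float(x.var())  # MLE
        fit = MixtureFit(K=1, weights=np.array([1.0]), means=np.array([mu]),
                         variances=np.array([max(var, 1e-12)]),
                         n_iterations=0, converged=True)
        _, ll = posterior_responsibilities(x, fit.weights, fit.means, fit.variances)
        fit.loglik_trace = [ll]
        return fit

    floor = max(cfg.variance_floor_frac * x.var(), 1e-12)
    weights, means, variances = _init_params(x, cfg)
    variances = np.maximum(variances, floor)

    trace: list[float] = []
    prev_ll = -np.inf
    converged = False
    it = 0
    for it in range(1, cfg.max_iter + 1):
        gamma, ll = posterior_responsibilities(x, weights, means, variances)
        assert ll >= prev_ll - 1e-9 * max(1.0, abs(prev_ll)), \
            "EM log-likelihood decreased"
        trace.append(ll)

        nk = gamma.sum(axis=0)
        weights = nk / len(x)
        means = (gamma * x[:, None]).sum(axis=0) / nk
        variances = (gamma * (x[:, None] - means[None, :]) ** 2).sum(axis=0) / nk
        variances = np.maximum(variances, floor)

        if np.isfinite(prev_ll) and abs(ll - prev_ll) < cfg.eps * max(1.0, abs(prev_ll)):
            converged = True
            break
        prev_ll = ll

    # prune numerically empty components
    alive = weights >= 1e-6
    if not alive.all():
        warnings.warn(f"pruned {int((~alive).sum())} degenerate mixture "
                      "component(s) with weight < 1e-6")
        weights = weights[alive] / weights[alive].sum()
        means, variances = means[alive], variances[alive]

    return MixtureFit(K=int(len(weights)), weights=weights, means=means,
                      variances=variances, loglik_trace=trace,
                      n_iterations=it, converged=converged)


def classify_positive(values, fit: MixtureFit) -> np.ndarray:
    """Binary positivity per value: positive iff the posterior-argmax
    component is the one with the largest mean. Exact posterior ties break
    toward negative."""
    x = np.asarray(values, dtype=float)
    gamma, _ = posterior_responsibilities(x, fit.weights, fit.means, fit.variances)
    top = fit.foreground_component
    fg = gamma[:, top]
    others = np.delete(gamma, top, axis=1)
    # strict >: a value whose foreground posterior exactly ties another
    # component's is called negative
    pos = fg > others.max(axis=1) if others.size else np.ones(len(x), dtype=bool)
    return pos.astype(np.int8)


def combine_markers_or(calls) -> np.ndarray:
    """Overall positivity P_i = OR over markers of the binary calls C_ib."""
    mat = np.asarray(calls)
    if mat.ndim == 1:
        mat = mat[:, None]
    if mat.ndim != 2:
        raise ValueError("calls must be a (n_cells, n_markers) matrix")
    return (mat.astype(bool).any(axis=1)).astype(np.int8)


def label_ce_nce(table: CellTable, P: np.ndarray | None = None, *,
                 em_cfg: EMConfig | None = None,
                 markers: tuple[str, ...] = BASAL_MARKERS
                 ) -> tuple[CellTable, dict[str, MixtureFit]]:
    """Label every cell CE / N-CE / stroma from basal-marker positivity.

    When ``P`` is not supplied, a mixture is fitted per basal marker on the
    epithelial cells' log2 intensities, positivity is called per marker, and
    the calls are OR-combined. Epithelial cells with P=1 are N-CE (a basal
    marker is expressed), P=0 are CE; stromal cells are labeled "stroma".
    Returns the labeled table and the per-marker fits (empty dict when P was
    given).
    """
    df = table.df.copy()
    epi = df["compartment"] == "epithelial"
    fits: dict[str, MixtureFit] = {}
    if P is None:
        calls = []
        for m in markers:
            fit = fit_gmm_em(df.loc[epi, m].to_numpy(), em_cfg)
            fits[m] = fit
            c = classify_positive(df.loc[epi, m].to_numpy(), fit)
            df.loc[epi, f"call_{m}"] = c
            calls.append(c)
        P = combine_markers_or(np.column_stack(calls))
    P = np.asarray(P).ravel()
    if len(P) != int(epi.sum()):
        raise ValueError("P must have one call per epithelial cell")
    df["cell_label"] = "stroma"
    df.loc[epi, "cell_label"] = np.where(P == 1, "N-CE", "CE")
    out = table.copy()
    out.df = df
    return out, fits


#: priority order used when a cell satisfies several phenotype definitions
PHENOTYPE_PRIORITY = ("T_reg", "T_H", "macrophage")


def assign_immune_phenotypes(calls: pd.DataFrame, *,
                             th_excludes_treg: bool = True) -> pd.Series:
    """Map binary immune-marker calls to phenotypes.

    T_reg = CD3+ CD4+ FOXP3+; T_H = CD3+ CD4+ (FOXP3- when
    ``th_excludes_treg``, the default, so the two T-cell classes are
    disjoint); macrophage = CD68+ (and not a T cell); anything else is
    "other". Expects boolean/0-1 columns named CD3, CD4, CD8, CD68, FOXP3.
    """
    for col in ("CD3", "CD4", "CD68", "FOXP3"):
        if col not in calls.columns:
            raise SchemaError(f"immune call table is missing column {col!r}")
    cd3 = calls["CD3"].astype(bool)
    cd4 = calls["CD4"].astype(bool)
    cd68 = calls["CD68"].astype(bool)
    foxp3 = calls["FOXP3"].astype(bool)

    treg = cd3 & cd4 & foxp3
    th = cd3 & cd4 & (~foxp3 if th_excludes_treg else True)
    mac = cd68

    out = pd.Series("other", index=calls.index, dtype=object)
    out[mac] = "macrophage"
    out[th] = "T_H"
    out[treg] = "T_reg"
    return out
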