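"""t-SNE embedding and model-based (Gaussian mixture) clustering.

ILC events are embedded in 2-D by t-SNE on the identification/regulatory
marker set, then clustered by finite Gaussian mixtures fitted with EM under
six covariance parameterizations (spherical / diagonal / full, each equal or
varying across components):

====== ==========================================
family covariance structure (2-D)
====== ==========================================
EII    spherical, shared across components
VII    spherical, per component
EEI    diagonal, shared
VVI    diagonal, per component
EEE    full, shared
VVV    full, per component
====== ==========================================

The component count G and family are selected by maximizing
``BIC = 2 loglik - k log n`` over a grid (G = 1..9 by default, the search
the analysis is built around).  Clustering operates on the t-SNE coordinates,
not marker space (a marker-space mode exists but is not the default path).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .panel_io import EventMatrix
from .group_stats import unpaired_ttest

logger = logging.getLogger(__name__)

#: default embedding markers: the gate's identification markers (less CD45)
#: plus the regulatory/activation receptors read alongside them.
DEFAULT_EMBED_MARKERS = (
    "CD127", "CRTH2", "c-Kit", "NKp44", "CD56",
    "CD161", "NKp46", "NKp30", "CD69", "CCR6",
)

FAMILIES = ("EII", "VII", "EEI", "VVI", "EEE", "VVV")


@dataclass(frozen=True)
class EmbeddingConfig:
    markers_used: tuple[str, ...] = DEFAULT_EMBED_MARKERS
    perplexity: float = 30.0
    n_iterations: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.perplexity <= 0:
            raise ValueError("perplexity must be positive")


def tsne_embed(ilc_events: EventMatrix,
               cfg: EmbeddingConfig | None = None) -> np.ndarray:
    """2-D t-SNE of the configured markers; deterministic given the seed."""
    cfg = cfg or EmbeddingConfig()
    n = ilc_events.n_events
    if n < 3 * cfg.perplexity + 1:
        raise ValueError(
            f"t-SNE needs > 3*perplexity events: n={n}, "
            f"perplexity={cfg.perplexity}")
    missing = [m for m in cfg.markers_used
               if m not in ilc_events.data.columns]
    if missing:
        raise KeyError(f"embedding markers missing from events: {missing}")
    from sklearn.manifold import TSNE
    x = ilc_events.data[list(cfg.markers_used)].to_numpy(dtype=float)
    tsne = TSNE(
        n_components=2, perplexity=cfg.perplexity,
        max_iter=cfg.n_iterations, random_state=cfg.seed, init="pca",
    )
    return tsne.fit_transform(x)


def n_free_params(family: str, G: int, d: int = 2) -> int:
    """Free-parameter count: means (G d) + weights (G - 1) + covariances."""
    cov = {
        "EII": 1, "VII": G, "EEI": d, "VVI": G * d,
        "EEE": d * (d + 1) // 2, "VVV": G * d * (d + 1) // 2,
    }[family]
    return G * d + (G - 1) + cov


@dataclass
class GmmModel:
    """Fitted finite Gaussian mixture (results object).

    ``bic = 2 loglik - k_params log n`` (maximized in model selection).
    """

    family: str
    G: int
    weights: np.ndarray
    means: np.ndarray        # (G, d)
    covariances: np.ndarray  # (G, d, d), structured per family
    loglik: float
    bic: float
    n: int
    k_params: int
    n_iter: int = 0
    loglik_path: np.ndarray = field(default_factory=lambda: np.empty(0))

    def log_resp(self, x: np.ndarray) -> np.ndarray:
        lp = _log_prob(x, self.means, self.covariances) + np.log(self.weights)
        return lp - logsumexp(lp, axis=1, keepdims=True)

    def predict(self, x: np.ndarray) -> np.ndarray:
        """1-based component labels."""
        return np.argmax(self.log_resp(x), axis=1) + 1

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame({
            "component": np.arange(1, self.G + 1),
            "weight": self.weights,
            "mean_x": self.means[:, 0],
            "mean_y": self.means[:, 1],
        })


def _log_prob(x: np.ndarray, means: np.ndarray,
              covs: np.ndarray) -> np.ndarray:
    """(n, G) log N(x | mu_g, Sigma_g)."""
    n, d = x.shape
    G = means.shape[0]
    out = np.empty((n, G))
    for g in range(G):
        diff = x - means[g]
        chol = np.linalg.cholesky(covs[g])
        sol = np.linalg.solve(chol, diff.T)
        maha = (sol ** 2).sum(axis=0)
        logdet = 2.0 * np.log(np.diag(chol)).sum()
        out[:, g] = -0.5 * (d * np.log(2 * np.pi) + logdet + maha)
    return out


def _kmeanspp_centers(x: np.ndarray, G: int,
                      rng: np.random.Generator) -> np.ndarray:
    centers = [x[rng.integers(len(x))]]
    for _ in range(1, G):
        d2 = np.min(
            ((x[:, None, :] - np.asarray(centers)[None, :, :]) ** 2
             ).sum(-1), axis=1)
        probs = d2 / d2.sum() if d2.sum() > 0 else None
        centers.append(x[rng.choice(len(x), p=probs)])
    return np.asarray(centers)


def _m_step_cov(x: np.ndarray, resp: np.ndarray, means: np.ndarray,
                family: str, floor: float) -> np.ndarray:
    n, d = x.shape
    G = means.shape[0]
    nk = resp.sum(axis=0)
    scatters = np.empty((G, d, d))
    for g in range(G):
        diff = x - means[g]
        scatters[g] = (resp[:, g, None] * diff).T @ diff
    covs = np.empty((G, d, d))
    eye = np.eye(d)
    if family == "EII":
        s2 = scatters.trace(axis1=1, axis2=2).sum() / (n * d)
        covs[:] = max(s2, floor) * eye
    elif family == "VII":
        for g in range(G):
            s2 = scatters[g].trace() / (nk[g] * d)
            covs[g] = max(s2, floor) * eye
    elif family == "EEI":
        diagv = np.maximum(np.diagonal(scatters, axis1=1, axis2=2
                                       ).sum(axis=0) / n, floor)
        covs[:] = np.diag(diagv)
    elif family == "VVI":
        for g in range(G):
            diagv = np.maximum(np.diag(scatters[g]) / nk[g], floor)
            covs[g] = np.diag(diagv)
    elif family == "EEE":
        sigma = scatters.sum(axis=0) / n + floor * eye
        covs[:] = sigma
    elif family == "VVV":
        for g in range(G):
            covs[g] = scatters[g] / nk[g] + floor * eye
    else:
        raise ValueError(f"unknown family {family!r}")
    return covs


def gmm_fit(coords: np.ndarray, G: int, family: str = "VVV",
            seed: int = 0, max_iter: int = 500, tol: float = 1e-6,
            n_restarts: int = 5) -> GmmModel:
    """EM fit of a G-component structured Gaussian mixture.

    Initialization draws k-means++-style centers; EM runs to a log-likelihood
    change below ``tol`` or ``max_iter`` sweeps.  The log-likelihood is
    asserted non-decreasing at every step.  A degenerate fit (component
    collapse) is retried with up to ``n_restarts`` derived seeds before
    raising.
    """
    x = np.asarray(coords, dtype=float)
    if x.ndim != 2:
        raise ValueError("coords must be (n, d)")
    n, d = x.shape
    if n <= G * 3:
        raise ValueError(f"too few points ({n}) for G={G}")
    if family not in FAMILIES:
        raise ValueError(f"unknown family {family!r}")
    floor = 1e-8 * float(x.var(axis=0).mean() + 1e-300)
    last_err: Exception | None = None
    for attempt in range(n_restarts):
        rng = np.random.default_rng([seed, attempt])
        try:
            return _em_once(x, G, family, rng, max_iter, tol, floor)
        except _Degenerate as exc:
            last_err = exc
            continue
    raise RuntimeError(
        f"GMM fit degenerate after {n_restarts} restarts "
        f"(G={G}, family={family}): {last_err}")


class _Degenerate(RuntimeError):
    pass


def _em_once(x: np.ndarray, G: int, family: str, rng: np.random.Generator,
             max_iter: int, tol: float, floor: float) -> GmmModel:
    n, d = x.shape
    means = _kmeanspp_centers(x, G, rng)
    # hard-assignment initialization from nearest centers
    d2 = ((x[:, None, :] - means[None, :, :]) ** 2).sum(-1)
    resp = np.zeros((n, G))
    resp[np.arange(n), d2.argmin(axis=1)] = 1.0
    resp = np.maximum(resp, 1e-10)
    resp /= resp.sum(axis=1, keepdims=True)

    loglik_prev = -np.inf
    path = []
    for it in range(max_iter):
        nk = resp.sum(axis=0)
        if (nk < 1.0) .any():
            raise _Degenerate(f"empty component at iter {it}")
        weights = nk / n
        means = (resp.T @ x) / nk[:, None]
        covs = _m_step_cov(x, resp, means, family, floor)
        try:
            lp = _log_prob(x, means, covs) + np.log(weights)
        except np.linalg.LinAlgError as exc:
            raise _Degenerate(f"covariance collapse at iter {it}") from exc
        norm = logsumexp(lp, axis=1)
        loglik = float(norm.sum())
        path.append(loglik)
        if loglik < loglik_prev - 1e-6 * max(1.0, abs(loglik_prev)):
            raise AssertionError(
                f"EM decreased log-likelihood: {loglik_prev} -> {loglik}")
        resp = np.exp(lp - norm[:, None])
        if loglik - loglik_prev < tol and it > 0:
            loglik_prev = loglik
            break
        loglik_prev = loglik
    k = n_free_params(family, G, d)
    bic = 2.0 * loglik_prev - k * np.log(n)
    return GmmModel(
        family=family, G=G, weights=weights, means=means, covariances=covs,
        loglik=loglik_prev, bic=float(bic), n=n, k_params=k,
        n_iter=len(path), loglik_path=np.asarray(path),
    )


_FAMILY_COMPLEXITY = {f: i for i, f in enumerate(
    ("EII", "EEI", "VII", "EEE", "VVI", "VVV"))}


def bic_select(coords: np.ndarray, G_range=range(1, 10),
               families=FAMILIES, seed: int = 0,
               ) -> tuple[GmmModel, pd.DataFrame]:
    """Fit every (G, family) pair; return the max-BIC model and the table.

    Ties break toward smaller G, then the simpler family.  Degenerate fits
    are recorded with a failure flag; all fits failing is a hard error.
    """
    rows = []
    best: GmmModel | None = None
    for G in G_range:
        for fam in families:
            try:
                model = gmm_fit(coords, G, fam, seed=seed)
            except (RuntimeError, ValueError) as exc:
                rows.append({"G": G, "family": fam, "bic": np.nan,
                             "loglik": np.nan, "k_params": np.nan,
                             "failed": True})
                logger.warning("GMM G=%d %s failed: %s", G, fam, exc)
                continue
            rows.append({"G": G, "family": fam, "bic": model.bic,
                         "loglik": model.loglik,
                         "k_params": model.k_params, "failed": False})
            if best is None or model.bic > best.bic + 1e-9 or (
                abs(model.bic - best.bic) <= 1e-9
                and (model.G, _FAMILY_COMPLEXITY[model.family])
                < (best.G, _FAMILY_COMPLEXITY[best.family])
            ):
                best = model
    if best is None:
        raise RuntimeError("all GMM fits degenerate")
    return best, pd.DataFrame(rows)


@dataclass
class ClusterAssignment:
    """Per-event 1-based cluster ids with provenance model."""

    cluster_id: np.ndarray
    model: GmmModel

    @property
    def G(self) -> int:
        return self.model.G


def cluster_composition(assign: ClusterAssignment,
                        labels: np.ndarray) -> pd.DataFrame:
    """G x phenotype count table plus per-cluster fractions."""
    labels = np.asarray(labels)
    if labels.shape[0] != assign.cluster_id.shape[0]:
        raise ValueError("assignment and labels have different lengths")
    df = pd.DataFrame({"cluster": assign.cluster_id, "phenotype": labels})
    counts = (df.groupby(["cluster", "phenotype"]).size()
              .unstack(fill_value=0)
              .reindex(range(1, assign.G + 1), fill_value=0))
    frac = counts.div(counts.sum(axis=1).replace(0, 1), axis=0)
    frac.columns = [f"frac_{c}" for c in frac.columns]
    return pd.concat([counts, frac], axis=1)


def per_sample_cluster_fractions(assign: ClusterAssignment,
                                 sample_ids: np.ndarray) -> pd.DataFrame:
    """Rows = samples, columns = clusters, values = fraction of the sample's
    ILC events in each cluster."""
    df = pd.DataFrame({"cluster": assign.cluster_id,
                       "sample_id": np.asarray(sample_ids)})
    counts = (df.groupby(["sample_id", "cluster"]).size()
              .unstack(fill_value=0)
              .reindex(columns=range(1, assign.G + 1), fill_value=0))
    return counts.div(counts.sum(axis=1), axis=0)


def cluster_stage_association(fractions: pd.DataFrame,
                              stages: pd.Series) -> pd.DataFrame:
    """Per-cluster unpaired t-test of sample-level fractions, T2 vs >=T3."""
    stages = stages.reindex(fractions.index)
    grp_a = stages == "T2"
    grp_b = stages.isin(["T3", "T4"]) | (stages == ">=T3")
    if grp_a.sum() < 2 or grp_b.sum() < 2:
        raise ValueError("need >= 2 samples per stage group")
    rows = []
    for cl in fractions.columns:
        res = unpaired_ttest(fractions.loc[grp_a, cl],
                             fractions.loc[grp_b, cl])
        rows.append({"cluster": cl, "t": res.t_statistic, "df": res.df,
                     "p_value": res.p_value, "mean_T2": res.mean_a,
                     "mean_T3plus": res.mean_b})
    return pd.DataFrame(rows)
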