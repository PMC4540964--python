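"""Maximum-likelihood fitting of trait-evolution models on painted trees.

Three model families share one machinery:

* **BM** (random drift): ``dX = sigma dB(t)``; tip covariance grows linearly
  with shared root-to-MRCA path length.  Parameters ``x0, sigma_sq`` (k=2).
* **M0** (stabilizing selection, one optimum): Ornstein-Uhlenbeck
  ``dX = alpha (theta - X) dt + sigma dB(t)`` with a single optimum theta on
  every branch.  Parameters ``alpha, sigma_sq, theta`` (k=3).
* **Branch-shift (Hansen)**: as M0 but the ``shift``-painted branches carry
  their own optimum ``theta_shift``.  Parameters ``alpha, sigma_sq,
  theta_base, theta_shift`` (k=4).

The root state is pinned to the root regime's optimum (it is not a free
parameter), so the likelihood-ratio between a branch-shift model and M0 has
one degree of freedom.  The process starts at the root with zero variance.

Under those conventions the tip trait vector is multivariate normal with

    E[X_i]   = x0 e^{-alpha s_i}
               + sum_b theta_b (e^{-alpha (s_i - t_end(b))}
                                - e^{-alpha (s_i - t_start(b))})
    V_ij     = sigma^2 / (2 alpha) * e^{-alpha (s_i + s_j - 2 t_ij)}
               * (1 - e^{-2 alpha t_ij})

where ``s_i`` is the root-to-tip distance, the sum runs over the branches
on the root-to-tip path, and ``t_ij`` is the root-to-MRCA distance of tips
i and j.  As ``alpha -> 0`` this degenerates smoothly to BM (``expm1`` keeps
the evaluation stable, no explicit series switch is needed).

For a fixed alpha the tip means are linear in the optima, so the optima are
solved by generalized least squares and sigma^2 in closed form; the profile
likelihood is then maximized over alpha by a log-spaced grid scan refined
with bounded Brent search.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.linalg import cho_factor, cho_solve

from .phylo import BASE, SHIFT, PhyloTree, RegimePainting

__all__ = [
    "OUParams",
    "BMParams",
    "ModelFit",
    "bm_loglik",
    "hansen_loglik",
    "fit_model",
    "fit_region",
    "fit_table",
    "fits_frame",
    "ALPHA_MIN",
]

ALPHA_MIN = 1e-8
_SIGMA_FLOOR = 1e-12
_GRID_SIZE = 17


@dataclass(frozen=True)
class OUParams:
    """Ornstein-Uhlenbeck / Hansen parameters.

    ``theta`` maps regime label (``"base"``/``"shift"``) to its optimum.
    ``x0`` is the root state; None pins it to the root regime's optimum
    (the package convention).
    """

    alpha: float
    sigma_sq: float
    theta: Mapping[str, float]
    x0: float | None = None

    def __post_init__(self):
        if self.alpha <= 0:
            raise ValueError("alpha must be > 0 for OU; use BMParams for alpha = 0")
        if self.sigma_sq <= 0:
            raise ValueError("sigma_sq must be > 0")


@dataclass(frozen=True)
class BMParams:
    x0: float
    sigma_sq: float

    def __post_init__(self):
        if self.sigma_sq <= 0:
            raise ValueError("sigma_sq must be > 0")


@dataclass
class ModelFit:
    """A fitted model for one region.

    ``status`` is ``"ok"``, ``"degenerate"`` (near-constant trait,
    sigma^2 floored) or ``"untestable"`` (all tips of one regime missing
    from the trait; parameters are NaN and the fit carries no likelihood).
    """

    model: str
    kind: str  # "bm" | "ou"
    alpha: float
    sigma_sq: float
    theta_base: float
    theta_shift: float
    x0: float
    loglik: float
    k: int
    aic: float
    n_tips: int
    status: str = "ok"

    @property
    def ok(self) -> bool:
        return self.status in ("ok", "degenerate")

    @property
    def has_shift(self) -> bool:
        return not math.isnan(self.theta_shift)


# ---------------------------------------------------------------------------
# Tree -> matrix structure
# ---------------------------------------------------------------------------


class _Design:
    """Per-(tree, painting, tip order) geometry, cached across regions.

    Holds tip depths, the root-to-MRCA depth matrix, and per-branch path
    segments (start/end times + regime index) used to assemble the OU mean
    weight matrix for any alpha.  Structure factorizations are memoized per
    alpha so that grid scans are shared across many trait vectors.
    """

    def __init__(self, tree: PhyloTree, painting: RegimePainting,
                 tip_order: Sequence[str]):
        self.tree = tree
        self.painting = painting
        self.tips = list(tip_order)
        self.n = len(self.tips)
        self.height = tree.height

        tipnodes = [tree.tip(t) for t in self.tips]
        self.s = np.array([t.time for t in tipnodes])

        # root-to-MRCA depths via ancestor paths
        paths = []
        for node in tipnodes:
            anc = []
            cur = node
            while cur is not None:
                anc.append(cur)
                cur = cur.parent
            paths.append(anc[::-1])  # root first
        T = np.zeros((self.n, self.n))
        for i in range(self.n):
            T[i, i] = self.s[i]
            for j in range(i + 1, self.n):
                shared = 0.0
                for a, b in zip(paths[i], paths[j]):
                    if a is b:
                        shared = a.time
                    else:
                        break
                T[i, j] = T[j, i] = shared
        self.T = T

        # regimes: base first (index 0); shift second when present
        labels = [BASE]
        if painting.has_shift:
            labels.append(SHIFT)
        self.regime_labels = labels
        self.n_regimes = len(labels)
        self.root_regime_idx = labels.index(painting.root_regime) \
            if painting.root_regime in labels else 0

        seg_tip, seg_t0, seg_t1, seg_reg = [], [], [], []
        for i, node in enumerate(tipnodes):
            cur = node
            while cur.parent is not None:
                reg = painting.regime_of(tree.branch_id(cur))
                seg_tip.append(i)
                seg_t0.append(cur.parent.time)
                seg_t1.append(cur.time)
                seg_reg.append(labels.index(reg) if reg in labels else 0)
                cur = cur.parent
        self._seg_tip = np.array(seg_tip, dtype=int)
        self._seg_t0 = np.array(seg_t0)
        self._seg_t1 = np.array(seg_t1)
        self._seg_reg = np.array(seg_reg, dtype=int)

        self._cache: dict[float, tuple] = {}

    # -- OU pieces ---------------------------------------------------

    def mean_weights(self, alpha: float) -> np.ndarray:
        """n x r matrix W with E[X] = W @ theta (x0 pinned to root regime)."""
        s = self.s
        W = np.zeros((self.n, self.n_regimes))
        w = (np.exp(-alpha * (s[self._seg_tip] - self._seg_t1))
             - np.exp(-alpha * (s[self._seg_tip] - self._seg_t0)))
        np.add.at(W, (self._seg_tip, self._seg_reg), w)
        W[:, self.root_regime_idx] += np.exp(-alpha * s)
        return W

    def ou_cov_unit(self, alpha: float) -> np.ndarray:
        """Tip covariance for sigma^2 = 1."""
        s, T = self.s, self.T
        return (np.exp(-alpha * (s[:, None] + s[None, :] - 2.0 * T))
                * (-np.expm1(-2.0 * alpha * T)) / (2.0 * alpha))

    def structure(self, alpha: float | None) -> tuple:
        """(cho, logdet, W) for OU at ``alpha``; BM when ``alpha`` is None."""
        key = -1.0 if alpha is None else alpha
        hit = self._cache.get(key)
        if hit is not None:
            return hit
        if alpha is None:
            V0 = self.T
            W = np.ones((self.n, 1))
        else:
            V0 = self.ou_cov_unit(alpha)
            W = self.mean_weights(alpha)
        try:
            cho = cho_factor(V0, lower=True)
        except np.linalg.LinAlgError as exc:
            raise ValueError(
                "singular tip covariance (coincident tips or zero-length "
                "branches); jitter the branch lengths"
            ) from exc
        logdet = 2.0 * float(np.sum(np.log(np.diag(cho[0]))))
        out = (cho, logdet, W)
        if len(self._cache) < 256:
            self._cache[key] = out
        return out


def _gls(y: np.ndarray, cho, logdet: float, W: np.ndarray):
    """GLS optima + closed-form ML sigma^2 + profile log-likelihood."""
    n = y.size
    Vi_y = cho_solve(cho, y)
    Vi_W = cho_solve(cho, W)
    A = W.T @ Vi_W
    b = W.T @ Vi_y
    try:
        theta = np.linalg.solve(A, b)
    except np.linalg.LinAlgError:
        theta = np.linalg.lstsq(A, b, rcond=None)[0]
    resid = y - W @ theta
    rss = float(resid @ cho_solve(cho, resid))
    rss = max(rss, 0.0)
    sigma_sq = rss / n
    degenerate = sigma_sq < _SIGMA_FLOOR
    if degenerate:
        sigma_sq = _SIGMA_FLOOR
    quad = rss / sigma_sq
    loglik = -0.5 * (n * math.log(2.0 * math.pi) + n * math.log(sigma_sq)
                     + logdet + quad)
    return theta, sigma_sq, loglik, degenerate


# ---------------------------------------------------------------------------
# Likelihoods at fixed parameters
# ---------------------------------------------------------------------------


def _as_series(trait) -> pd.Series:
    s = pd.Series(trait, dtype=float)
    return s[s.notna()]


def _prep(tree: PhyloTree, painting: RegimePainting, trait, min_tips: int = 2):
    """Align trait with tree (pruning missing tips), re-derive painting."""
    s = _as_series(trait)
    if not np.isfinite(s.to_numpy()).all():
        raise ValueError("trait values must be finite")
    unknown = set(s.index) - set(tree.tip_labels)
    if unknown:
        raise ValueError(f"trait tips not in tree: {sorted(unknown)}")
    tips = [t for t in tree.tip_labels if t in s.index]
    if len(tips) < min_tips:
        raise ValueError(f"need trait values for at least {min_tips} tips")
    if len(tips) < tree.n_tips:
        tree = tree.prune(tips)
        painting = painting.rederive(tree)
    return tree, painting, s.reindex(tips)


def _mvn_loglik(y, mean, V):
    cho = cho_factor(V, lower=True)
    logdet = 2.0 * float(np.sum(np.log(np.diag(cho[0]))))
    r = y - mean
    quad = float(r @ cho_solve(cho, r))
    return -0.5 * (y.size * math.log(2.0 * math.pi) + logdet + quad)


def bm_loglik(tree: PhyloTree, trait, x0: float, sigma_sq: float) -> float:
    """Brownian-motion log-likelihood: MVN with mean ``x0`` and covariance
    ``sigma_sq * (shared root-to-MRCA path length)``."""
    if sigma_sq <= 0:
        raise ValueError("sigma_sq must be > 0")
    from .phylo import bm_painting
    tree, painting, s = _prep(tree, bm_painting(tree), trait)
    design = _Design(tree, painting, list(s.index))
    y = s.to_numpy()
    try:
        return _mvn_loglik(y, np.full(y.size, x0), sigma_sq * design.T)
    except np.linalg.LinAlgError as exc:
        raise ValueError(
            "singular BM covariance (duplicate zero-depth tips); jitter the "
            "branch lengths"
        ) from exc


def hansen_loglik(tree: PhyloTree, painting: RegimePainting, trait,
                  params: OUParams) -> float:
    """OU/Hansen log-likelihood on a painted tree at fixed parameters."""
    if params.alpha <= 0:
        raise ValueError("alpha must be > 0; use bm_loglik for alpha = 0")
    tree, painting, s = _prep(tree, painting, trait)
    design = _Design(tree, painting, list(s.index))
    y = s.to_numpy()
    theta_vec = np.array([params.theta[lab] for lab in design.regime_labels])
    W = design.mean_weights(params.alpha)
    mean = W @ theta_vec
    if params.x0 is not None:
        root_theta = theta_vec[design.root_regime_idx]
        mean += (params.x0 - root_theta) * np.exp(-params.alpha * design.s)
    V = params.sigma_sq * design.ou_cov_unit(params.alpha)
    return _mvn_loglik(y, mean, V)


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------


def _profile_ou(design: _Design, y: np.ndarray, alpha_seeds: Iterable[float] = ()):
    """Maximize the alpha-profile likelihood: grid scan + Brent refinement."""
    lo = ALPHA_MIN
    hi = max(100.0 / design.height, 10.0 * lo)
    grid = np.geomspace(lo, hi, _GRID_SIZE)

    def nll_log(lna: float) -> float:
        cho, logdet, W = design.structure(math.exp(lna))
        return -_gls(y, cho, logdet, W)[2]

    evals: list[tuple[float, float]] = []  # (loglik, alpha)
    for a in grid:
        evals.append((-nll_log(math.log(a)), a))
    best_ll, best_a = max(evals)
    i = int(np.argmin(np.abs(grid - best_a)))
    brackets = [(grid[max(i - 1, 0)], grid[min(i + 1, grid.size - 1)])]
    for seed in alpha_seeds:
        if np.isfinite(seed) and seed > 0:
            brackets.append((max(lo, seed / 4.0), min(hi, seed * 4.0)))
    for blo, bhi in brackets:
        if bhi <= blo:
            continue
        res = optimize.minimize_scalar(
            nll_log, bounds=(math.log(blo), math.log(bhi)), method="bounded",
            options={"xatol": 1e-6},
        )
        evals.append((-float(res.fun), math.exp(float(res.x))))
    best_ll, best_a = max(evals)
    cho, logdet, W = design.structure(best_a)
    theta, sigma_sq, loglik, degenerate = _gls(y, cho, logdet, W)
    return best_a, theta, sigma_sq, loglik, degenerate


def _nan_fit(model: str, kind: str, n: int, status: str) -> ModelFit:
    nan = float("nan")
    return ModelFit(model, kind, nan, nan, nan, nan, nan, nan,
                    2 if kind == "bm" else 0, nan, n, status)


def fit_model(tree: PhyloTree, painting: RegimePainting, trait,
              alpha_seeds: Iterable[float] = ()) -> ModelFit:
    """ML fit of the painted model to one trait vector.

    Missing tips are pruned (regimes re-derived on the pruned tree).  If a
    branch-shift painting loses all of its shift (or base) tips the result
    has ``status="untestable"`` rather than raising.  ``alpha_seeds`` adds
    refinement brackets around externally suggested alphas (e.g. the M0
    fit's alpha-hat), which also guarantees the nesting inequality
    ``loglik(Mx) >= loglik(M0)`` in practice.
    """
    original_shift = painting.shift_tips
    shift_model = painting.kind == "ou" and painting.has_shift
    tree, painting, s = _prep(tree, painting, trait, min_tips=3)
    y = s.to_numpy()
    n = y.size
    tipset = frozenset(s.index)

    if shift_model:
        in_shift = tipset & original_shift
        if not in_shift or in_shift == tipset:
            return _nan_fit(painting.model_id, "ou", n, "untestable")

    design = _Design(tree, painting, list(s.index))

    if painting.kind == "bm":
        cho, logdet, W = design.structure(None)
        theta, sigma_sq, loglik, degenerate = _gls(y, cho, logdet, W)
        k = 2
        fit = ModelFit(painting.model_id, "bm", 0.0, sigma_sq, float("nan"),
                       float("nan"), float(theta[0]), loglik, k,
                       2 * k - 2 * loglik, n,
                       "degenerate" if degenerate else "ok")
        return fit

    alpha, theta, sigma_sq, loglik, degenerate = _profile_ou(design, y, alpha_seeds)
    theta_map = dict(zip(design.regime_labels, theta))
    theta_base = float(theta_map.get(BASE, theta[0]))
    theta_shift = float(theta_map[SHIFT]) if SHIFT in theta_map else float("nan")
    k = 3 + (1 if painting.has_shift else 0)
    x0 = float(theta[design.root_regime_idx])
    return ModelFit(painting.model_id, "ou", float(alpha), float(sigma_sq),
                    theta_base, theta_shift, x0, float(loglik), k,
                    2 * k - 2 * float(loglik), n,
                    "degenerate" if degenerate else "ok")


def fit_region(tree: PhyloTree, trait, paintings: Sequence[RegimePainting]
               ) -> dict[str, ModelFit]:
    """Fit several paintings to one trait; M0's alpha-hat (when present)
    seeds the branch-shift refinements."""
    by_id = {p.model_id: p for p in paintings}
    fits: dict[str, ModelFit] = {}
    seeds: list[float] = []
    if "M0" in by_id:
        fits["M0"] = fit_model(tree, by_id["M0"], trait)
        if fits["M0"].ok:
            seeds = [fits["M0"].alpha]
    for p in paintings:
        if p.model_id in fits:
            continue
        fits[p.model_id] = fit_model(tree, p, trait, alpha_seeds=seeds)
    return fits


def fit_table(tree: PhyloTree, traits: pd.DataFrame,
              paintings: Sequence[RegimePainting]
              ) -> dict[str, dict[str, ModelFit]]:
    """Fit all paintings to every row (region) of a trait table.

    ``traits``: rows = regions, columns = species, NaN = missing ortholog.
    """
    return {str(region): fit_region(tree, row, paintings)
            for region, row in traits.iterrows()}


def fits_frame(region_fits: Mapping[str, Mapping[str, ModelFit]]) -> pd.DataFrame:
    """Flatten nested {region: {model: ModelFit}} into a tidy DataFrame."""
    rows = []
    for region, fits in region_fits.items():
        for model, f in fits.items():
            rows.append({
                "region": region, "model": model, "kind": f.kind,
                "alpha": f.alpha, "sigma_sq": f.sigma_sq,
                "theta_base": f.theta_base, "theta_shift": f.theta_shift,
                "x0": f.x0, "loglik": f.loglik, "k": f.k, "aic": f.aic,
                "n_tips": f.n_tips, "status": f.status,
            })
    return pd.DataFrame(rows)
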