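"""Model comparison: likelihood-ratio tests, Akaike weights, divergence
calls with gain/loss direction, and multiple-testing adjustment.

The default comparison is pairwise — each branch-shift model Mx against
the single-optimum model M0 — using Akaike weights (a region is divergent
under Mx iff wAIC(Mx) > wAIC(M0), i.e. > 0.5 of the pair, with ties broken
toward the simpler M0).  The "triple" (BM / M0 / Mx) and "all" modes pick
the argmax-weight model and are more stringent.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2
from statsmodels.stats.multitest import multipletests

from .oufit import ModelFit

__all__ = [
    "DivergenceCall",
    "lr_test",
    "lr_pvalue",
    "akaike_weights",
    "classify_direction",
    "call_divergence",
    "call_table",
    "bh_adjust",
    "calls_frame",
    "filter_by_max_score",
    "MODES",
]

MODES = ("pairwise", "triple", "all")
_THETA_TIE = 1e-9


@dataclass
class DivergenceCall:
    model: str  # the branch-shift model being called (or the winner)
    mode: str
    waic: dict[str, float]  # weight per compared model
    divergent: bool
    direction: str | None = None  # "gain" | "loss" | "indeterminate" | None
    lr: float | None = None
    p: float | None = None
    region: str | None = None
    pwm: str | None = None
    #: AIC evidence margin of the called model over its best competitor
    #: (AIC_competitor - AIC_model); > 0 iff the call is divergent.  Kept in
    #: the divergence database as a strength summary because Akaike weights
    #: saturate at 1 for strong signals.
    aic_margin: float | None = None


def lr_pvalue(lr: float) -> float:
    """Upper chi-square(1) tail of a (non-negative) LR statistic."""
    if lr < 0:
        raise ValueError("LR must be >= 0")
    return float(chi2.sf(lr, df=1))


def _loglik(fit) -> float:
    return fit.loglik if isinstance(fit, ModelFit) else float(fit)


def lr_test(fit_null, fit_alt) -> tuple[float, float]:
    """LR = 2(loglik_alt - loglik_null), clipped at 0, with its
    chi-square(1) upper-tail p-value.

    Accepts :class:`ModelFit` objects (checked for nesting: M0 within a
    branch-shift model; BM is not nested in this parameterization) or raw
    log-likelihoods.
    """
    if isinstance(fit_null, ModelFit) and isinstance(fit_alt, ModelFit):
        if fit_null.kind == "bm" or fit_alt.kind == "bm" or fit_null.has_shift:
            raise ValueError(
                "models are not nested (expected M0 as null and a "
                "branch-shift model as alternative); use akaike_weights for "
                "non-nested comparisons")
    ll0, ll1 = _loglik(fit_null), _loglik(fit_alt)
    if ll1 < ll0 - 1e-6:
        raise ValueError(
            f"alternative log-likelihood ({ll1:.6f}) is below the null "
            f"({ll0:.6f}) beyond numerical tolerance; models may not be nested")
    lr = max(0.0, 2.0 * (ll1 - ll0))
    return lr, lr_pvalue(lr)


def akaike_weights(aics: Sequence[float]) -> np.ndarray:
    """w_i = exp(-Delta_i / 2) / sum_r exp(-Delta_r / 2),
    Delta_i = AIC_i - min AIC (shifted for numerical stability)."""
    a = np.asarray(list(aics), dtype=float)
    if a.size < 2:
        raise ValueError("need at least 2 AIC values")
    if not np.all(np.isfinite(a)):
        raise ValueError("all AIC values must be finite")
    d = a - a.min()
    w = np.exp(-0.5 * d)
    return w / w.sum()


def classify_direction(fit: ModelFit) -> str:
    """gain iff theta_shift > theta_base; near-ties are indeterminate."""
    if not fit.has_shift:
        raise ValueError("direction is defined only for branch-shift fits")
    diff = fit.theta_shift - fit.theta_base
    if abs(diff) < _THETA_TIE:
        return "indeterminate"
    return "gain" if diff > 0 else "loss"


def bh_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(list(pvals), dtype=float)
    if p.size == 0:
        return p
    if np.any(p < 0) or np.any(p > 1) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _usable(fits: Mapping[str, ModelFit]) -> dict[str, ModelFit]:
    return {m: f for m, f in fits.items() if f.ok}


def call_divergence(fits: Mapping[str, ModelFit], mode: str = "pairwise",
                    region: str | None = None, pwm: str | None = None
                    ) -> list[DivergenceCall]:
    """Compare fitted models for one region.

    ``pairwise``: one call per branch-shift model Mx, each weighted against
    M0 alone.  ``triple``: one call per Mx over {BM, M0, Mx}.  ``all``: a
    single call over every supplied model, winner = argmax weight (ties
    broken toward fewer parameters).  Untestable fits are skipped.
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")
    fits = _usable(fits)
    if "M0" not in fits:
        raise ValueError("an M0 (single-optimum) fit is required")
    m0 = fits["M0"]
    shift_models = [m for m, f in fits.items() if f.has_shift]

    calls: list[DivergenceCall] = []
    if mode == "pairwise":
        for mx in shift_models:
            fx = fits[mx]
            w = akaike_weights([fx.aic, m0.aic])
            divergent = w[0] > 0.5  # exact tie -> not divergent (simpler M0)
            lr, p = lr_test(m0, fx)
            calls.append(DivergenceCall(
                mx, mode, {mx: float(w[0]), "M0": float(w[1])}, bool(divergent),
                classify_direction(fx) if divergent else None,
                lr, p, region, pwm, float(m0.aic - fx.aic)))
        return calls

    if mode == "triple":
        if "BM" not in fits:
            raise ValueError("triple mode needs a BM fit")
        bm = fits["BM"]
        for mx in shift_models:
            fx = fits[mx]
            models = [mx, "M0", "BM"]
            aics = [fx.aic, m0.aic, bm.aic]
            w = akaike_weights(aics)
            order = sorted(range(3), key=lambda i: (-w[i], fits[models[i]].k))
            winner = models[order[0]]
            divergent = winner == mx
            others = [a for m, a in zip(models, aics) if m != mx]
            calls.append(DivergenceCall(
                mx, mode, dict(zip(models, map(float, w))), bool(divergent),
                classify_direction(fx) if divergent else None,
                None, None, region, pwm, float(min(others) - fx.aic)))
        return calls

    # mode == "all"
    models = list(fits)
    w = akaike_weights([fits[m].aic for m in models])
    order = sorted(range(len(models)),
                   key=lambda i: (-w[i], fits[models[i]].k, models[i]))
    winner = models[order[0]]
    fw = fits[winner]
    divergent = fw.has_shift
    others = [fits[m].aic for m in models if m != winner]
    margin = float(min(others) - fw.aic) if others else None
    calls.append(DivergenceCall(
        winner, mode, dict(zip(models, map(float, w))), bool(divergent),
        classify_direction(fw) if divergent else None,
        None, None, region, pwm, margin))
    return calls


def call_table(region_fits: Mapping[str, Mapping[str, ModelFit]],
               mode: str = "pairwise", pwm: str | None = None
               ) -> list[DivergenceCall]:
    """Run :func:`call_divergence` over every region of a fit table."""
    calls: list[DivergenceCall] = []
    for region, fits in region_fits.items():
        calls.extend(call_divergence(fits, mode=mode, region=region, pwm=pwm))
    return calls


def calls_frame(calls: Iterable[DivergenceCall],
                adjust_bh: bool = False) -> pd.DataFrame:
    """Tidy DataFrame of calls; optionally BH-adjust the LR p-values across
    all rows (regions x models)."""
    rows = []
    for c in calls:
        rows.append({
            "region": c.region, "pwm": c.pwm, "model": c.model, "mode": c.mode,
            "waic_model": c.waic.get(c.model, np.nan),
            "waic_M0": c.waic.get("M0", np.nan),
            "lr": c.lr, "p": c.p, "divergent": c.divergent,
            "direction": c.direction,
        })
    df = pd.DataFrame(rows)
    if adjust_bh and len(df) and df["p"].notna().all():
        df["p_bh"] = bh_adjust(df["p"].to_numpy())
    return df


def filter_by_max_score(calls: Iterable[DivergenceCall],
                        score_matrix: pd.DataFrame,
                        min_score: float) -> list[DivergenceCall]:
    """Optional filter: keep calls only for regions whose maximum tip CRM
    score reaches ``min_score`` in at least one species (off by default in
    the pipelines; the Glass case study used a threshold of 6)."""
    maxima = score_matrix.max(axis=1)
    keep = set(maxima.index[maxima >= min_score].astype(str))
    return [c for c in calls if c.region in keep]
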