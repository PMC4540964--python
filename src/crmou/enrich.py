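"""Divergent-motif discovery by hypergeometric overlap.

An input set of experimentally divergent regions (from cross-species
ChIP-Seq, STARR-Seq or FAIRE-Seq) is intersected with every predicted
divergent-region set — one per (PWM, model, direction) — and scored with an
upper-tail hypergeometric test on a fixed region universe, Bonferroni
corrected over all performed tests.  Parameters follow the usual naming:
N = universe size, n = input-set size, K = predicted-set size, k = overlap.
"""
from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .select import DivergenceCall

__all__ = [
    "EnrichmentResult",
    "DivergenceDB",
    "hypergeom_test",
    "overlap_test",
    "discover_motifs",
    "results_frame",
    "select_divergent_chip",
    "select_divergent_starr",
]


@dataclass(frozen=True)
class EnrichmentResult:
    pwm: str
    model: str
    direction: str
    N: int
    n: int
    K: int
    k: int
    p: float
    p_adj: float
    rank: int | None = None


def hypergeom_test(N: int, K: int, n: int, k: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n), computed in log space."""
    for name, v in (("N", N), ("K", K), ("n", n), ("k", k)):
        if int(v) != v or v < 0:
            raise ValueError(f"{name} must be a non-negative integer")
    N, K, n, k = int(N), int(K), int(n), int(k)
    if K > N or n > N or k > min(n, K):
        raise ValueError(
            f"arguments must satisfy 0 <= k <= min(n, K) <= N "
            f"(got N={N}, K={K}, n={n}, k={k})")
    if k == 0:
        return 1.0
    p = float(np.exp(hypergeom.logsf(k - 1, N, K, n)))
    return min(p, 1.0)


def overlap_test(set_a: Iterable, set_b: Iterable, N: int,
                 pwm: str = "", model: str = "", direction: str = ""
                 ) -> EnrichmentResult:
    """Single overlap test: n = |a|, K = |b|, k = |a & b|."""
    a, b = set(set_a), set(set_b)
    p = hypergeom_test(N, len(b), len(a), len(a & b))
    return EnrichmentResult(pwm, model, direction, int(N), len(a), len(b),
                            len(a & b), p, min(1.0, p))


@dataclass
class DivergenceDB:
    """Predicted divergent-region sets, one per (PWM, model, direction).

    Besides the region ids, each set keeps the per-region AIC evidence
    margin of its call (when available): Akaike weights saturate at 1 for
    strong signals, so the margin is the only graded strength summary left,
    and it breaks exact ties between overlap tests (e.g. a gain in one
    clade versus the near-complementary loss)."""

    sets: dict[tuple[str, str, str], frozenset[str]] = field(default_factory=dict)
    universe: frozenset[str] | None = None
    margins: dict[tuple[str, str, str], dict[str, float]] = field(
        default_factory=dict)

    @classmethod
    def from_calls(cls, calls: Iterable[DivergenceCall],
                   universe: Iterable[str] | None = None) -> "DivergenceDB":
        sets: dict[tuple[str, str, str], set[str]] = {}
        margins: dict[tuple[str, str, str], dict[str, float]] = {}
        for c in calls:
            if not c.divergent or c.region is None:
                continue
            direction = c.direction or "indeterminate"
            key = (c.pwm or "", c.model, direction)
            sets.setdefault(key, set()).add(c.region)
            if c.aic_margin is not None:
                margins.setdefault(key, {})[c.region] = float(c.aic_margin)
        return cls({k: frozenset(v) for k, v in sets.items()},
                   frozenset(universe) if universe is not None else None,
                   margins)

    def mean_margin(self, key: tuple[str, str, str]) -> float:
        vals = self.margins.get(key)
        if not vals:
            return float("-inf")
        return float(np.mean(list(vals.values())))

    def save(self, directory) -> None:
        """One text file per (PWM, model, direction): region id per line,
        with the call's AIC margin as an optional second column."""
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        for (pwm, model, direction), ids in sorted(self.sets.items()):
            key = (pwm, model, direction)
            marg = self.margins.get(key, {})
            lines = []
            for rid in sorted(ids):
                if rid in marg:
                    lines.append(f"{rid}\t{marg[rid]:.6g}")
                else:
                    lines.append(rid)
            name = f"{pwm}__{model}__{direction}.ids.txt"
            (d / name).write_text("\n".join(lines) + "\n")
        if self.universe is not None:
            (d / "universe.txt").write_text(
                "\n".join(sorted(self.universe)) + "\n")

    @classmethod
    def load(cls, directory) -> "DivergenceDB":
        d = Path(directory)
        sets = {}
        margins: dict[tuple[str, str, str], dict[str, float]] = {}
        universe = None
        for path in sorted(d.glob("*.ids.txt")):
            pwm, model, direction = path.name[:-len(".ids.txt")].split("__")
            key = (pwm, model, direction)
            ids = set()
            for line in filter(None, path.read_text().splitlines()):
                fields = line.split("\t")
                ids.add(fields[0])
                if len(fields) > 1:
                    margins.setdefault(key, {})[fields[0]] = float(fields[1])
            sets[key] = frozenset(ids)
        upath = d / "universe.txt"
        if upath.exists():
            universe = frozenset(filter(None, upath.read_text().splitlines()))
        return cls(sets, universe, margins)


def discover_motifs(input_regions: Iterable[str], db: DivergenceDB,
                    N: int | None = None, adjust: str = "bonferroni"
                    ) -> list[EnrichmentResult]:
    """One hypergeometric test per non-empty predicted set, ranked by
    adjusted then raw p-value (larger overlaps break exact ties).

    ``N`` defaults to the size of the database's region universe; the input
    set must lie within that universe when one is recorded.  Exact p ties
    (identical overlap counts) rank the set with the stronger mean
    per-region AIC margin first.
    """
    if adjust != "bonferroni":
        raise ValueError("only Bonferroni adjustment is supported")
    inp = set(input_regions)
    if not inp:
        raise ValueError("empty input region set")
    if db.universe is not None:
        outside = inp - db.universe
        if outside:
            raise ValueError(
                f"input regions outside the universe: {sorted(outside)[:10]}"
                + ("..." if len(outside) > 10 else ""))
        if N is None:
            N = len(db.universe)
    if N is None:
        raise ValueError("universe size N is required when the database has "
                         "no recorded universe")
    tests = [(key, ids) for key, ids in db.sets.items() if len(ids) >= 1]
    m = len(tests)
    results = []
    for (pwm, model, direction), ids in tests:
        k = len(inp & ids)
        p = hypergeom_test(N, len(ids), len(inp), k)
        results.append(EnrichmentResult(pwm, model, direction, int(N),
                                        len(inp), len(ids), k, p,
                                        min(1.0, p * m)))
    results.sort(key=lambda r: (r.p_adj, r.p, -r.k, r.K,
                                -db.mean_margin((r.pwm, r.model, r.direction)),
                                (r.pwm, r.model, r.direction)))
    return [replace(r, rank=i + 1) for i, r in enumerate(results)]


def results_frame(results: Iterable[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results])


# -- presets for defining experimentally divergent input sets ---------------


def select_divergent_chip(table: pd.DataFrame, fold_col: str,
                          min_fold: float = 2.0) -> set[str]:
    """Regions whose lineage ChIP signal fold-change exceeds ``min_fold``
    (default > 2-fold)."""
    sel = table.index[table[fold_col] > min_fold]
    return set(map(str, sel))


def select_divergent_starr(table: pd.DataFrame, p_col: str, fold_col: str,
                           max_p: float = 0.001, min_fold: float = 3.0
                           ) -> set[str]:
    """Lineage-specific STARR-Seq enhancers: p <= 0.001 and >= 3-fold
    enrichment over input."""
    mask = (table[p_col] <= max_p) & (table[fold_col] >= min_fold)
    return set(map(str, table.index[mask]))
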