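"""Synthetic data generation: traits under known regimes, ortholog
sequence panels with planted or deleted motif clusters, and enrichment
benchmarks.

Every generator is a pure function of its parameters and seed.  Sequence
panels do **not** model substitution along the tree: each species'
background is an independent draw, with motif sites planted (or withheld)
per scenario.  That is a deliberately non-phylogenetic sequence null —
sufficient to exercise the scorer and the trait models, but it does not
emulate the correlated sequence divergence of real orthologs (see the
methods note).
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .crmscore import BASES, PWM, reverse_complement
from .phylo import PhyloTree, RegimePainting
from .pmc import simulate_traits

__all__ = [
    "SyntheticPanel",
    "Benchmark",
    "gen_trait_dataset",
    "gen_sequence_panel",
    "gen_enrichment_benchmark",
    "synthetic_pwm",
]

#: Cluster window = CLUSTER_WINDOW_GAPS x expected gap (+ site lengths),
#: guaranteeing single-cluster structure.
CLUSTER_WINDOW_GAPS = 3.0


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    if seed is None:
        raise ValueError("an explicit seed is required")
    return np.random.default_rng(seed)


def synthetic_pwm(pwm_id: str, length: int = 8, dominance: float = 0.85,
                  consensus: str | None = None, seed=None) -> PWM:
    """A synthetic PWM: at each position the consensus base has probability
    ``dominance`` and the rest share the remainder.  ``dominance=0.85`` on
    8 positions gives ~9.2 bits — a realistic TF motif."""
    if consensus is None:
        rng = _rng(seed)
        consensus = "".join(rng.choice(list(BASES), size=length))
    probs = np.full((len(consensus), 4), (1.0 - dominance) / 3.0)
    for i, b in enumerate(consensus.upper()):
        probs[i, BASES.index(b)] = dominance
    return PWM(pwm_id, probs)


# ---------------------------------------------------------------------------
# Traits
# ---------------------------------------------------------------------------


def gen_trait_dataset(tree: PhyloTree, painting: RegimePainting, params,
                      n_regions: int, seed) -> tuple[pd.DataFrame, list[str]]:
    """Simulate ``n_regions`` independent traits under one model; the truth
    label of every region is the generating model id."""
    if n_regions < 1:
        raise ValueError("n_regions must be >= 1")
    table = simulate_traits(tree, painting, params, n_regions, seed)
    return table, [painting.model_id] * n_regions


# ---------------------------------------------------------------------------
# Sequence panels
# ---------------------------------------------------------------------------


@dataclass
class SyntheticPanel:
    """An ortholog sequence panel with ground truth.

    ``sequences``: {species: {region_id: sequence}} (a region may be absent
    from a species only when a dropout rate was requested).
    ``labels``: region_id -> "gain" | "loss" | "conserved".
    """

    tree: PhyloTree
    pwm: PWM
    sequences: dict[str, dict[str, str]]
    labels: dict[str, str]
    clade_tips: frozenset[str]
    direction: str
    params: dict
    seed: int | None = None

    @property
    def regions(self) -> list[str]:
        return list(self.labels)

    def divergent_regions(self) -> set[str]:
        return {r for r, lab in self.labels.items() if lab == self.direction}

    def write_fastas(self, directory) -> dict[str, Path]:
        """One FASTA per species; record ids are ``region|species``."""
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        paths = {}
        for species, regions in self.sequences.items():
            path = d / f"{species}.fa"
            with open(path, "w") as out:
                for rid, seq in regions.items():
                    out.write(f">{rid}|{species}\n")
                    for i in range(0, len(seq), 70):
                        out.write(seq[i:i + 70] + "\n")
            paths[species] = path
        return paths


def _draw_background(rng, length: int, composition: np.ndarray) -> np.ndarray:
    return rng.choice(4, size=length, p=composition)


def _plant_sites(rng, seq: np.ndarray, pwm: PWM, n_sites: int,
                 gap: float) -> None:
    """Plant ``n_sites`` PWM-sampled sites, clustered within a window of
    ~CLUSTER_WINDOW_GAPS x gap, non-overlapping, random strand."""
    L = pwm.length
    n = seq.size
    window = min(n, int(round(CLUSTER_WINDOW_GAPS * gap)) + n_sites * L)
    if window < n_sites * L:
        raise ValueError(
            f"cannot pack {n_sites} sites of length {L} into a region of "
            f"length {n}")
    wstart = int(rng.integers(0, n - window + 1))
    starts = None
    for _ in range(200):
        cand = np.sort(rng.integers(0, window - L + 1, size=n_sites))
        if n_sites == 1 or np.all(np.diff(cand) >= L):
            starts = cand
            break
    if starts is None:  # dense packing fallback: evenly spread
        space = (window - n_sites * L) // max(1, n_sites - 1) if n_sites > 1 else 0
        starts = np.array([i * (L + space) for i in range(n_sites)])
    for s in starts:
        site = np.array([int(rng.choice(4, p=row)) for row in pwm.probs])
        if rng.random() < 0.5:
            site = 3 - site[::-1]  # reverse complement in 0..3 coding
        seq[wstart + s: wstart + s + site.size] = site


def gen_sequence_panel(tree: PhyloTree, pwm: PWM, clade_tips: Iterable[str],
                       direction: str = "gain", n_sites: int = 3,
                       region_length: int = 300, n_regions: int = 20,
                       frac_divergent: float = 0.5,
                       background: Sequence[float] = (0.25, 0.25, 0.25, 0.25),
                       gap: float = 35.0, dropout: float = 0.0,
                       seed=None) -> SyntheticPanel:
    """Generate an ortholog panel with motif clusters planted per scenario.

    ``direction="gain"``: divergent regions carry sites only in the clade
    species; ``"loss"``: sites in every species *except* the clade.
    Conserved regions carry sites everywhere or nowhere (50/50).
    """
    if direction not in ("gain", "loss"):
        raise ValueError("direction must be 'gain' or 'loss'")
    clade_tips = frozenset(clade_tips)
    unknown = clade_tips - set(tree.tip_labels)
    if unknown:
        raise ValueError(f"clade tips not in tree: {sorted(unknown)}")
    if region_length < n_sites * pwm.length:
        raise ValueError("region_length must fit n_sites x PWM length")
    comp = np.asarray(background, float)
    comp = comp / comp.sum()
    rng = _rng(seed)

    species = tree.tip_labels
    n_div = int(round(n_regions * frac_divergent))
    labels: dict[str, str] = {}
    sequences: dict[str, dict[str, str]] = {sp: {} for sp in species}
    base_codes = np.array(list(BASES))

    for i in range(n_regions):
        rid = f"region_{i:04d}"
        if i < n_div:
            labels[rid] = direction
            sites_everywhere = None
        else:
            labels[rid] = "conserved"
            sites_everywhere = bool(rng.random() < 0.5)
        for sp in species:
            if dropout and rng.random() < dropout:
                continue
            seq = _draw_background(rng, region_length, comp)
            if labels[rid] == "gain":
                has_sites = sp in clade_tips
            elif labels[rid] == "loss":
                has_sites = sp not in clade_tips
            else:
                has_sites = sites_everywhere
            if has_sites and n_sites > 0:
                _plant_sites(rng, seq, pwm, n_sites, gap)
            sequences[sp][rid] = "".join(base_codes[seq])

    return SyntheticPanel(tree, pwm, sequences, labels, clade_tips, direction,
                          dict(n_sites=n_sites, region_length=region_length,
                               n_regions=n_regions,
                               frac_divergent=frac_divergent,
                               background=tuple(comp), gap=gap,
                               dropout=dropout),
                          seed if isinstance(seed, int) else None)


# ---------------------------------------------------------------------------
# Enrichment benchmark
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Benchmark:
    universe: frozenset[str]
    input_set: frozenset[str]
    truth: tuple[str, str, str]  # (pwm, model, direction)


def gen_enrichment_benchmark(panel: SyntheticPanel, truth_model: str,
                             n_background_regions: int = 300,
                             noise: float = 0.0, seed=None) -> Benchmark:
    """Build a discovery benchmark around a generated panel.

    Universe = panel regions + ``n_background_regions`` synthetic ids
    standing in for the rest of the region catalog.  The input set is the
    panel's truly divergent regions, with a ``noise`` fraction replaced by
    uniform draws from the universe (noise=1 => a fully random input set).
    """
    if not 0.0 <= noise <= 1.0:
        raise ValueError("noise must be in [0, 1]")
    rng = _rng(seed)
    background = [f"bg_{i:05d}" for i in range(n_background_regions)]
    universe = list(panel.regions) + background
    true_set = sorted(panel.divergent_regions())
    n_noise = int(round(noise * len(true_set)))
    kept = list(rng.choice(true_set, size=len(true_set) - n_noise,
                           replace=False)) if n_noise < len(true_set) else []
    pool = sorted(set(universe) - set(kept))
    noisy = list(rng.choice(pool, size=n_noise, replace=False)) if n_noise else []
    return Benchmark(frozenset(universe), frozenset(kept) | frozenset(noisy),
                     (panel.pwm.pwm_id, truth_model, panel.direction))
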