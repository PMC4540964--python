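"""Homotypic-cluster CRM scoring of sequences against a PWM.

The score of a region for a motif is a log2 likelihood ratio between a
*cluster model* and a background model, maximized over subsegments of the
region.  Within a candidate subsegment the cluster model sums, by the
forward algorithm, over **all** parses of the subsegment into motif
occurrences (either strand, non-overlapping) and background gaps:

* each motif occurrence of site sequence ``s`` contributes
  ``(q / 2) * odds(s)`` where ``odds`` is the PWM-vs-background likelihood
  ratio and the strand factor is 1/2;
* each background base inside the subsegment contributes ``1 - q``
  (the probability of *not* opening a site), which makes inter-site gap
  lengths geometric with mean ``(1 - q) / q``; ``q = 1 / (1 + expected_gap)``.

The empty parse of an empty subsegment has ratio 1, so the reported region
score — the best subsegment, in log2 — is floored at exactly 0.  A single
strong match scores as a one-site cluster.  ``N`` bases contribute a factor
of 1 to both models (score-neutral).

The exact maximization over subsegments is a dynamic programme over
segment ends that carries, in log space, the forward sum for every
candidate segment start at once (O(length^2) with vectorized inner steps;
regions are scored in milliseconds at typical enhancer lengths).
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PWM",
    "MotifHit",
    "ClusterScore",
    "pwm_from_counts",
    "load_pwms",
    "crm_score",
    "score_orthologs",
    "read_fasta_panel",
    "reverse_complement",
    "DEFAULT_PSEUDOCOUNT",
    "DEFAULT_GAP",
]

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

DEFAULT_PSEUDOCOUNT = 0.375  # per count cell, Cluster-Buster-compatible
DEFAULT_GAP = 35.0  # expected gap (bp) between sites in a cluster


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class PWM:
    """Position probability matrix over A, C, G, T.

    ``probs`` has shape (length, 4); every row sums to 1 and is strictly
    positive (pseudocounted).  Information content is
    ``sum_pos (2 + sum_b p log2 p)`` bits.
    """

    pwm_id: str
    probs: np.ndarray

    def __post_init__(self):
        p = np.asarray(self.probs, dtype=float)
        if p.ndim != 2 or p.shape[1] != 4 or p.shape[0] < 1:
            raise ValueError("PWM probs must be an L x 4 matrix with L >= 1")
        if not np.all(p > 0):
            raise ValueError("PWM probabilities must be strictly positive "
                             "(apply a pseudocount)")
        if np.max(np.abs(p.sum(axis=1) - 1.0)) > 1e-9:
            raise ValueError("PWM rows must each sum to 1 (within 1e-9)")
        object.__setattr__(self, "probs", p)

    @property
    def length(self) -> int:
        return self.probs.shape[0]

    @property
    def info_content(self) -> float:
        p = self.probs
        return float(np.sum(2.0 + np.sum(p * np.log2(p), axis=1)))

    def reverse_complement(self) -> "PWM":
        return PWM(self.pwm_id, self.probs[::-1, ::-1])

    def consensus(self) -> str:
        return "".join(BASES[i] for i in np.argmax(self.probs, axis=1))


def pwm_from_counts(pwm_id: str, counts, pseudocount: float = DEFAULT_PSEUDOCOUNT
                    ) -> PWM:
    """Normalize an L x 4 count matrix with a per-cell pseudocount."""
    c = np.asarray(counts, dtype=float)
    if c.ndim != 2 or c.shape[1] != 4:
        raise ValueError("counts must be an L x 4 matrix (columns A, C, G, T)")
    if np.any(c < 0) or not np.all(np.isfinite(c)):
        raise ValueError("counts must be finite and non-negative")
    if np.any(c.sum(axis=1) == 0) and pseudocount <= 0:
        raise ValueError("a position has all-zero counts and no pseudocount")
    c = c + pseudocount
    return PWM(pwm_id, c / c.sum(axis=1, keepdims=True))


def load_pwms(source, pseudocount: float = DEFAULT_PSEUDOCOUNT) -> list[PWM]:
    """Load JASPAR-style matrices (count or probability) from a path or
    handle.  Matrix values are treated as counts; the pseudocount is added
    per cell before normalization."""
    from Bio import motifs as bio_motifs

    def parse(handle):
        try:
            records = bio_motifs.parse(handle, "jaspar")
        except (ValueError, KeyError) as exc:
            raise ValueError(f"cannot parse PWM file: {exc}") from exc
        out = []
        for m in records:
            counts = np.array([[m.counts[b][i] for b in BASES]
                               for i in range(m.length)], dtype=float)
            name = m.matrix_id or m.name
            out.append(pwm_from_counts(str(name), counts, pseudocount))
        if not out:
            raise ValueError("no PWM records found")
        return out

    if hasattr(source, "read"):
        return parse(source)
    with open(source) as handle:
        return parse(handle)


# ---------------------------------------------------------------------------
# Scoring
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MotifHit:
    pos: int  # 0-based start within the region
    strand: str  # "+" | "-"
    log_odds: float  # per-site log2 PWM-vs-background odds


@dataclass(frozen=True)
class ClusterScore:
    region: str
    species: str
    score: float  # log2 cluster-vs-background, >= 0
    start: int  # best-cluster interval, 0-based half-open
    end: int
    hits: tuple[MotifHit, ...] = ()


def _background_freqs(seq: str, background) -> np.ndarray:
    if background == "uniform":
        return np.full(4, 0.25)
    if background == "region":
        counts = np.array([seq.count(b) for b in BASES], dtype=float)
        return (counts + 1.0) / (counts.sum() + 4.0)  # mild smoothing
    freqs = np.asarray(background, dtype=float)
    if freqs.shape != (4,) or np.any(freqs <= 0):
        raise ValueError("background must be 'region', 'uniform' or 4 "
                         "positive frequencies (A, C, G, T)")
    return freqs / freqs.sum()


def _site_log_odds(seq_idx: np.ndarray, pwm: PWM, bg: np.ndarray) -> np.ndarray:
    """Natural-log odds of a site starting at each position, one strand.

    ``seq_idx`` codes A,C,G,T as 0..3 and N as 4; N positions contribute 0.
    Returns an array of length ``n - L + 1``.
    """
    L = pwm.length
    n = seq_idx.size
    if n < L:
        return np.empty(0)
    logratio = np.concatenate(
        [np.log(pwm.probs) - np.log(bg)[None, :], np.zeros((L, 1))], axis=1
    )  # L x 5; the 5th column is N
    out = np.zeros(n - L + 1)
    for j in range(L):
        out += logratio[j, seq_idx[j:n - L + 1 + j]]
    return out


def crm_score(seq: str, pwm: PWM, gap: float = DEFAULT_GAP,
              background="region", region: str = "", species: str = ""
              ) -> ClusterScore:
    """Score one sequence for a homotypic cluster of one motif.

    ``gap`` is the expected background gap (bp) between sites inside a
    cluster; ``background`` is ``"region"`` (0th-order frequencies from the
    scored sequence, lightly smoothed), ``"uniform"``, or explicit
    A/C/G/T frequencies.
    """
    if not seq:
        raise ValueError("empty sequence")
    seq = seq.upper()
    if set(seq) - set("ACGTN"):
        raise ValueError(f"sequence contains non-ACGTN characters: "
                         f"{sorted(set(seq) - set('ACGTN'))}")
    L = pwm.length
    n = len(seq)
    if n < L:
        raise ValueError(f"sequence length {n} < PWM length {L}")
    if gap <= 0:
        raise ValueError("expected gap must be > 0")

    bg = _background_freqs(seq, background)
    seq_idx = np.array([_BASE_INDEX.get(b, 4) for b in seq], dtype=int)
    q = 1.0 / (1.0 + gap)
    ln_1q = math.log1p(-q)

    llr_fwd = _site_log_odds(seq_idx, pwm, bg)
    llr_rev = _site_log_odds(seq_idx, pwm.reverse_complement(), bg)
    # both strands collapse into one per-start term: (q/2)(odds_f + odds_r)
    site_ln = math.log(q / 2.0) + np.logaddexp(llr_fwd, llr_rev)

    # logH[b][a] = ln sum over parses of segment [a, b); ring buffer over b.
    neg_inf = float("-inf")
    ring: list[np.ndarray] = [np.zeros(n + 1)]  # b = 0 column: all empty
    best = 0.0
    best_ab = (0, 0)
    for b in range(1, n + 1):
        prev = ring[-1]
        col = np.full(n + 1, neg_inf)
        col[b:] = 0.0  # empty segments (a >= b)
        col[:b] = ln_1q + prev[:b]  # last base of [a, b) is background
        if b >= L:
            colL = ring[-L]  # column b - L (ring keeps the last L+1 columns)
            lim = b - L + 1  # site needs start >= a, i.e. a <= b - L
            col[:lim] = np.logaddexp(col[:lim], site_ln[b - L] + colL[:lim])
        m = int(np.argmax(col[:b]))
        if col[m] > best:
            best = float(col[m])
            best_ab = (m, b)
        ring.append(col)
        if len(ring) > L + 1:
            ring.pop(0)

    score = best / math.log(2.0)
    a, b = best_ab
    hits = []
    if score > 0:
        for p in range(a, b - L + 1):
            for llr, strand in ((llr_fwd[p], "+"), (llr_rev[p], "-")):
                net = math.log(q / 2.0) + llr
                if net > 0:
                    hits.append(MotifHit(p, strand, llr / math.log(2.0)))
    return ClusterScore(region, species, score, a, b, tuple(hits))


# ---------------------------------------------------------------------------
# Ortholog panels
# ---------------------------------------------------------------------------


def read_fasta_panel(paths: Mapping[str, str]) -> dict[str, dict[str, str]]:
    """Read per-species FASTA files into {species: {region_id: sequence}}.

    Record ids may carry a ``region|species`` suffix, which is stripped.
    Duplicate region ids within one species file are an error.
    """
    from Bio import SeqIO

    panel: dict[str, dict[str, str]] = {}
    for species, path in paths.items():
        regions: dict[str, str] = {}
        for rec in SeqIO.parse(str(path), "fasta"):
            region = rec.id.split("|")[0]
            if region in regions:
                raise ValueError(
                    f"duplicate region id {region!r} in {path} ({species})")
            regions[region] = str(rec.seq)
        panel[species] = regions
    return panel


def score_orthologs(panel: Mapping[str, Mapping[str, str]], pwm: PWM,
                    gap: float = DEFAULT_GAP, background="region"
                    ) -> pd.DataFrame:
    """Score every (region, species) present in an ortholog panel.

    ``panel``: {species: {region_id: sequence}}.  Returns a DataFrame with
    one row per region and one column per species; absent orthologs are
    NaN (missing, not zero).
    """
    species = list(panel)
    regions: list[str] = []
    seen = set()
    for sp in species:
        for rid in panel[sp]:
            if rid not in seen:
                seen.add(rid)
                regions.append(rid)
    mat = pd.DataFrame(np.nan, index=regions, columns=species, dtype=float)
    for sp in species:
        for rid, seq in panel[sp].items():
            mat.loc[rid, sp] = crm_score(seq, pwm, gap=gap,
                                         background=background,
                                         region=rid, species=sp).score
    mat.index.name = "region"
    return mat
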