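"""Core-sequence (truncation) scanning and differential k-mer enrichment.

To test whether a short subsequence of a full-length aptamer carries the
binding activity, the subsequence is embedded at every admissible start index
inside each of the four homopolymer backgrounds (all-A, all-C, all-G, all-T)
and every embedding is scored by a fixed-length model. A core of length *l*
in an *L*-nt window therefore yields 4*(L-l+1) scored variants; cores whose
score stays high regardless of placement and background are the best
truncation candidates.

The module also provides a Fisher-exact differential k-mer screen as a
lightweight in-repo motif finder (a deliberate simplification of EM/PWM-style
motif discovery).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact

from ._util import BASES, check_sequence
from .walker import Scorer

DEFAULT_CORE_LENGTHS = (15, 19, 23, 27, 31, 35, 39)


def embed_core(
    core: str, start: int, background_base: str, total_length: int = 40
) -> str:
    """Place *core* at *start* inside a homopolymer of *background_base*."""
    check_sequence(core)
    if background_base not in BASES:
        raise ValueError(f"background base must be one of {BASES}")
    if not 0 <= start <= total_length - len(core):
        raise ValueError(
            f"start {start} invalid for core of length {len(core)} in {total_length}"
        )
    suffix = total_length - start - len(core)
    return background_base * start + core + background_base * suffix


@dataclass
class CoreScan:
    """Score distribution for one core over all backgrounds and placements."""

    core: str
    length: int
    scores: np.ndarray  # shape (4 backgrounds, L - l + 1 starts)
    median: float
    variance: float  # population variance

    @classmethod
    def from_scores(cls, core: str, scores: np.ndarray) -> "CoreScan":
        return cls(
            core=core,
            length=len(core),
            scores=scores,
            median=float(np.median(scores)),
            variance=float(np.var(scores)),
        )


def scan_cores(
    full_sequence: str,
    scorer: Scorer,
    lengths: Sequence[int] = DEFAULT_CORE_LENGTHS,
    min_length: int = 15,
    total_length: int = 40,
) -> list[CoreScan]:
    """Score every subsequence of the requested lengths in all embeddings.

    Each distinct (length, start-in-parent) subsequence yields one
    :class:`CoreScan` with 4*(total_length - l + 1) scores. All embeddings are
    scored in one batched scorer call.
    """
    check_sequence(full_sequence)
    L = len(full_sequence)
    use_lengths = sorted({l for l in lengths if min_length <= l <= min(L, total_length)})
    cores: list[str] = []
    for l in use_lengths:
        for i in range(L - l + 1):
            cores.append(full_sequence[i : i + l])
    variants: list[str] = []
    slices: list[tuple[str, int]] = []  # (core, n_variants)
    for core in cores:
        n_starts = total_length - len(core) + 1
        for base in BASES:
            for start in range(n_starts):
                variants.append(embed_core(core, start, base, total_length))
        slices.append((core, 4 * n_starts))
    all_scores = np.asarray(scorer(variants), dtype=float) if variants else np.array([])
    scans = []
    offset = 0
    for core, n in slices:
        block = all_scores[offset : offset + n].reshape(4, n // 4)
        offset += n
        scan = CoreScan.from_scores(core, block)
        assert scan.scores.size == 4 * (total_length - scan.length + 1)
        scans.append(scan)
    return scans


def rank_cores(scans: Sequence[CoreScan], mode: str = "max_median") -> list[CoreScan]:
    """Order cores by the chosen summary statistic.

    ``max_median`` prefers consistently high scores; ``min_variance`` prefers
    placement-insensitive scores; ``min_median`` surfaces sanity-check picks
    expected NOT to retain binding. Ties break by length ascending, then
    lexicographic core sequence.
    """
    if mode == "max_median":
        key = lambda s: (-s.median, s.length, s.core)
    elif mode == "min_variance":
        key = lambda s: (s.variance, s.length, s.core)
    elif mode == "min_median":
        key = lambda s: (s.median, s.length, s.core)
    else:
        raise ValueError(f"unknown ranking mode {mode!r}")
    return sorted(scans, key=key)


def scans_to_frame(scans: Sequence[CoreScan]) -> pd.DataFrame:
    """Long-form table (core, length, background, start, score) for TSV export."""
    rows = []
    for scan in scans:
        for bi, base in enumerate(BASES):
            for start in range(scan.scores.shape[1]):
                rows.append(
                    {
                        "core": scan.core,
                        "length": scan.length,
                        "background": base,
                        "start": start,
                        "score": scan.scores[bi, start],
                    }
                )
    return pd.DataFrame(rows)


def summary_frame(scans: Sequence[CoreScan], mode: str = "max_median") -> pd.DataFrame:
    ranked = rank_cores(scans, mode)
    return pd.DataFrame(
        [
            {
                "rank": i,
                "core": s.core,
                "length": s.length,
                "median": s.median,
                "variance": s.variance,
            }
            for i, s in enumerate(ranked)
        ]
    )


# ---------------------------------------------------------------------------
# Differential k-mer enrichment
# ---------------------------------------------------------------------------


@dataclass
class EnrichmentResult:
    table: pd.DataFrame  # per k-mer: k, log_odds, p, p_bonferroni, counts
    consensus: str | None  # best k-mer at the most significant k, if any


def differential_kmer_enrichment(
    positives: Sequence[str],
    background: Sequence[str],
    k_range: Sequence[int] = range(4, 9),
    alpha: float = 0.05,
) -> EnrichmentResult:
    """Screen for k-mers over-represented in positive vs background sequences.

    Per k-mer: occurrence-frequency log-odds with pseudocount 1, and a Fisher
    exact test on presence/absence with Bonferroni correction over all 4^k
    k-mers. The consensus is the k-mer with the strongest raw Fisher evidence
    among those surviving the corrected *alpha*; exact ties (a motif and a
    substring of it covering the same positive set) resolve to the longer,
    more specific k-mer, then to higher log-odds. None when nothing is
    significant.
    """
    if not positives or not background:
        raise ValueError("need non-empty positive and background sets")
    n_pos, n_bg = len(positives), len(background)
    rows = []
    for k in k_range:
        occ_pos: dict[str, int] = {}
        occ_bg: dict[str, int] = {}
        pres_pos: dict[str, int] = {}
        pres_bg: dict[str, int] = {}
        for seqs, occ, pres in ((positives, occ_pos, pres_pos), (background, occ_bg, pres_bg)):
            for s in seqs:
                seen = set()
                for i in range(len(s) - k + 1):
                    kmer = s[i : i + k]
                    occ[kmer] = occ.get(kmer, 0) + 1
                    seen.add(kmer)
                for kmer in seen:
                    pres[kmer] = pres.get(kmer, 0) + 1
        tot_pos = sum(occ_pos.values())
        tot_bg = sum(occ_bg.values())
        for kmer in sorted(set(occ_pos) | set(occ_bg)):
            cp, cb = occ_pos.get(kmer, 0), occ_bg.get(kmer, 0)
            log_odds = float(
                np.log((cp + 1) / (tot_pos + 4**k)) - np.log((cb + 1) / (tot_bg + 4**k))
            )
            pp, pb = pres_pos.get(kmer, 0), pres_bg.get(kmer, 0)
            _, p = fisher_exact(
                [[pp, n_pos - pp], [pb, n_bg - pb]], alternative="greater"
            )
            rows.append(
                {
                    "kmer": kmer,
                    "k": k,
                    "count_pos": cp,
                    "count_bg": cb,
                    "present_pos": pp,
                    "present_bg": pb,
                    "log_odds": log_odds,
                    "p": float(p),
                    "p_bonferroni": float(min(1.0, p * 4**k)),
                }
            )
    table = pd.DataFrame(rows)
    consensus = None
    significant = table[table["p_bonferroni"] < alpha]
    if len(significant):
        consensus = significant.sort_values(
            ["p", "k", "log_odds", "kmer"], ascending=[True, False, False, True]
        ).iloc[0]["kmer"]
    return EnrichmentResult(table=table, consensus=consensus)
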