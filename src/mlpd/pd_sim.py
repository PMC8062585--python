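"""Particle-display physics and synthetic screen generation.

Models the chain from equilibrium binding occupancy through FACS gating,
multi-round sort-and-amplify enrichment, and sequencing-count sampling, with a
configurable ground-truth affinity oracle. Also provides the single-site K_D
curve fit and the coarse interval-based K_D assignment used to calibrate
stringency thresholds.

The central identities: a bead displaying an aptamer with dissociation
constant K_D, incubated at target concentration [T], has occupancy
Fr = [T] / ([T] + K_D). Sorting at a fluorescence gate of F_max/3 therefore
collects exactly the aptamers with K_D <= 2[T]; a ladder of fourfold-decreasing
concentrations yields fourfold-decreasing affinity thresholds.
"""

from __future__ import annotations

import json
import warnings
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import curve_fit

from ._util import check_sequence, derive_rng, random_sequences
from .seqdata import CountTable, PoolInfo, pool_name

DEFAULT_MOTIF = "TGGATAG"


# ---------------------------------------------------------------------------
# Binding math
# ---------------------------------------------------------------------------


def binding_fraction(T, kd):
    """Equilibrium occupancy Fr = [T] / ([T] + K_D); both in nM.

    Strictly increasing in [T], strictly decreasing in K_D, and equal to 1/3
    at [T] = K_D/2 — which is why sorting at the F_max/3 gate after incubation
    at [T] isolates aptamers with K_D <= 2[T].
    """
    T = np.asarray(T, dtype=float)
    kd = np.asarray(kd, dtype=float)
    if np.any(kd <= 0):
        raise ValueError("K_D must be positive")
    if np.any(T < 0):
        raise ValueError("target concentration must be non-negative")
    out = T / (T + kd)
    return float(out) if out.ndim == 0 else out


def kd_threshold_for_concentration(T: float) -> float:
    """Affinity threshold isolated by the F_max/3 gate at concentration [T]: 2[T]."""
    if T <= 0:
        raise ValueError("concentration must be positive")
    return 2.0 * T


# ---------------------------------------------------------------------------
# Ground-truth affinity oracle
# ---------------------------------------------------------------------------


@dataclass
class AffinityOracle:
    """Rule-based map sequence -> true K_D (nM), the simulator's ground truth.

    K_D = baseline / prod(fold ** occurrences(motif)) for each planted motif,
    optionally perturbed by per-k-mer log-additive weights and seeded
    per-sequence lognormal noise. Occurrences are counted non-overlapping, so
    acquiring a second copy of a planted motif compounds the bonus.
    """

    baseline_kd: float = 10_000.0
    motifs: dict[str, float] = field(default_factory=lambda: {DEFAULT_MOTIF: 100.0})
    kmer_weights: dict[str, float] | None = None  # log-space additive effects
    lognormal_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.baseline_kd <= 0:
            raise ValueError("baseline K_D must be positive")
        if any(f <= 0 for f in self.motifs.values()):
            raise ValueError("motif fold-improvements must be positive")

    def kd(self, sequence: str) -> float:
        check_sequence(sequence)
        log_kd = np.log(self.baseline_kd)
        for motif, fold in self.motifs.items():
            log_kd -= sequence.count(motif) * np.log(fold)
        if self.kmer_weights:
            for kmer, w in self.kmer_weights.items():
                log_kd += sequence.count(kmer) * w
        if self.lognormal_sigma > 0:
            key = zlib.crc32(sequence.encode()) % (2**31)
            noise_rng = np.random.default_rng(
                np.random.SeedSequence([int(self.seed) % (2**31), key])
            )
            log_kd += self.lognormal_sigma * noise_rng.standard_normal()
        return float(np.exp(log_kd))

    def kds(self, sequences: Sequence[str]) -> np.ndarray:
        return np.array([self.kd(s) for s in sequences])

    def score(self, sequences: Sequence[str]) -> np.ndarray:
        """Oracle affinity score for walk guidance: -log10 K_D (higher = better)."""
        return -np.log10(self.kds(sequences))


# ---------------------------------------------------------------------------
# Stringency ladder
# ---------------------------------------------------------------------------


@dataclass
class StringencyLadder:
    """Ordered target concentrations, weakest (highest [T]) to strongest.

    Consecutive concentrations must decrease by exactly *fold*; the affinity
    threshold at each level is 2[T].
    """

    concentrations: list[float]
    fold: float = 4.0
    gate_fraction: float = 1.0 / 3.0
    bead_coverage: float = 100.0  # expected reads per full bead-complement

    def __post_init__(self) -> None:
        c = self.concentrations
        if not c or any(x <= 0 for x in c):
            raise ValueError("concentrations must be positive")
        for a, b in zip(c, c[1:]):
            if not np.isclose(a / b, self.fold, rtol=1e-9):
                raise ValueError(
                    f"consecutive concentrations {a}/{b} do not match fold {self.fold}"
                )
        if not 0 < self.gate_fraction < 1:
            raise ValueError("gate_fraction must be in (0,1)")
        if self.bead_coverage <= 0:
            raise ValueError("bead_coverage must be positive")

    @property
    def thresholds(self) -> list[float]:
        return [kd_threshold_for_concentration(T) for T in self.concentrations]

    @property
    def n_levels(self) -> int:
        return len(self.concentrations)

    @classmethod
    def training_default(cls, **kw) -> "StringencyLadder":
        """Three-level design used to generate model training data
        (thresholds 2048/512/128 nM)."""
        return cls([1024.0, 256.0, 64.0], **kw)

    @classmethod
    def mlpd(cls, **kw) -> "StringencyLadder":
        """Four-level validation design (thresholds 512/128/32/8 nM)."""
        return cls([256.0, 64.0, 16.0, 4.0], **kw)


# ---------------------------------------------------------------------------
# Sorting and sequencing
# ---------------------------------------------------------------------------


def simulate_sort(
    sequences: Sequence[str] | Mapping[str, int],
    oracle: AffinityOracle,
    T: float,
    gate_fraction: float = 1.0 / 3.0,
    noise_cv: float = 0.1,
    beads_per_sequence: int = 10,
    rng: np.random.Generator | None = None,
) -> tuple[dict[str, int], dict[str, int]]:
    """Sort a bead population at concentration [T] into positive/negative pools.

    Each bead carries one sequence and fluoresces F = F_max * Fr * (1 + eps)
    with eps ~ Normal(0, noise_cv); beads at or above gate_fraction * F_max
    (boundary inclusive) are collected as positive. With noise_cv = 0 a
    sequence is positive iff K_D <= 2[T] exactly.
    """
    if not 0 < gate_fraction < 1:
        raise ValueError("gate_fraction must be in (0,1)")
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    rng = rng if rng is not None else np.random.default_rng()
    if isinstance(sequences, Mapping):
        beads = dict(sequences)
    else:
        beads = {s: beads_per_sequence for s in sequences}
    pos: dict[str, int] = {}
    neg: dict[str, int] = {}
    for seq in sorted(beads):
        n = beads[seq]
        fr = binding_fraction(T, oracle.kd(seq))
        if noise_cv == 0:
            n_pos = n if fr >= gate_fraction else 0
        else:
            eps = rng.normal(0.0, noise_cv, size=n)
            n_pos = int(np.sum(fr * (1.0 + eps) >= gate_fraction))
        if n_pos:
            pos[seq] = n_pos
        if n - n_pos:
            neg[seq] = n - n_pos
    return pos, neg


def simulate_sequencing(
    pool: Mapping[str, int],
    total_reads: int,
    rng: np.random.Generator | None = None,
) -> dict[str, int]:
    """Multinomial read sampling proportional to bead abundance."""
    if total_reads < 0:
        raise ValueError("total_reads must be >= 0")
    if total_reads == 0:
        return {}
    if not pool:
        raise ValueError("cannot sequence an empty pool")
    rng = rng if rng is not None else np.random.default_rng()
    seqs = sorted(pool)
    beads = np.array([pool[s] for s in seqs], dtype=float)
    counts = rng.multinomial(total_reads, beads / beads.sum())
    return {s: int(c) for s, c in zip(seqs, counts) if c}


# ---------------------------------------------------------------------------
# Whole-experiment simulation
# ---------------------------------------------------------------------------


@dataclass
class SimConfig:
    """Desk-scale defaults for a simulated two-round particle-display screen."""

    library_size: int = 2500
    sequence_length: int = 40
    motif_fraction: float = 0.1  # fraction of the library with an implanted motif
    implant_motif: str | None = None  # default: the oracle's first planted motif
    rounds: int = 2
    round1_levels: list[int] | None = None  # default: all but the strongest level
    beads_per_sequence: int = 10
    noise_cv: float = 0.1

    def __post_init__(self) -> None:
        if self.rounds < 1:
            raise ValueError("rounds must be >= 1")


@dataclass
class SimulatedExperiment:
    """Simulator output: library with true K_D, pool counts, and provenance."""

    library: list[str]
    true_kd: dict[str, float]
    table: CountTable
    bead_pools: dict[str, dict[str, int]]
    provenance: dict

    def write(self, directory: str | Path) -> Path:
        directory = Path(directory)
        manifest = self.table.write(directory)
        with open(directory / "library.tsv", "w") as fh:
            fh.write("sequence\ttrue_kd_nm\n")
            for seq in self.library:
                fh.write(f"{seq}\t{self.true_kd[seq]:.6g}\n")
        (directory / "provenance.json").write_text(json.dumps(self.provenance, indent=1))
        return manifest


def generate_library(
    n: int,
    length: int = 40,
    motif: str | None = DEFAULT_MOTIF,
    motif_fraction: float = 0.1,
    rng: np.random.Generator | None = None,
) -> list[str]:
    """Random fixed-length library with a motif implanted in a set fraction."""
    rng = rng if rng is not None else np.random.default_rng()
    seqs = random_sequences(n, length, rng)
    if motif and motif_fraction > 0:
        n_implant = int(round(motif_fraction * n))
        which = rng.choice(n, size=n_implant, replace=False)
        for i in which:
            start = int(rng.integers(0, length - len(motif) + 1))
            s = seqs[i]
            seqs[i] = s[:start] + motif + s[start + len(motif):]
    return seqs


def _pool_and_resample(
    positive_pools: list[dict[str, int]],
    total_beads: int,
    rng: np.random.Generator,
) -> dict[str, int]:
    """Mix round-1 positive pools at equal total bead mass, then resample
    proportionally to abundance (amplification + re-synthesis)."""
    mixture: dict[str, float] = {}
    for pool in positive_pools:
        total = sum(pool.values())
        if total == 0:
            continue
        for seq, n in pool.items():
            mixture[seq] = mixture.get(seq, 0.0) + n / total / len(positive_pools)
    if not mixture:
        return {}
    seqs = sorted(mixture)
    probs = np.array([mixture[s] for s in seqs])
    counts = rng.multinomial(total_beads, probs / probs.sum())
    return {s: int(c) for s, c in zip(seqs, counts) if c}


def simulate_experiment(
    config: SimConfig,
    ladder: StringencyLadder,
    oracle: AffinityOracle,
    seed: int = 0,
    library: Sequence[str] | None = None,
) -> SimulatedExperiment:
    """Run a multi-round, multi-stringency particle-display screen in silico.

    Round 1 sorts the full library at the weaker stringencies; round-1
    positive pools are mixed 1:1 and resampled to form the round-2 input,
    which is sorted at every stringency. Each (round, level) emits a positive
    and a negative sequencing count pool.
    """
    rng = derive_rng(seed, "simulate_experiment")
    if library is None:
        library = generate_library(
            config.library_size,
            config.sequence_length,
            config.implant_motif or next(iter(oracle.motifs), None),
            config.motif_fraction,
            derive_rng(seed, "library"),
        )
    library = list(library)
    if config.round1_levels is not None:
        r1_levels = list(config.round1_levels)
    elif config.rounds > 1 and ladder.n_levels > 1:
        r1_levels = list(range(ladder.n_levels - 1))
    else:
        r1_levels = list(range(ladder.n_levels))

    counts: dict[str, dict[str, int]] = {}
    bead_pools: dict[str, dict[str, int]] = {}
    infos: list[PoolInfo] = []
    input_beads: Mapping[str, int] = {s: config.beads_per_sequence for s in library}
    for rnd in range(1, config.rounds + 1):
        levels = r1_levels if rnd == 1 else list(range(ladder.n_levels))
        round_positives: list[dict[str, int]] = []
        for lvl in levels:
            T = ladder.concentrations[lvl]
            pos, neg = simulate_sort(
                input_beads,
                oracle,
                T,
                ladder.gate_fraction,
                config.noise_cv,
                rng=derive_rng(seed, f"sort_r{rnd}_l{lvl}"),
            )
            round_positives.append(pos)
            for polarity, pool in (("pos", pos), ("neg", neg)):
                name = pool_name(rnd, T, polarity)
                n_beads = sum(pool.values())
                total_reads = int(round(ladder.bead_coverage * n_beads / config.beads_per_sequence))
                reads = (
                    simulate_sequencing(pool, total_reads, derive_rng(seed, f"seq_{name}"))
                    if n_beads
                    else {}
                )
                counts[name] = reads
                bead_pools[name] = pool
                infos.append(
                    PoolInfo(
                        name=name,
                        round=rnd,
                        concentration=T,
                        polarity=polarity,
                        total_reads=sum(reads.values()),
                        expected_coverage=ladder.bead_coverage,
                    )
                )
        if rnd < config.rounds:
            total_beads = len(library) * config.beads_per_sequence
            input_beads = _pool_and_resample(
                round_positives, total_beads, derive_rng(seed, f"resample_r{rnd}")
            )
            if not input_beads:
                warnings.warn(f"no positive beads after round {rnd}; later rounds are empty")

    table = CountTable.from_counts(counts, infos)
    # every pooled sequence must come from the library
    lib_set = set(library)
    assert all(s in lib_set for s in table.sequences)
    provenance = {
        "seed": int(seed),
        "config": {k: v for k, v in vars(config).items()},
        "ladder": {
            "concentrations_nm": ladder.concentrations,
            "fold": ladder.fold,
            "gate_fraction": ladder.gate_fraction,
            "bead_coverage": ladder.bead_coverage,
        },
        "oracle": {
            "baseline_kd": oracle.baseline_kd,
            "motifs": oracle.motifs,
            "lognormal_sigma": oracle.lognormal_sigma,
            "seed": oracle.seed,
        },
    }
    return SimulatedExperiment(
        library=library,
        true_kd={s: oracle.kd(s) for s in library},
        table=table,
        bead_pools=bead_pools,
        provenance=provenance,
    )


def write_fastq(
    counts: Mapping[str, int],
    path: str | Path,
    forward_primer: str = "",
    reverse_primer: str = "",
    quality: int = 40,
) -> None:
    """Emit a pool as FASTQ with uniform qualities (pipeline-compat testing)."""
    qchar = chr(quality + 33)
    with open(path, "w") as fh:
        i = 0
        for seq in sorted(counts):
            full = forward_primer + seq + reverse_primer
            for _ in range(counts[seq]):
                fh.write(f"@read{i}\n{full}\n+\n{qchar * len(full)}\n")
                i += 1


# ---------------------------------------------------------------------------
# K_D estimation
# ---------------------------------------------------------------------------


class FitError(RuntimeError):
    """Raised when a binding-curve fit is underdetermined or degenerate."""


def fit_kd(
    concentrations: Sequence[float], intensities: Sequence[float]
) -> tuple[float, float]:
    """Least-squares fit of the single-site model F = F_max * [T]/([T] + K_D).

    Returns (K_D, F_max). Requires >= 3 distinct concentrations; raises
    :class:`FitError` on flat or all-zero curves.
    """
    T = np.asarray(concentrations, dtype=float)
    F = np.asarray(intensities, dtype=float)
    if T.shape != F.shape:
        raise ValueError("concentrations and intensities must have equal length")
    if len(np.unique(T)) < 3:
        raise FitError("need >= 3 distinct concentrations for a K_D fit")
    if np.all(F == 0) or np.ptp(F) == 0:
        raise FitError("intensities carry no binding signal (flat curve)")

    def model(t, fmax, kd):
        return fmax * t / (t + kd)

    try:
        popt, _ = curve_fit(
            model,
            T,
            F,
            p0=[float(F.max()), float(np.median(T))],
            bounds=([1e-12, 1e-12], [np.inf, np.inf]),
            maxfev=10_000,
        )
    except RuntimeError as exc:  # pragma: no cover - scipy non-convergence
        raise FitError(f"K_D fit did not converge: {exc}") from exc
    fmax, kd = popt
    return float(kd), float(fmax)


@dataclass(frozen=True)
class KdInterval:
    """Open K_D interval (lo, hi) in nM; *conflict* marks inconsistent levels."""

    lo: float
    hi: float
    conflict: bool = False

    def contains(self, kd: float) -> bool:
        return self.lo < kd < self.hi


def assign_approximate_kd(
    intensities: Sequence[float],
    f_max: float,
    concentrations: Sequence[float],
    tolerance: float = 0.1,
) -> KdInterval:
    """Interval K_D assignment from median intensities at a few concentrations.

    Per concentration [T]: intensity <= F_max/5 implies K_D > 4[T];
    in (F_max/5, F_max/3] implies 2[T] < K_D < 4[T]; above F_max/3 implies
    K_D < 2[T]. Individual intervals are intersected into the tightest
    consistent interval; if they are inconsistent (noise), the widest
    consistent hull is returned with the conflict flag set.
    """
    T = np.asarray(concentrations, dtype=float)
    F = np.asarray(intensities, dtype=float)
    if np.any(np.diff(T) <= 0):
        raise ValueError("concentrations must be sorted ascending")
    if np.any(F < 0) or np.any(F > f_max * (1 + tolerance)):
        raise ValueError("intensities outside [0, f_max*(1+tolerance)]")
    los, his = [], []
    for t, f in zip(T, F):
        if f <= f_max / 5:
            los.append(4 * t)
            his.append(np.inf)
        elif f <= f_max / 3:
            los.append(2 * t)
            his.append(4 * t)
        else:
            los.append(0.0)
            his.append(2 * t)
    lo, hi = max(los), min(his)
    if lo < hi:
        return KdInterval(lo, hi, conflict=False)
    return KdInterval(min(los), max(his), conflict=True)
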