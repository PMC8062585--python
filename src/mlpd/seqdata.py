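"""Sequencing-pool data handling for particle-display screens.

Covers read filtering, Levenshtein clustering of variable regions
(k-mer-signature candidate generation, edit-distance verification, connected
components, and an all-pairs/projection split for large inputs), per-stringency
ternary labeling, the seven-level SuperBin summary, pool normalization,
cross-stringency concordance, and cluster-respecting train/test folds.
"""

from __future__ import annotations

import itertools
import json
import math
import warnings
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import edlib
import numpy as np
import pandas as pd

from ._util import BASES, derive_rng

# Ternary per-stringency labels.
POSITIVE = 1
NEGATIVE = 0
AMBIGUOUS = -1

DEFAULT_MAX_EDIT = 5
DEFAULT_COSINE_MAX = 0.9
DEFAULT_SIGNATURE_K = 6


# ---------------------------------------------------------------------------
# Count tables
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PoolInfo:
    """Metadata for one sequenced FACS pool."""

    name: str
    round: int
    concentration: float  # target concentration [T] in nM
    polarity: str  # "pos" (above gate) or "neg" (below gate)
    total_reads: int
    expected_coverage: float  # expected reads for one full bead-complement

    def __post_init__(self) -> None:
        if self.polarity not in ("pos", "neg"):
            raise ValueError(f"polarity must be 'pos'/'neg', got {self.polarity!r}")


def pool_name(round_: int, concentration: float, polarity: str) -> str:
    return f"R{round_}_{concentration:g}nM_{polarity}"


class CountTable:
    """Per-sequence sequencing counts across named pools.

    Thin wrapper over a pandas DataFrame (rows = sequences, columns = pools,
    values = raw read counts) plus per-pool :class:`PoolInfo` metadata.
    """

    def __init__(self, df: pd.DataFrame, pools: Mapping[str, PoolInfo]):
        if set(df.columns) != set(pools):
            raise ValueError("count columns and pool metadata disagree")
        if (df.values < 0).any():
            raise ValueError("counts must be non-negative")
        self.df = df.astype(np.int64)
        self.pools = dict(pools)

    @classmethod
    def from_counts(
        cls, counts: Mapping[str, Mapping[str, int]], pools: Iterable[PoolInfo]
    ) -> "CountTable":
        """Build from ``{pool name: {sequence: count}}``."""
        pools = {p.name: p for p in pools}
        df = pd.DataFrame(
            {name: pd.Series(c, dtype=np.int64) for name, c in counts.items()},
            columns=list(pools),
        ).fillna(0)
        df = df.sort_index()
        return cls(df, pools)

    @property
    def sequences(self) -> list[str]:
        return list(self.df.index)

    def total_counts(self) -> pd.Series:
        """Summed raw count per sequence across all pools."""
        return self.df.sum(axis=1)

    def pool_total(self, name: str) -> int:
        return int(self.df[name].sum())

    # -- persistence (TSV pools + JSON manifest) ----------------------------

    def write(self, directory: str | Path) -> Path:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        manifest = {"pools": []}
        for name, info in self.pools.items():
            path = directory / f"{name}.tsv"
            col = self.df[name]
            col[col > 0].rename("count").to_csv(path, sep="\t", index_label="sequence")
            manifest["pools"].append(
                {
                    "name": name,
                    "round": info.round,
                    "concentration_nm": info.concentration,
                    "polarity": info.polarity,
                    "total_reads": info.total_reads,
                    "expected_coverage": info.expected_coverage,
                    "path": path.name,
                }
            )
        manifest_path = directory / "manifest.json"
        manifest_path.write_text(json.dumps(manifest, indent=1))
        return manifest_path

    @classmethod
    def read(cls, directory: str | Path) -> "CountTable":
        directory = Path(directory)
        manifest = json.loads((directory / "manifest.json").read_text())
        counts: dict[str, dict[str, int]] = {}
        pools = []
        for entry in manifest["pools"]:
            info = PoolInfo(
                name=entry["name"],
                round=int(entry["round"]),
                concentration=float(entry["concentration_nm"]),
                polarity=entry["polarity"],
                total_reads=int(entry["total_reads"]),
                expected_coverage=float(entry["expected_coverage"]),
            )
            series = pd.read_csv(directory / entry["path"], sep="\t", index_col="sequence")[
                "count"
            ]
            if int(series.sum()) != info.total_reads:
                raise ValueError(
                    f"pool {info.name}: counts sum to {series.sum()}, manifest "
                    f"says {info.total_reads}"
                )
            counts[info.name] = series.to_dict()
            pools.append(info)
        return cls.from_counts(counts, pools)


def normalize_counts(table: CountTable, per: str = "pool") -> pd.DataFrame:
    """Sequencing fractions: count / total, per pool (default) or per experiment."""
    df = table.df.astype(float)
    if per == "pool":
        totals = df.sum(axis=0)
        empty = totals[totals == 0].index
        if len(empty):
            warnings.warn(f"empty pools normalized to zero: {list(empty)}")
            totals = totals.replace(0, 1)
        return df / totals
    if per == "experiment":
        grand = df.values.sum()
        return df / (grand if grand else 1)
    raise ValueError(f"per must be 'pool' or 'experiment', got {per!r}")


# ---------------------------------------------------------------------------
# Read filtering
# ---------------------------------------------------------------------------


def filter_and_extract(
    reads: Iterable,
    forward_primer: str,
    reverse_primer: str,
    region_length: int = 40,
    min_mean_quality: float = 20.0,
) -> tuple[list[str], Counter]:
    """Extract fixed-length variable regions between exact primer matches.

    *reads* may be Bio.SeqRecord objects (FASTQ, with ``phred_quality``),
    ``(sequence, qualities)`` tuples, or plain strings (quality check skipped).
    Returns the kept inserts and a tally of rejection reasons.
    """
    kept: list[str] = []
    rejects: Counter = Counter()
    for read in reads:
        if isinstance(read, str):
            seq, quals = read, None
        elif isinstance(read, tuple):
            seq, quals = read
        else:  # Bio.SeqRecord
            seq = str(read.seq)
            quals = read.letter_annotations.get("phred_quality")
        fp = seq.find(forward_primer)
        if fp < 0:
            rejects["primer"] += 1
            continue
        start = fp + len(forward_primer)
        rp = seq.find(reverse_primer, start)
        if rp < 0:
            rejects["primer"] += 1
            continue
        insert = seq[start:rp]
        if len(insert) != region_length:
            rejects["length"] += 1
            continue
        if any(c not in BASES for c in insert):
            rejects["ambiguous"] += 1
            continue
        if quals is not None and np.mean(quals[start:rp]) < min_mean_quality:
            rejects["quality"] += 1
            continue
        kept.append(insert)
    return kept, rejects


# ---------------------------------------------------------------------------
# Clustering: signatures -> candidates -> verified edges -> components
# ---------------------------------------------------------------------------


def kmer_signature(sequence: str, k: int = DEFAULT_SIGNATURE_K) -> dict[str, int]:
    """Sparse k-mer occurrence-count vector (entries sum to L-k+1)."""
    if len(sequence) < k:
        raise ValueError(f"sequence shorter than k={k}: {sequence!r}")
    sig: dict[str, int] = {}
    for i in range(len(sequence) - k + 1):
        kmer = sequence[i : i + k]
        sig[kmer] = sig.get(kmer, 0) + 1
    return sig


def _cosine_distance(a: Mapping[str, int], b: Mapping[str, int]) -> float:
    if len(b) < len(a):
        a, b = b, a
    dot = sum(v * b.get(kmer, 0) for kmer, v in a.items())
    na = math.sqrt(sum(v * v for v in a.values()))
    nb = math.sqrt(sum(v * v for v in b.values()))
    if na == 0 or nb == 0:
        return 1.0
    return 1.0 - dot / (na * nb)


def candidate_neighbors(
    signatures: Sequence[Mapping[str, int]],
    cosine_distance_max: float = DEFAULT_COSINE_MAX,
) -> list[tuple[int, int]]:
    """All index pairs sharing >= 1 k-mer with cosine distance <= threshold.

    Inverted-index candidate generation: only pairs that co-occur in some
    posting list are ever compared, which is a superset of any Levenshtein
    neighborhood tight enough for the q-gram bound to apply.
    """
    if not 0 < cosine_distance_max < 1:
        raise ValueError("cosine_distance_max must be in (0,1)")
    postings: dict[str, list[int]] = defaultdict(list)
    for i, sig in enumerate(signatures):
        for kmer in sig:
            postings[kmer].append(i)
    seen: set[tuple[int, int]] = set()
    out: list[tuple[int, int]] = []
    for ids in postings.values():
        for i, j in itertools.combinations(ids, 2):
            pair = (i, j) if i < j else (j, i)
            if pair in seen:
                continue
            seen.add(pair)
            if _cosine_distance(signatures[pair[0]], signatures[pair[1]]) <= cosine_distance_max:
                out.append(pair)
    out.sort()
    return out


def candidate_neighbors_between(
    query_signatures: Sequence[Mapping[str, int]],
    index_signatures: Sequence[Mapping[str, int]],
    cosine_distance_max: float = DEFAULT_COSINE_MAX,
) -> list[tuple[int, int]]:
    """Candidate (query, index) pairs for projecting one set onto another."""
    postings: dict[str, list[int]] = defaultdict(list)
    for i, sig in enumerate(index_signatures):
        for kmer in sig:
            postings[kmer].append(i)
    out: list[tuple[int, int]] = []
    for qi, sig in enumerate(query_signatures):
        cand: set[int] = set()
        for kmer in sig:
            cand.update(postings.get(kmer, ()))
        for ij in sorted(cand):
            if _cosine_distance(sig, index_signatures[ij]) <= cosine_distance_max:
                out.append((qi, ij))
    return out


def levenshtein(a: str, b: str, max_edit: int | None = None) -> int:
    """Edit distance via edlib; returns -1 if above *max_edit* (banded mode)."""
    k = -1 if max_edit is None else max_edit
    return edlib.align(a, b, task="distance", k=k)["editDistance"]


def verify_neighbors(
    pairs: Iterable[tuple[int, int]],
    sequences: Sequence[str],
    other_sequences: Sequence[str] | None = None,
    max_edit: int = DEFAULT_MAX_EDIT,
) -> list[tuple[int, int]]:
    """Keep candidate pairs whose Levenshtein distance is <= max_edit (inclusive)."""
    right = sequences if other_sequences is None else other_sequences
    edges = []
    for i, j in pairs:
        d = levenshtein(sequences[i], right[j], max_edit)
        if 0 <= d <= max_edit:
            edges.append((i, j))
    return edges


@dataclass
class ClusterAssignment:
    """Sequence -> cluster id map with representatives and phase provenance."""

    assignment: dict[str, int]
    representatives: dict[int, str] = field(default_factory=dict)
    phase: dict[str, str] = field(default_factory=dict)  # "all_pairs" | "projected"

    @property
    def n_clusters(self) -> int:
        return len(set(self.assignment.values()))

    def members(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = defaultdict(list)
        for seq, cid in self.assignment.items():
            out[cid].append(seq)
        return dict(out)

    def compute_representatives(self, counts: Mapping[str, int] | None = None) -> None:
        """Representative = member with maximal summed count; ties lexicographic."""
        counts = counts or {}
        for cid, seqs in self.members().items():
            self.representatives[cid] = min(seqs, key=lambda s: (-counts.get(s, 0), s))

    def write(self, path: str | Path) -> None:
        rows = [
            {
                "sequence": seq,
                "cluster": cid,
                "phase": self.phase.get(seq, "all_pairs"),
                "representative": self.representatives.get(cid, ""),
            }
            for seq, cid in sorted(self.assignment.items())
        ]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)

    @classmethod
    def read(cls, path: str | Path) -> "ClusterAssignment":
        df = pd.read_csv(path, sep="\t")
        ca = cls(
            assignment=dict(zip(df["sequence"], df["cluster"])),
            phase=dict(zip(df["sequence"], df["phase"])),
        )
        reps = df.dropna(subset=["representative"])
        ca.representatives = dict(zip(reps["cluster"], reps["representative"]))
        return ca


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


def connected_components(
    edges: Iterable[tuple[int, int]],
    nodes: Sequence[str],
    counts: Mapping[str, int] | None = None,
) -> ClusterAssignment:
    """Cluster ids from connected components; isolated nodes become singletons.

    Cluster ids are dense and ordered by each component's smallest node index,
    so the labeling is deterministic for a fixed node order.
    """
    uf = _UnionFind(len(nodes))
    for i, j in edges:
        uf.union(i, j)
    root_to_cid: dict[int, int] = {}
    assignment: dict[str, int] = {}
    for i, seq in enumerate(nodes):
        root = uf.find(i)
        if root not in root_to_cid:
            root_to_cid[root] = len(root_to_cid)
        assignment[seq] = root_to_cid[root]
    ca = ClusterAssignment(assignment, phase={s: "all_pairs" for s in nodes})
    ca.compute_representatives(counts)
    return ca


def cluster_all_pairs(
    sequences: Sequence[str],
    counts: Mapping[str, int] | None = None,
    max_edit: int = DEFAULT_MAX_EDIT,
    cosine_distance_max: float = DEFAULT_COSINE_MAX,
    signature_k: int = DEFAULT_SIGNATURE_K,
) -> ClusterAssignment:
    """Full candidate/verify/components pipeline on one sequence set."""
    sigs = [kmer_signature(s, signature_k) for s in sequences]
    cand = candidate_neighbors(sigs, cosine_distance_max)
    edges = verify_neighbors(cand, sequences, max_edit=max_edit)
    return connected_components(edges, sequences, counts)


def cluster_with_projection(
    table: CountTable | Mapping[str, int],
    all_pairs_cap: int = 100_000,
    max_edit: int = DEFAULT_MAX_EDIT,
    cosine_distance_max: float = DEFAULT_COSINE_MAX,
    signature_k: int = DEFAULT_SIGNATURE_K,
) -> ClusterAssignment:
    """Two-phase clustering for large inputs.

    Multi-read sequences (total count > 1 across all pools) fill the all-pairs
    subset, padded with singletons up to *all_pairs_cap*; the remainder is
    projected onto the nearest verified all-pairs cluster (ties: smaller
    Levenshtein distance, then smaller cluster id) or becomes a new singleton.
    """
    if all_pairs_cap < 1:
        raise ValueError("all_pairs_cap must be >= 1")
    if isinstance(table, CountTable):
        totals = table.total_counts().to_dict()
    else:
        totals = dict(table)
    # deterministic priority: multi-read first, by count descending then sequence
    ordered = sorted(totals, key=lambda s: (-totals[s], s))
    core = [s for s in ordered if totals[s] > 1]
    singles = [s for s in ordered if totals[s] <= 1]
    core = core[:all_pairs_cap]
    pad = all_pairs_cap - len(core)
    core_set = set(core)
    core += [s for s in singles if s not in core_set][:max(pad, 0)]
    core_set = set(core)
    projected = [s for s in ordered if s not in core_set]

    ca = cluster_all_pairs(core, totals, max_edit, cosine_distance_max, signature_k)
    next_cid = ca.n_clusters
    if projected:
        core_sigs = [kmer_signature(s, signature_k) for s in core]
        proj_sigs = [kmer_signature(s, signature_k) for s in projected]
        cand = candidate_neighbors_between(proj_sigs, core_sigs, cosine_distance_max)
        by_query: dict[int, list[tuple[int, int]]] = defaultdict(list)
        for qi, ij in cand:
            d = levenshtein(projected[qi], core[ij], max_edit)
            if 0 <= d <= max_edit:
                by_query[qi].append((d, ca.assignment[core[ij]]))
        for qi, seq in enumerate(projected):
            hits = by_query.get(qi)
            if hits:
                _, cid = min(hits)
                ca.assignment[seq] = cid
            else:
                ca.assignment[seq] = next_cid
                next_cid += 1
            ca.phase[seq] = "projected"
    ca.compute_representatives(totals)
    return ca


# ---------------------------------------------------------------------------
# Stringency labels
# ---------------------------------------------------------------------------


class StringencyLabels:
    """Ternary label per (sequence, stringency level).

    Columns are target concentrations ordered weakest (highest [T]) to
    strongest (lowest [T]); values are POSITIVE/NEGATIVE/AMBIGUOUS.
    """

    def __init__(self, df: pd.DataFrame):
        self.df = df.astype(np.int8)
        self.concentrations = [float(c) for c in df.columns]
        if self.concentrations != sorted(self.concentrations, reverse=True):
            raise ValueError("stringency columns must be ordered weakest to strongest")

    @property
    def sequences(self) -> list[str]:
        return list(self.df.index)

    def write(self, path: str | Path) -> None:
        out = self.df.copy()
        out.columns = [f"{c:g}" for c in self.concentrations]
        out.to_csv(path, sep="\t", index_label="sequence")

    @classmethod
    def read(cls, path: str | Path) -> "StringencyLabels":
        df = pd.read_csv(path, sep="\t", index_col="sequence")
        df.columns = [float(c) for c in df.columns]
        return cls(df)


def label_pools(table: CountTable, coverage_fraction: float = 0.2) -> StringencyLabels:
    """Ternary per-stringency labels from paired positive/negative pools.

    A sequence is positive at a level if its count in the positive pool is at
    least ``coverage_fraction`` of the pool's expected bead coverage AND its
    normalized fraction is larger in the positive pool than in the negative
    pool; negative under the mirrored criterion; otherwise ambiguous. When a
    level was screened in several rounds, the latest round with a
    non-ambiguous call wins (round-1 negative pools supply negatives for
    sequences that never reached round 2).
    """
    by_level: dict[float, dict[int, dict[str, PoolInfo]]] = defaultdict(dict)
    for info in table.pools.values():
        by_level[info.concentration].setdefault(info.round, {})[info.polarity] = info
    concentrations = sorted(by_level, reverse=True)
    with warnings.catch_warnings():
        # empty pools (e.g. a noiseless negative pool) are expected here
        warnings.simplefilter("ignore", UserWarning)
        fractions = normalize_counts(table)
    seqs = table.df.index
    data = {}
    for conc in concentrations:
        rounds = by_level[conc]
        paired = {r: p for r, p in rounds.items() if set(p) == {"pos", "neg"}}
        if not paired:
            raise ValueError(f"stringency {conc:g} nM lacks a paired pos/neg pool")
        level = np.full(len(seqs), AMBIGUOUS, dtype=np.int8)
        for r in sorted(paired):  # later rounds overwrite earlier non-ambiguous calls
            pos, neg = paired[r]["pos"], paired[r]["neg"]
            cp = table.df[pos.name].values
            cn = table.df[neg.name].values
            fp = fractions[pos.name].values
            fn = fractions[neg.name].values
            is_pos = (cp >= coverage_fraction * pos.expected_coverage) & (fp > fn)
            is_neg = (cn >= coverage_fraction * neg.expected_coverage) & (fn > fp)
            level[is_pos] = POSITIVE
            level[is_neg & ~is_pos] = NEGATIVE
        data[conc] = level
    return StringencyLabels(pd.DataFrame(data, index=seqs))


def superbin(labels: StringencyLabels) -> pd.Series:
    """Collapse per-stringency ternary labels into a single affinity level.

    With *m* stringencies the levels run 0..2m (seven levels for m = 3):
    level = 2 x (consecutive stringencies passed from the weakest), plus one
    if the next stricter level is borderline (ambiguous). Sequences with
    conflicting labels (positive at a stricter level but negative at a weaker
    one) or with no information at all (all ambiguous) are excluded.
    """
    vals = labels.df.values  # ordered weakest -> strongest
    m = vals.shape[1]
    levels = {}
    for seq, row in zip(labels.df.index, vals):
        neg_seen = False
        conflict = False
        for v in row:
            if v == NEGATIVE:
                neg_seen = True
            elif v == POSITIVE and neg_seen:
                conflict = True
                break
        if conflict or (row == AMBIGUOUS).all():
            continue
        p = 0
        while p < m and row[p] == POSITIVE:
            p += 1
        level = 2 * p
        if p < m and row[p] == AMBIGUOUS:
            level += 1
        levels[seq] = level
    return pd.Series(levels, dtype=np.int64, name="superbin_level")


def concordance(labels: StringencyLabels) -> pd.Series:
    """Per stringency, the fraction of its positives also positive at every
    weaker stringency (vacuously 1.0 at the weakest level)."""
    vals = labels.df.values
    out = {}
    for j, conc in enumerate(labels.concentrations):
        pos = vals[:, j] == POSITIVE
        if j == 0 or not pos.any():
            out[conc] = 1.0
            continue
        nested = pos & (vals[:, :j] == POSITIVE).all(axis=1)
        out[conc] = nested.sum() / pos.sum()
    return pd.Series(out, name="concordance")


# ---------------------------------------------------------------------------
# Train/test folds
# ---------------------------------------------------------------------------


@dataclass
class SplitAssignment:
    """Cluster -> fold map with a designated test fold."""

    fold_of_cluster: dict[int, int]
    n_folds: int
    test_fold: int
    clusters: ClusterAssignment

    def fold_of_sequence(self, seq: str) -> int:
        return self.fold_of_cluster[self.clusters.assignment[seq]]

    def train_test_sequences(self) -> tuple[list[str], list[str]]:
        train, test = [], []
        for seq in sorted(self.clusters.assignment):
            (test if self.fold_of_sequence(seq) == self.test_fold else train).append(seq)
        return train, test

    def write(self, path: str | Path) -> None:
        rows = [
            {"sequence": s, "cluster": cid, "fold": self.fold_of_cluster[cid]}
            for s, cid in sorted(self.clusters.assignment.items())
        ]
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def split_folds(
    clusters: ClusterAssignment,
    n_folds: int = 5,
    test_fold: int = 0,
    seed: int = 0,
) -> SplitAssignment:
    """Shuffle clusters with the seed, deal them round-robin into folds.

    No cluster ever spans folds, so sequence pairs within the clustering edit
    distance can never leak across the train/test boundary.
    """
    cids = sorted(set(clusters.assignment.values()))
    if len(cids) < n_folds:
        warnings.warn(
            f"only {len(cids)} clusters for {n_folds} folds; some folds will be empty"
        )
    rng = derive_rng(seed, "split_folds")
    order = [cids[i] for i in rng.permutation(len(cids))]
    fold_of_cluster = {cid: pos % n_folds for pos, cid in enumerate(order)}
    return SplitAssignment(fold_of_cluster, n_folds, test_fold, clusters)
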