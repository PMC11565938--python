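"""MinHash set representation of RNA-seq samples.

A sample's reads are decomposed into canonical k-mers (the lexicographic
minimum of each k-mer and its reverse complement, so the representation is
strand-neutral); k-mers seen fewer than ``min_count`` times are discarded as
likely sequencing errors; each surviving k-mer is hashed with a fixed,
seeded 64-bit mixer and the ``s`` smallest distinct hash values are kept
together with their k-mer counts.  The resulting set of (hash, count) pairs
is the neural encoder's input and also supports the Mash distance

    d(A, B) = -ln(2j / (1 + j)) / k,

where ``j`` is the bottom-s Jaccard estimate of the two sketches
(``j = 0`` saturates the distance at 1).

Defaults follow common sketching practice: k = 21, s = 1000, min_count = 2.
"""

from __future__ import annotations

import gzip
import json
from dataclasses import dataclass, field
from collections import Counter
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "SketchSet",
    "kmerize",
    "minhash_sketch",
    "mash_distance",
    "znorm_corpus",
    "apply_znorm",
    "read_sequences",
]

_CODE = np.full(256, 255, dtype=np.uint8)
for i, b in enumerate(b"ACGT"):
    _CODE[b] = i
    _CODE[ord(chr(b).lower())] = i

#: golden-ratio constant used to fold the seed into the hash input
_SEED_MIX = np.uint64(0x9E3779B97F4A7C15)


def _mix64(x: np.ndarray, seed: int) -> np.ndarray:
    """Seeded splitmix64-style finalizer on uint64 values (wraps mod 2^64)."""
    x = x.astype(np.uint64, copy=True)
    x ^= np.uint64((int(seed) * 0x9E3779B97F4A7C15) % (1 << 64))
    x ^= x >> np.uint64(30)
    x *= np.uint64(0xBF58476D1CE4E5B9)
    x ^= x >> np.uint64(27)
    x *= np.uint64(0x94D049BB133111EB)
    x ^= x >> np.uint64(31)
    return x


def _packed_canonical_kmers(read: str, k: int) -> np.ndarray:
    """2-bit-packed canonical k-mers of one read; non-ACGT windows skipped.

    With the alphabetical base encoding A=0 < C=1 < G=2 < T=3, numeric order
    of packed values equals lexicographic order of the k-mer strings, so the
    canonical form is simply min(packed forward, packed reverse complement).
    """
    if len(read) < k:
        return np.empty(0, dtype=np.uint64)
    codes = _CODE[np.frombuffer(read.encode("ascii"), dtype=np.uint8)]
    win = np.lib.stride_tricks.sliding_window_view(codes, k)
    valid = (win != 255).all(axis=1)
    if not valid.any():
        return np.empty(0, dtype=np.uint64)
    win = win[valid].astype(np.uint64)
    shifts_f = np.arange(k - 1, -1, -1, dtype=np.uint64) * np.uint64(2)
    fwd = (win << shifts_f).sum(axis=1, dtype=np.uint64)
    # reverse complement: complement (3 - c) and reverse the window
    shifts_r = np.arange(k, dtype=np.uint64) * np.uint64(2)
    rev = ((np.uint64(3) - win) << shifts_r).sum(axis=1, dtype=np.uint64)
    return np.minimum(fwd, rev)


def _unpack(packed: int, k: int) -> str:
    bases = "ACGT"
    return "".join(bases[(packed >> (2 * (k - 1 - i))) & 3] for i in range(k))


def kmerize(reads: Iterable[str], k: int) -> Counter:
    """Multiset (Counter) of canonical k-mer strings over all reads."""
    if k < 1:
        raise ValueError("k must be positive")
    counts: Counter = Counter()
    for read in reads:
        for packed in _packed_canonical_kmers(read, k):
            counts[_unpack(int(packed), k)] += 1
    return counts


@dataclass
class SketchSet:
    """Bottom-s MinHash sketch: sorted hash values with k-mer counts."""

    hashes: np.ndarray  # uint64, ascending
    counts: np.ndarray  # int64, parallel to hashes
    k: int = 21
    s: int = 1000
    min_count: int = 2
    seed: int = 42
    sample_id: str = ""

    def __post_init__(self) -> None:
        self.hashes = np.asarray(self.hashes, dtype=np.uint64)
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if len(self.hashes) != len(self.counts):
            raise ValueError("hashes/counts length mismatch")
        if len(self.hashes) > self.s:
            raise ValueError("sketch larger than its nominal size")
        if np.any(np.diff(self.hashes.astype(np.uint64)) <= 0) and len(
            self.hashes
        ) > 1:
            raise ValueError("hashes must be strictly ascending")

    def __len__(self) -> int:
        return len(self.hashes)

    def elements(self) -> np.ndarray:
        """(n, 2) float array of (hash value, k-mer count) pairs."""
        return np.column_stack(
            [self.hashes.astype(np.float64), self.counts.astype(np.float64)]
        )

    def save(self, path: str | Path) -> None:
        payload = {
            "k": self.k,
            "s": self.s,
            "min_count": self.min_count,
            "seed": self.seed,
            "sample_id": self.sample_id,
            "hashes": [int(h) for h in self.hashes],
            "counts": [int(c) for c in self.counts],
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path: str | Path) -> "SketchSet":
        payload = json.loads(Path(path).read_text())
        return cls(
            hashes=np.array(payload["hashes"], dtype=np.uint64),
            counts=np.array(payload["counts"], dtype=np.int64),
            k=payload["k"],
            s=payload["s"],
            min_count=payload["min_count"],
            seed=payload["seed"],
            sample_id=payload.get("sample_id", ""),
        )


def minhash_sketch(
    reads: Iterable[str],
    k: int = 21,
    s: int = 1000,
    min_count: int = 2,
    seed: int = 42,
    sample_id: str = "",
) -> SketchSet:
    """Bottom-s sketch of the canonical k-mer content of a read set."""
    if k < 1 or s < 1 or min_count < 1:
        raise ValueError("k, s and min_count must be positive")
    chunks = [_packed_canonical_kmers(r, k) for r in reads]
    if chunks:
        packed = np.concatenate(chunks)
    else:
        packed = np.empty(0, dtype=np.uint64)
    if len(packed) == 0:
        return SketchSet(
            np.empty(0, np.uint64), np.empty(0, np.int64), k, s, min_count, seed,
            sample_id,
        )
    kmers, counts = np.unique(packed, return_counts=True)
    keep = counts >= min_count
    kmers, counts = kmers[keep], counts[keep]
    hashes = _mix64(kmers, seed)
    order = np.argsort(hashes, kind="stable")
    hashes, counts = hashes[order], counts[order]
    # 64-bit collisions are vanishingly rare; merge counts if they occur
    if len(hashes) > 1 and np.any(np.diff(hashes) == 0):
        uniq, idx = np.unique(hashes, return_index=True)
        merged = np.add.reduceat(counts, idx)
        hashes, counts = uniq, merged
    return SketchSet(
        hashes[:s], counts[:s].astype(np.int64), k, s, min_count, seed, sample_id
    )


def mash_distance(a: SketchSet, b: SketchSet) -> float:
    """Mash k-mer distance between two sketches (same k and hash seed)."""
    if a.k != b.k or a.seed != b.seed:
        raise ValueError("sketches must share k and hash seed")
    if len(a) == 0 or len(b) == 0:
        return 1.0
    union = np.union1d(a.hashes, b.hashes)
    bottom = union[: min(min(a.s, b.s), len(union))]
    shared = np.intersect1d(bottom, np.intersect1d(a.hashes, b.hashes)).size
    j = shared / len(bottom)
    if j <= 0:
        return 1.0
    if j >= 1:
        return 0.0
    return float(min(1.0, -np.log(2 * j / (1 + j)) / a.k))


def znorm_corpus(
    sketches: Sequence[SketchSet],
) -> tuple[list[np.ndarray], dict]:
    """Z-score both element dimensions over a training corpus of sketches.

    The mean/std of the hash-value and count dimensions are pooled over all
    elements of all sketches (corpus-wide, so hash values stay comparable
    across samples) and returned so new samples can be normalized the same
    way.
    """
    if not sketches:
        raise ValueError("empty sketch corpus")
    pooled = np.concatenate([sk.elements() for sk in sketches], axis=0)
    mean = pooled.mean(axis=0)
    std = pooled.std(axis=0)
    if np.any(std == 0):
        raise ValueError("zero-variance dimension; cannot z-normalize")
    stats = {
        "hash_mean": float(mean[0]),
        "hash_std": float(std[0]),
        "count_mean": float(mean[1]),
        "count_std": float(std[1]),
    }
    return [apply_znorm(sk, stats) for sk in sketches], stats


def apply_znorm(sketch: SketchSet, stats: dict) -> np.ndarray:
    """Normalize one sketch's elements with stored corpus statistics."""
    el = sketch.elements()
    out = np.empty_like(el)
    out[:, 0] = (el[:, 0] - stats["hash_mean"]) / stats["hash_std"]
    out[:, 1] = (el[:, 1] - stats["count_mean"]) / stats["count_std"]
    return out


def read_sequences(path: str | Path) -> list[str]:
    """Read sequences from FASTA or FASTQ, optionally gzip-compressed."""
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    stem = path.name[:-3] if path.suffix == ".gz" else path.name
    with opener(path, "rt") as fh:
        first = fh.read(1)
        fh.seek(0)
        seqs = []
        if first == ">":  # FASTA
            cur: list[str] = []
            for line in fh:
                line = line.strip()
                if line.startswith(">"):
                    if cur:
                        seqs.append("".join(cur))
                        cur = []
                elif line:
                    cur.append(line)
            if cur:
                seqs.append("".join(cur))
        elif first == "@":  # FASTQ
            while True:
                header = fh.readline()
                if not header:
                    break
                seq = fh.readline().strip()
                fh.readline()
                fh.readline()
                if seq:
                    seqs.append(seq)
        else:
            raise ValueError(f"unrecognized sequence format: {stem}")
    return seqs


def write_fastq(reads: Sequence[str], path: str | Path, prefix: str = "r") -> None:
    with open(path, "w") as fh:
        for i, seq in enumerate(reads):
            fh.write(f"@{prefix}{i}\n{seq}\n+\n{'I' * len(seq)}\n")
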