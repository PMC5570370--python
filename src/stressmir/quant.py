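"""Small-RNA read quantification against a mature-miRNA reference.

The pipeline turns raw small-RNA reads into a per-sample count column:

1. 3' adapter trimming (leftmost adapter-prefix occurrence).
2. Quality surrogate: drop reads with more than 10% N calls.
3. Length filter: reads shorter than 18 nt are removed.
4. Positional (Hamming) matching against mature sequences: a hit requires
   zero mismatches in the first 18 nt and at most two mismatches after
   position 18.  No indels.  Reads longer than the reference are compared
   over the reference length with up to 3 nt of untemplated 3' overhang
   tolerated; shorter reads are compared over the read length.
5. Multimapping: reads hitting more than ``max_hits`` (default 5) reference
   records (weighted by optional per-record genome copy counts) are
   discarded; ties at the minimum mismatch count are assigned fractionally
   (1/k to each of k tied records) so column totals equal the number of
   counted reads.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import SeqIO

_VALID = set("ACGTN")


def _normalize(seq: str) -> str:
    return seq.upper().replace("U", "T")


@dataclass
class MatureReference:
    """Ordered mature-miRNA records: id -> sequence, optional genome copy count."""

    sequences: dict[str, str]
    copy_counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        norm = {}
        for rid, seq in self.sequences.items():
            if not seq:
                raise ValueError(f"empty sequence for {rid}")
            norm[rid] = _normalize(seq)
        self.sequences = norm

    @classmethod
    def from_fasta(cls, path) -> "MatureReference":
        opener = gzip.open if str(path).endswith(".gz") else open
        with opener(path, "rt") as fh:
            records = list(SeqIO.parse(fh, "fasta"))
        ids = [r.id for r in records]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate ids in reference FASTA")
        return cls({r.id: str(r.seq) for r in records})

    def copies(self, rid: str) -> int:
        return self.copy_counts.get(rid, 1)

    def __len__(self) -> int:
        return len(self.sequences)

    def items(self):
        return self.sequences.items()


@dataclass(frozen=True)
class ReadHit:
    """One read-to-reference alignment passing the mismatch rules."""

    read_id: str
    mirna_id: str
    mismatch_positions: tuple[int, ...]
    n_mismatch_head: int  # within the first 18 nt
    n_mismatch_tail: int  # at positions >= 18

    @property
    def n_mismatch(self) -> int:
        return self.n_mismatch_head + self.n_mismatch_tail


def trim_adapter(read: str, adapter: str, min_overlap: int = 5) -> str:
    """Remove the suffix starting at the leftmost adapter(-prefix) occurrence.

    A match at position ``i`` means ``read[i:]`` equals a prefix of the
    adapter of length >= ``min_overlap`` (a full internal adapter occurrence
    also matches, as the prefix then extends to the adapter's full length).
    Returns the read unchanged when no occurrence is found.
    """
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    n, m = len(read), len(adapter)
    for i in range(0, n - min_overlap + 1):
        span = min(n - i, m)
        if span >= min_overlap and read[i : i + span] == adapter[:span]:
            return read[:i]
    return read


def drop_low_quality(reads, max_n_frac: float = 0.1):
    """Quality surrogate: drop reads whose N fraction exceeds ``max_n_frac``."""
    kept = []
    for item in reads:
        seq = item[1] if isinstance(item, tuple) else item
        if len(seq) == 0 or seq.count("N") / len(seq) <= max_n_frac:
            kept.append(item)
    return kept


def filter_reads(reads, min_length: int = 18):
    """Retain reads of length >= ``min_length`` (order preserved)."""
    out = []
    for item in reads:
        seq = item[1] if isinstance(item, tuple) else item
        if len(seq) >= min_length:
            out.append(item)
    return out


def map_read(
    read: str,
    reference: MatureReference,
    read_id: str = "read",
    max_tail_mismatch: int = 2,
    max_overhang: int = 3,
) -> list[ReadHit]:
    """All reference records the read maps to under the positional rules.

    Hits are sorted by (total mismatch count, reference id).
    """
    read = _normalize(read)
    if set(read) - _VALID:
        bad = sorted(set(read) - _VALID)
        raise ValueError(f"read contains non-ACGTN symbols: {bad}")
    hits: list[ReadHit] = []
    for rid, ref in reference.items():
        span = min(len(read), len(ref))
        if len(read) > len(ref) + max_overhang:
            continue
        mismatches = tuple(
            i for i in range(span) if read[i] != ref[i] or read[i] == "N"
        )
        head = sum(1 for i in mismatches if i < 18)
        tail = len(mismatches) - head
        if head == 0 and tail <= max_tail_mismatch:
            hits.append(ReadHit(read_id, rid, mismatches, head, tail))
    hits.sort(key=lambda h: (h.n_mismatch, h.mirna_id))
    return hits


def quantify(
    reads,
    reference: MatureReference,
    max_hits: int = 5,
    multimap: str = "fractional",
    seed: int | None = None,
) -> pd.Series:
    """Count column for one sample from trimmed, length-filtered reads.

    Reads with zero hits, or whose copy-weighted hit multiplicity exceeds
    ``max_hits``, contribute nothing.  Among the remaining hits the best
    tier (minimum mismatch count) is counted: fractionally (1/k per tied
    record, the default, which conserves column totals) or by a seeded
    random winner (``multimap="random"``).
    """
    if len(reference) == 0:
        raise ValueError("empty reference")
    if multimap not in ("fractional", "random"):
        raise ValueError("multimap must be 'fractional' or 'random'")
    rng = np.random.default_rng(seed)
    counts = pd.Series(0.0, index=pd.Index(reference.sequences.keys(), name="mirna"))
    for item in reads:
        rid, seq = item if isinstance(item, tuple) else ("read", item)
        hits = map_read(seq, reference, read_id=rid)
        if not hits:
            continue
        multiplicity = sum(reference.copies(h.mirna_id) for h in hits)
        if multiplicity > max_hits:
            continue
        best = hits[0].n_mismatch
        tied = [h.mirna_id for h in hits if h.n_mismatch == best]
        if multimap == "fractional":
            for m in tied:
                counts[m] += 1.0 / len(tied)
        else:
            counts[tied[int(rng.integers(len(tied)))]] += 1.0
    return counts


def read_fastq(path) -> list[tuple[str, str]]:
    """Load FASTQ records as (id, sequence) pairs (gzip-transparent)."""
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "rt") as fh:
        return [(r.id, str(r.seq)) for r in SeqIO.parse(fh, "fastq")]


def quantify_sample(
    fastq_path,
    reference: MatureReference,
    adapter: str,
    min_length: int = 18,
    max_hits: int = 5,
    max_n_frac: float = 0.1,
) -> pd.Series:
    """Full per-sample pipeline: trim, quality/length filter, map, count."""
    reads = read_fastq(fastq_path)
    trimmed = [(rid, trim_adapter(seq, adapter)) for rid, seq in reads]
    kept = filter_reads(drop_low_quality(trimmed, max_n_frac), min_length)
    return quantify(kept, reference, max_hits=max_hits)
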