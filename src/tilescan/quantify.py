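"""Guide counting from amplicon FASTQ.

Reads from a pooled screen carry the integrated guide cassette: vector
backbone, then ``CACCG`` + 20-nt spacer + ``GTTT``. The spacer is pulled
out by that backbone anchor and matched exactly against the library
spacers — alignment-free and reproducible, since library spacers are exact
known sequences. Each read is searched as given and as its reverse
complement (amplicon orientation is sequencing-setup dependent); the
leftmost valid cassette wins and a read is counted once.
"""

from __future__ import annotations

import gzip
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from tilescan.library_design import SgRNALibrary

ANCHOR_5 = "CACCG"
ANCHOR_3 = "GTTT"
SPACER_LEN = 20


@dataclass(frozen=True)
class SampleMeta:
    """Screen sample identity: timepoint (day0/day16) and replicate index."""

    sample_id: str
    timepoint: str
    replicate: int

    def __post_init__(self) -> None:
        if self.timepoint not in ("day0", "day16"):
            raise ValueError(f"timepoint must be day0 or day16, got {self.timepoint!r}")
        if self.replicate < 1:
            raise ValueError("replicate index is 1-based")

    @classmethod
    def from_id(cls, sample_id: str) -> "SampleMeta":
        """Parse the canonical '<timepoint>_rep<k>' sample id."""
        timepoint, _, rep = sample_id.partition("_rep")
        return cls(sample_id=sample_id, timepoint=timepoint, replicate=int(rep))


@dataclass
class CountTable:
    """Guide × sample read counts plus per-sample extraction accounting.

    ``unmapped`` counts reads with an extractable spacer absent from the
    library; ``unextractable`` counts reads without the backbone cassette.
    mapped + unmapped + unextractable = total reads processed, per sample.
    """

    guide_ids: list[str]
    samples: list[SampleMeta]
    counts: np.ndarray  # (n_guides, n_samples) int64
    unmapped: np.ndarray = field(default=None)  # type: ignore[assignment]
    unextractable: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (len(self.guide_ids), len(self.samples)):
            raise ValueError("counts shape does not match guides × samples")
        if (self.counts < 0).any():
            raise ValueError("negative counts")
        if self.unmapped is None:
            self.unmapped = np.zeros(len(self.samples), dtype=np.int64)
        if self.unextractable is None:
            self.unextractable = np.zeros(len(self.samples), dtype=np.int64)

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    def column(self, sample_id: str) -> np.ndarray:
        return self.counts[:, self.sample_ids.index(sample_id)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.guide_ids, columns=self.sample_ids)

    def to_tsv(self, path: str | Path) -> None:
        df = self.to_frame()
        df.index.name = "guide_id"
        df.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CountTable":
        df = pd.read_csv(path, sep="\t", index_col="guide_id")
        samples = [SampleMeta.from_id(c) for c in df.columns]
        return cls(guide_ids=list(df.index), samples=samples, counts=df.to_numpy())

    @classmethod
    def concat(cls, columns: Iterable["CountTable"]) -> "CountTable":
        """Column-bind single-sample tables sharing one guide universe."""
        cols = list(columns)
        guide_ids = cols[0].guide_ids
        for c in cols[1:]:
            if c.guide_ids != guide_ids:
                raise ValueError("count tables have different guide universes")
        return cls(
            guide_ids=guide_ids,
            samples=[s for c in cols for s in c.samples],
            counts=np.hstack([c.counts for c in cols]),
            unmapped=np.concatenate([c.unmapped for c in cols]),
            unextractable=np.concatenate([c.unextractable for c in cols]),
        )

    def stats_record(self, sample_id: str) -> dict:
        j = self.sample_ids.index(sample_id)
        mapped = int(self.counts[:, j].sum())
        return {
            "sample_id": sample_id,
            "mapped": mapped,
            "unmapped": int(self.unmapped[j]),
            "unextractable": int(self.unextractable[j]),
            "total": mapped + int(self.unmapped[j]) + int(self.unextractable[j]),
        }

    def write_stats_jsonl(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for s in self.sample_ids:
                fh.write(json.dumps(self.stats_record(s)) + "\n")


def extract_spacer(read: str) -> str | None:
    """The 20 nt between the leftmost ``CACCG`` that is followed, 20 nt
    later, by ``GTTT``; ``None`` if no such cassette exists."""
    read = read.upper()
    start = 0
    while True:
        i = read.find(ANCHOR_5, start)
        if i < 0:
            return None
        lo = i + len(ANCHOR_5)
        hi = lo + SPACER_LEN
        if read[hi : hi + len(ANCHOR_3)] == ANCHOR_3:
            return read[lo:hi]
        start = i + 1


def _iter_fastq_seqs(fastq: str | Path | Iterable[str]) -> Iterator[str]:
    """Sequences from a FASTQ path (.gz ok) or an iterable of read strings."""
    if isinstance(fastq, (str, Path)):
        opener = gzip.open if str(fastq).endswith(".gz") else open
        with opener(fastq, "rt") as fh:  # type: ignore[operator]
            for k, line in enumerate(fh):
                if k % 4 == 1:
                    yield line.strip()
    else:
        yield from fastq


def count_reads(
    fastq: str | Path | Iterable[str],
    library: SgRNALibrary,
    sample: SampleMeta | str,
    mismatches: int = 0,
    search_revcomp: bool = True,
) -> CountTable:
    """Tally library spacers in one sample's reads.

    Exact matching by default; ``mismatches=1`` enables Hamming-1 rescue of
    extracted spacers against the library. Order-independent and
    deterministic.
    """
    if isinstance(sample, str):
        sample = SampleMeta.from_id(sample)
    if not library.guides:
        raise ValueError("empty library")
    index = library.spacer_index()
    guide_ids = [g.guide_id for g in library.guides]
    row = {gid: i for i, gid in enumerate(guide_ids)}
    counts = np.zeros(len(guide_ids), dtype=np.int64)
    unmapped = 0
    unextractable = 0
    for seq in _iter_fastq_seqs(fastq):
        spacer = extract_spacer(seq)
        if spacer is None and search_revcomp:
            spacer = extract_spacer(str(Seq(seq).reverse_complement()))
        if spacer is None:
            unextractable += 1
            continue
        gid = index.get(spacer)
        if gid is None and mismatches >= 1:
            gid = _hamming1_match(spacer, index)
        if gid is None:
            unmapped += 1
        else:
            counts[row[gid]] += 1
    return CountTable(
        guide_ids=guide_ids,
        samples=[sample],
        counts=counts[:, None],
        unmapped=np.array([unmapped], dtype=np.int64),
        unextractable=np.array([unextractable], dtype=np.int64),
    )


def _hamming1_match(spacer: str, index: dict[str, str]) -> str | None:
    """Unique library spacer within Hamming distance 1, else None."""
    hit: str | None = None
    for cand, gid in index.items():
        d = sum(a != b for a, b in zip(spacer, cand))
        if d <= 1:
            if hit is not None:
                return None  # ambiguous
            hit = gid
    return hit
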