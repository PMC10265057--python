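"""sgRNA tiling-library design over a coding sequence.

Enumerates every SpCas9 protospacer (20 nt + NGG PAM) on both strands of a
spliced CDS, assigns each guide a cut coordinate and codon, attaches control
guides, and computes design statistics such as the targeting density
(bp of CDS per test guide).

Coordinates are 1-based closed throughout this module. The cut site follows
standard SpCas9 biochemistry: a blunt cut between protospacer positions 17
and 18, i.e. 3 bp 5' of the PAM; ``cut_pos`` is the coding-strand coordinate
of the base immediately 5' of the cut on the coding strand.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

_VALID_BASES = frozenset("ACGT")

LIBRARY_COLUMNS = [
    "guide_id",
    "spacer",
    "strand",
    "pam_start",
    "cut_pos",
    "cut_residue",
    "category",
    "gene",
]


@dataclass(frozen=True)
class CodingSequence:
    """A spliced coding sequence in frame, 5'→3' on the coding strand."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        if not seq:
            raise ValueError("empty coding sequence")
        bad = set(seq) - _VALID_BASES
        if bad:
            raise ValueError(f"ambiguity codes not allowed in CDS: {sorted(bad)}")
        if len(seq) % 3 != 0:
            raise ValueError(f"CDS length {len(seq)} not divisible by 3")

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def n_residues(self) -> int:
        return len(self.sequence) // 3

    @classmethod
    def from_fasta(cls, path: str | Path, record_id: str | None = None) -> "CodingSequence":
        for rec in SeqIO.parse(str(path), "fasta"):
            if record_id is None or rec.id == record_id:
                return cls(id=rec.id, sequence=str(rec.seq))
        raise ValueError(f"no record {record_id!r} in {path}")


@dataclass(frozen=True)
class SgRNA:
    """One guide: spacer written 5'→3' on its own strand.

    ``pam_start`` is the 1-based coding-strand coordinate of the PAM's first
    base (the N of NGG for + guides; the first C of CCN for − guides).
    Control guides carry no coordinates.
    """

    guide_id: str
    spacer: str
    strand: str | None = None
    pam_start: int | None = None
    cut_pos: int | None = None
    cut_residue: int | None = None
    category: str = "test"
    gene: str = ""

    def __post_init__(self) -> None:
        if len(self.spacer) != 20:
            raise ValueError(f"spacer must be 20 nt, got {len(self.spacer)}")
        if self.category not in ("test", "neg_ctrl", "pos_ctrl"):
            raise ValueError(f"unknown category {self.category!r}")
        if self.strand not in (None, "+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")


@dataclass
class SgRNALibrary:
    """A guide library over one CDS; the TSV form is the pipeline interchange."""

    guides: list[SgRNA]
    cds_ref: str
    cds_length: int
    collapsed_duplicates: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = [g.guide_id for g in self.guides]
        if len(set(ids)) != len(ids):
            raise ValueError("guide_ids not unique within library")

    @property
    def test_guides(self) -> list[SgRNA]:
        return [g for g in self.guides if g.category == "test"]

    @property
    def targeting_density(self) -> float:
        """bp of CDS per test guide."""
        n = len(self.test_guides)
        if n == 0:
            raise ValueError("library has no test guides")
        return self.cds_length / n

    def category_counts(self) -> dict[str, int]:
        out = {"test": 0, "neg_ctrl": 0, "pos_ctrl": 0}
        for g in self.guides:
            out[g.category] += 1
        return out

    def spacer_index(self) -> dict[str, str]:
        """spacer → guide_id; spacers must be unique (post-collapse they are)."""
        idx: dict[str, str] = {}
        for g in self.guides:
            if g.spacer in idx:
                raise ValueError(f"duplicate spacer {g.spacer} in library")
            idx[g.spacer] = g.guide_id
        return idx

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "guide_id": g.guide_id,
                "spacer": g.spacer,
                "strand": g.strand or "",
                "pam_start": g.pam_start,
                "cut_pos": g.cut_pos,
                "cut_residue": g.cut_residue,
                "category": g.category,
                "gene": g.gene,
            }
            for g in self.guides
        ]
        df = pd.DataFrame(rows, columns=LIBRARY_COLUMNS)
        for col in ("pam_start", "cut_pos", "cut_residue"):
            df[col] = df[col].astype("Int64")  # keep ints despite control NAs
        return df

    def to_tsv(self, path: str | Path) -> None:
        df = self.to_frame()
        df.to_csv(path, sep="\t", index=False, na_rep="")

    @classmethod
    def from_tsv(cls, path: str | Path, cds_length: int | None = None) -> "SgRNALibrary":
        guides: list[SgRNA] = []
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh, delimiter="\t"):
                guides.append(
                    SgRNA(
                        guide_id=row["guide_id"],
                        spacer=row["spacer"],
                        strand=row["strand"] or None,
                        pam_start=int(row["pam_start"]) if row["pam_start"] else None,
                        cut_pos=int(row["cut_pos"]) if row["cut_pos"] else None,
                        cut_residue=int(row["cut_residue"]) if row["cut_residue"] else None,
                        category=row["category"],
                        gene=row.get("gene", ""),
                    )
                )
        cds_ref = guides[0].gene if guides else ""
        if cds_length is None:
            # recoverable from the deepest cut codon only approximately; require
            # explicit length when density matters
            cds_length = max((g.cut_residue or 0) for g in guides) * 3
        return cls(guides=guides, cds_ref=cds_ref, cds_length=cds_length)


def pam_scan(cds: CodingSequence) -> list[tuple[str, int]]:
    """All SpCas9 PAM sites on both strands of the CDS.

    Returns ``(strand, pam_start)`` pairs: ``+`` hits are NGG occurrences on
    the coding strand (pam_start = coordinate of the N); ``-`` hits are NGG
    on the opposite strand, i.e. CCN on the coding strand (pam_start =
    coordinate of the first C). Overlapping PAMs are all reported. Sorted by
    coordinate, ``+`` before ``-`` at ties.
    """
    seq = cds.sequence
    hits: list[tuple[str, int]] = []
    for i in range(len(seq) - 2):  # 0-based start of a trinucleotide
        tri = seq[i : i + 3]
        if tri[1:] == "GG":
            hits.append(("+", i + 1))
        if tri[:2] == "CC":
            hits.append(("-", i + 1))
    hits.sort(key=lambda h: (h[1], h[0] == "-"))
    return hits


def _revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def build_tiling_library(
    cds: CodingSequence,
    gene: str | None = None,
    edge: str = "drop",
    flank5: str = "",
    flank3: str = "",
) -> SgRNALibrary:
    """One test guide per PAM site, tiling the whole CDS.

    ``edge='drop'`` discards PAM sites whose 20-nt protospacer would extend
    beyond the CDS; ``edge='context'`` extends into the supplied genomic
    flanks instead. Guides whose cut falls outside the CDS are always
    dropped (they do not disrupt a codon). Duplicate spacers are collapsed
    to the first occurrence and tallied in ``collapsed_duplicates``.
    """
    if len(cds) < 23:
        raise ValueError("CDS shorter than 23 nt cannot host a full protospacer+PAM")
    if edge not in ("drop", "context"):
        raise ValueError(f"edge policy must be 'drop' or 'context', got {edge!r}")
    gene = gene if gene is not None else cds.id
    L = len(cds)
    extended = flank5.upper() + cds.sequence + flank3.upper() if edge == "context" else cds.sequence
    offset = len(flank5) if edge == "context" else 0  # extended[(p-1)+offset] == coding pos p

    guides: list[SgRNA] = []
    seen: dict[str, str] = {}
    collapsed: dict[str, int] = {}
    for strand, pam_start in pam_scan(cds):
        if strand == "+":
            proto_start = pam_start - 20  # 1-based CDS coord of protospacer 5' end
            cut_pos = pam_start - 4
            ext_lo = proto_start - 1 + offset
            if ext_lo < 0 or ext_lo + 20 > len(extended):
                continue
            spacer = extended[ext_lo : ext_lo + 20]
        else:
            proto_start = pam_start + 3  # coding-strand coord of protospacer segment
            cut_pos = pam_start + 5
            ext_lo = proto_start - 1 + offset
            if ext_lo < 0 or ext_lo + 20 > len(extended):
                continue
            spacer = _revcomp(extended[ext_lo : ext_lo + 20])
        if not 1 <= cut_pos <= L:
            continue
        if spacer in seen:
            collapsed[seen[spacer]] = collapsed.get(seen[spacer], 1) + 1
            continue
        gid = f"{gene}_{strand}{pam_start}"
        seen[spacer] = gid
        guides.append(
            SgRNA(
                guide_id=gid,
                spacer=spacer,
                strand=strand,
                pam_start=pam_start,
                cut_pos=cut_pos,
                cut_residue=(cut_pos - 1) // 3 + 1,
                category="test",
                gene=gene,
            )
        )
    if not guides:
        raise ValueError("no designable guides")
    return SgRNALibrary(
        guides=guides, cds_ref=cds.id, cds_length=L, collapsed_duplicates=collapsed
    )


def attach_controls(
    library: SgRNALibrary,
    neg: Sequence[str] | Iterable[str],
    pos: Sequence[str] | Iterable[str],
) -> SgRNALibrary:
    """Append negative/positive control guides (no cut coordinates)."""
    existing = {g.spacer for g in library.guides}
    guides = list(library.guides)
    for category, prefix, spacers in (("neg_ctrl", "neg", neg), ("pos_ctrl", "pos", pos)):
        for k, spacer in enumerate(spacers, start=1):
            spacer = spacer.upper()
            if spacer in existing:
                raise ValueError(f"duplicate spacer across categories: {spacer}")
            existing.add(spacer)
            guides.append(SgRNA(guide_id=f"{prefix}_{k}", spacer=spacer, category=category))
    return replace(library, guides=guides)
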