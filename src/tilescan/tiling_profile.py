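"""Per-residue essentiality from guide scan scores.

Normalized scan scores of kept test guides, located at their cut
coordinates along the CDS, are interpolated by Nadaraya–Watson Gaussian
kernel regression evaluated at every CDS nucleotide, then averaged over
each trinucleotide codon to give one score per peptide position. The
resulting profile supports depleted-region calling, top-residue lookup,
and export to 3D structure annotations (UCSF Chimera "define attribute"
files, or direct B-factor replacement in a coordinate file).
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from pathlib import Path

import gemmi
import numpy as np
import pandas as pd

from tilescan.library_design import SgRNALibrary
from tilescan.screen_stats import ScanScores


@dataclass
class SmoothingConfig:
    """Gaussian kernel bandwidth (sd, in CDS nucleotides) and the minimum
    total kernel mass below which a position is reported as NA.

    The 10-nt default (≈3.3 codons) smooths over the ~7 bp inter-guide
    spacing of a saturating tiling library while preserving features on
    the ~10-residue scale of short motifs such as Walker A.
    """

    bandwidth_nt: float = 10.0
    min_weight: float = 1e-3

    def __post_init__(self) -> None:
        if self.bandwidth_nt <= 0:
            raise ValueError("bandwidth must be > 0")
        if self.min_weight < 0:
            raise ValueError("min_weight must be >= 0")


@dataclass
class ResidueProfile:
    """Smoothed per-residue score (NaN = not covered) and, per residue, the
    number of kept test guides contributing non-negligible kernel weight."""

    scores: np.ndarray
    n_supporting_guides: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        self.n_supporting_guides = np.asarray(self.n_supporting_guides, dtype=np.int64)
        if self.scores.shape != self.n_supporting_guides.shape:
            raise ValueError("scores and support arrays differ in length")

    @property
    def n_residues(self) -> int:
        return self.scores.size

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(
            {
                "residue": np.arange(1, self.n_residues + 1),
                "score": self.scores,
                "n_supporting_guides": self.n_supporting_guides,
            }
        ).to_csv(path, sep="\t", index=False, na_rep="NA")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ResidueProfile":
        df = pd.read_csv(path, sep="\t", na_values="NA").sort_values("residue")
        return cls(df["score"].to_numpy(), df["n_supporting_guides"].to_numpy())


@dataclass(frozen=True)
class DepletedRegion:
    """Maximal run of consecutive residues at or below a score threshold."""

    start_residue: int
    end_residue: int
    min_score: float
    argmin_residue: int


def kernel_smooth(
    cut_pos: np.ndarray,
    scores: np.ndarray,
    n_nucleotides: int,
    config: SmoothingConfig | None = None,
) -> np.ndarray:
    """Nadaraya–Watson estimate over guide cut positions at every CDS
    nucleotide: ŝ(x) = Σ K((x−c_i)/h)·S_i / Σ K((x−c_i)/h), K the standard
    Gaussian density. Positions with total kernel mass below
    ``config.min_weight`` are NaN.
    """
    config = config or SmoothingConfig()
    cut_pos = np.asarray(cut_pos, dtype=float)
    scores = np.asarray(scores, dtype=float)
    if cut_pos.size == 0:
        raise ValueError("no kept test guides to smooth")
    x = np.arange(1, n_nucleotides + 1, dtype=float)
    z = (x[:, None] - cut_pos[None, :]) / config.bandwidth_nt
    k = np.exp(-0.5 * z**2) / math.sqrt(2 * math.pi)
    mass = k.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        curve = (k @ scores) / mass
    curve[mass < config.min_weight] = np.nan
    return curve


def _guide_support(
    cut_pos: np.ndarray, n_nucleotides: int, config: SmoothingConfig
) -> np.ndarray:
    """Per-nucleotide count of guides whose individual kernel weight
    exceeds min_weight."""
    x = np.arange(1, n_nucleotides + 1, dtype=float)
    z = (x[:, None] - np.asarray(cut_pos, float)[None, :]) / config.bandwidth_nt
    k = np.exp(-0.5 * z**2) / math.sqrt(2 * math.pi)
    return (k > config.min_weight).sum(axis=1)


def codon_average(curve: np.ndarray) -> np.ndarray:
    """Mean of each trinucleotide codon's values → one score per residue;
    NaN only when all three nucleotides are NaN."""
    curve = np.asarray(curve, dtype=float)
    if curve.size % 3 != 0:
        raise ValueError(f"curve length {curve.size} not divisible by 3")
    tri = curve.reshape(-1, 3)
    ok = ~np.isnan(tri)
    n = ok.sum(axis=1)
    total = np.where(ok, tri, 0.0).sum(axis=1)
    return np.where(n > 0, total / np.maximum(n, 1), np.nan)


def residue_profile(
    scan: ScanScores, library: SgRNALibrary, config: SmoothingConfig | None = None
) -> ResidueProfile:
    """Kept test guides → smoothed nucleotide curve → per-residue profile."""
    config = config or SmoothingConfig()
    kept = scan.kept_test()
    cut_pos = kept["cut_pos"].to_numpy(dtype=float)
    scores = kept["score"].to_numpy(dtype=float)
    n_nt = library.cds_length
    curve = kernel_smooth(cut_pos, scores, n_nt, config)
    support = _guide_support(cut_pos, n_nt, config).reshape(-1, 3).max(axis=1)
    return ResidueProfile(scores=codon_average(curve), n_supporting_guides=support)


def top_depleted_residue(profile: ResidueProfile) -> int:
    """1-based argmin of the smoothed score; ties → smallest index."""
    if np.isnan(profile.scores).all():
        raise ValueError("all-NA profile")
    return int(np.nanargmin(profile.scores)) + 1


def call_depleted_regions(profile: ResidueProfile, threshold: float) -> list[DepletedRegion]:
    """Maximal runs of consecutive residues with score ≤ threshold; NA
    residues break runs."""
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    below = np.where(np.isnan(profile.scores), False, profile.scores <= threshold)
    regions: list[DepletedRegion] = []
    start = None
    for i, flag in enumerate(np.append(below, False)):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            seg = profile.scores[start:i]
            j = int(np.argmin(seg))
            regions.append(
                DepletedRegion(
                    start_residue=start + 1,
                    end_residue=i,
                    min_score=float(seg[j]),
                    argmin_residue=start + j + 1,
                )
            )
            start = None
    return regions


def regions_to_tsv(regions: list[DepletedRegion], path: str | Path) -> None:
    pd.DataFrame([vars(r) for r in regions]).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Structure annotation

_ATTR_LINE = re.compile(r"^\t:(\d+)(?:\.(\S+))?\t(-?\d+\.\d+)$")


def export_chimera_attribute(
    profile: ResidueProfile,
    attribute_name: str = "crisprScan",
    chains: list[str] | None = None,
    path: str | Path | None = None,
) -> str:
    """UCSF Chimera "define attribute" file for render-by-attribute coloring.

    Header: ``attribute``, ``match mode: 1-to-1``, ``recipient: residues``;
    then one TAB-prefixed assignment line per non-NA residue per chain,
    values at 4 decimals. Without chains the selectors are chain-less.
    """
    if profile.n_residues == 0:
        raise ValueError("empty profile")
    if not re.fullmatch(r"[a-z][A-Za-z0-9]*", attribute_name):
        raise ValueError("attribute name must be alphanumeric and start lowercase")
    lines = [
        f"attribute: {attribute_name}",
        "match mode: 1-to-1",
        "recipient: residues",
    ]
    selectors = chains if chains else [None]
    for r in range(1, profile.n_residues + 1):
        v = profile.scores[r - 1]
        if np.isnan(v):
            continue
        for chain in selectors:
            sel = f":{r}.{chain}" if chain else f":{r}"
            lines.append(f"\t{sel}\t{v:.4f}")
    text = "\n".join(lines) + "\n"
    if path is not None:
        Path(path).write_text(text)
    return text


def read_chimera_attribute(source: str | Path) -> tuple[str, dict[tuple[int, str | None], float]]:
    """Parse the attribute dialect written above → (name, {(residue, chain): value})."""
    text = Path(source).read_text() if isinstance(source, Path) else source
    if isinstance(source, str) and "\n" not in source and Path(source).exists():
        text = Path(source).read_text()
    name = None
    values: dict[tuple[int, str | None], float] = {}
    for line in text.splitlines():
        if line.startswith("attribute:"):
            name = line.split(":", 1)[1].strip()
            continue
        m = _ATTR_LINE.match(line)
        if m:
            values[(int(m.group(1)), m.group(2))] = float(m.group(3))
    if name is None:
        raise ValueError("not a Chimera attribute file (no 'attribute:' header)")
    return name, values


def annotate_structure_bfactor(
    profile: ResidueProfile,
    structure_path: str | Path,
    target_chains: list[str],
    out_path: str | Path,
    offset: int = 0,
    scale: float = 100.0,
    na_sentinel: float = 0.0,
) -> int:
    """Write a copy of a PDB/mmCIF structure with target-chain B-factors
    replaced by the smoothed score × ``scale`` (clamped to ±999.99, the PDB
    column limit). Structure residue number = profile residue + ``offset``.
    NA residues get the sentinel; non-target chains are untouched. Returns
    the number of residues annotated.
    """
    st = gemmi.read_structure(str(structure_path))
    n_annotated = 0
    for model in st:
        for chain in model:
            if chain.name not in target_chains:
                continue
            for residue in chain:
                num = residue.seqid.num
                r = num - offset
                if not 1 <= r <= profile.n_residues:
                    continue
                v = profile.scores[r - 1]
                b = na_sentinel if np.isnan(v) else float(np.clip(v * scale, -999.99, 999.99))
                for atom in residue:
                    atom.b_iso = b
                n_annotated += 1
    if n_annotated == 0:
        raise ValueError("no residues of the target chains matched the profile")
    out_path = str(out_path)
    if out_path.endswith(".cif") or out_path.endswith(".mmcif"):
        st.make_mmcif_document().write_file(out_path)
    else:
        st.write_pdb(out_path)
    return n_annotated
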