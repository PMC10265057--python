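"""Screen scoring: frequencies, filters, log10 fold changes, control-anchored
normalization, and gene-level quartile impact scores.

The scan score of a guide is the mean (over replicates) log10 fold change of
its pseudocounted relative frequency between day 0 and day 16, affinely
rescaled so that the median of kept negative-control guides sits at 0.0 and
the median of kept positive-control guides at −1.0. Guides whose day-0
frequency falls below 5% of the library-average frequency are excluded
before anchoring.

The gene-level CRISPR impact score is the first quartile (25th percentile,
linear interpolation between order statistics) of a gene's per-guide raw
log10 fold changes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from tilescan.library_design import SgRNALibrary
from tilescan.quantify import CountTable, SampleMeta


@dataclass
class FrequencyTable:
    """Pseudocounted relative frequencies per (guide, sample); each sample
    column sums to 1."""

    guide_ids: list[str]
    samples: list[SampleMeta]
    freqs: np.ndarray  # (n_guides, n_samples) float
    pseudocount: float

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    def timepoint_columns(self, timepoint: str) -> list[int]:
        return [j for j, s in enumerate(self.samples) if s.timepoint == timepoint]


@dataclass
class ScanScores:
    """Per-guide raw and normalized scan scores with the control anchors.

    ``frame`` columns: guide_id, category, gene, cut_pos, cut_residue,
    raw_log10fc, kept, score (NaN for excluded guides). ``m_neg``/``m_pos``
    are the medians of kept negative / positive control raw scores.
    """

    frame: pd.DataFrame
    m_neg: float
    m_pos: float

    def kept_test(self) -> pd.DataFrame:
        f = self.frame
        return f[(f["category"] == "test") & f["kept"]]

    def to_tsv(self, path: str | Path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)

    def anchors_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump({"m_neg": self.m_neg, "m_pos": self.m_pos}, fh, indent=1)

    @classmethod
    def from_tsv(cls, path: str | Path, anchors: str | Path) -> "ScanScores":
        frame = pd.read_csv(path, sep="\t")
        with open(anchors) as fh:
            a = json.load(fh)
        return cls(frame=frame, m_neg=a["m_neg"], m_pos=a["m_pos"])


def frequencies(counts: CountTable, pseudocount: float = 0.5) -> FrequencyTable:
    """Relative frequency f = (count + pc) / Σ(count + pc), per sample."""
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    x = counts.counts.astype(float) + pseudocount
    totals = x.sum(axis=0)
    if (totals <= 0).any():
        bad = [counts.sample_ids[j] for j in np.flatnonzero(totals <= 0)]
        raise ValueError(f"sample(s) with zero total mass: {bad}")
    return FrequencyTable(
        guide_ids=list(counts.guide_ids),
        samples=list(counts.samples),
        freqs=x / totals,
        pseudocount=pseudocount,
    )


def filter_underrepresented(
    freqs: FrequencyTable, threshold_frac: float = 0.05, timepoint: str = "day0"
) -> np.ndarray:
    """Kept flags: a guide is excluded iff its mean frequency at the given
    timepoint is below ``threshold_frac`` × the guide-average frequency."""
    cols = freqs.timepoint_columns(timepoint)
    if not cols:
        raise ValueError(f"no {timepoint} samples present")
    mean_f = freqs.freqs[:, cols].mean(axis=1)
    return mean_f >= threshold_frac * mean_f.mean()


def log10_fold_change(freqs: FrequencyTable) -> np.ndarray:
    """Per-guide mean over replicates of log10(f_day16 / f_day0).

    Replicates are paired by replicate index; each replicate contributes
    equally regardless of sequencing depth.
    """
    by_rep: dict[int, dict[str, int]] = {}
    for j, s in enumerate(freqs.samples):
        by_rep.setdefault(s.replicate, {})[s.timepoint] = j
    pairs = [(v["day0"], v["day16"]) for v in by_rep.values() if "day0" in v and "day16" in v]
    if not pairs:
        raise ValueError("need at least one replicate with both day0 and day16")
    per_rep = np.stack(
        [np.log10(freqs.freqs[:, j16] / freqs.freqs[:, j0]) for j0, j16 in pairs], axis=1
    )
    return per_rep.mean(axis=1)


def normalize_scan_scores(
    raw: np.ndarray, kept: np.ndarray, categories: np.ndarray
) -> tuple[np.ndarray, float, float]:
    """Two-point control anchoring: the unique affine map sending the kept
    negative-control median to 0.0 and the kept positive-control median to
    −1.0; S = (s − m_neg) / (m_neg − m_pos). Excluded guides get NaN."""
    raw = np.asarray(raw, dtype=float)
    kept = np.asarray(kept, dtype=bool)
    categories = np.asarray(categories)
    neg = raw[kept & (categories == "neg_ctrl")]
    pos = raw[kept & (categories == "pos_ctrl")]
    if neg.size == 0 or pos.size == 0:
        raise ValueError("need >=1 kept negative and >=1 kept positive control")
    m_neg = float(np.median(neg))
    m_pos = float(np.median(pos))
    if m_neg == m_pos:
        raise ValueError("degenerate anchors: negative and positive medians equal")
    score = (raw - m_neg) / (m_neg - m_pos)
    score = np.where(kept, score, np.nan)
    return score, m_neg, m_pos


def score_screen(
    counts: CountTable,
    library: SgRNALibrary,
    pseudocount: float = 0.5,
    threshold_frac: float = 0.05,
    filter_timepoint: str = "day0",
) -> ScanScores:
    """Full per-guide scoring: frequencies → under-representation filter →
    raw log10FC → control-anchored normalization."""
    meta = library.to_frame().set_index("guide_id")
    meta = meta.loc[counts.guide_ids]
    freqs = frequencies(counts, pseudocount=pseudocount)
    kept = filter_underrepresented(freqs, threshold_frac=threshold_frac, timepoint=filter_timepoint)
    raw = log10_fold_change(freqs)
    score, m_neg, m_pos = normalize_scan_scores(raw, kept, meta["category"].to_numpy())
    frame = pd.DataFrame(
        {
            "guide_id": counts.guide_ids,
            "category": meta["category"].to_numpy(),
            "gene": meta["gene"].to_numpy(),
            "cut_pos": meta["cut_pos"].to_numpy(),
            "cut_residue": meta["cut_residue"].to_numpy(),
            "raw_log10fc": raw,
            "kept": kept,
            "score": score,
        }
    )
    return ScanScores(frame=frame, m_neg=m_neg, m_pos=m_pos)


def first_quartile(values: np.ndarray) -> float:
    """25th percentile with linear interpolation between order statistics
    (h = 0.25·(n−1), zero-based)."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("empty group")
    return float(np.percentile(values, 25, method="linear"))


def gene_impact_score(scores: pd.DataFrame, min_guides: int = 4) -> pd.DataFrame:
    """Gene-level impact: Q1 of each gene's per-guide raw log10 fold changes.

    ``scores`` needs columns ``gene`` and ``raw_log10fc``. Genes with fewer
    than ``min_guides`` guides are rejected; a warning threshold of 25 (the
    panel design size) is advisory only.
    """
    out = []
    for gene, grp in scores.groupby("gene", sort=True):
        vals = grp["raw_log10fc"].to_numpy()
        if vals.size < min_guides:
            raise ValueError(f"gene {gene!r} has {vals.size} guides (<{min_guides})")
        out.append({"gene": gene, "n_guides": int(vals.size), "impact": first_quartile(vals)})
    if not out:
        raise ValueError("no gene groups")
    return pd.DataFrame(out)
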