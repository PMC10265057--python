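"""ChIP-seq TSS-window target classification.

A gene is a bound target when its ChIP pileup signal, summed over the
transcription start site ± 1 kb, exceeds tenfold the matched input signal
(strict inequality). A bound target is additionally "regulated" when its
ChIP window signal drops by more than 40% between two conditions.

User-facing coordinates are 1-based closed; bedGraph files on disk are
0-based half-open. The conversion lives in :func:`tss_window_signal` only.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class TSSRecord:
    gene: str
    chrom: str
    tss: int  # 1-based
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.tss < 1:
            raise ValueError("tss must be >= 1")
        if self.strand not in ("+", "-"):
            raise ValueError("strand must be '+' or '-'")


@dataclass
class SignalTrack:
    """Binned nonnegative signal, bedGraph semantics: per chromosome, sorted
    non-overlapping 0-based half-open intervals with per-base values."""

    data: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]

    def __post_init__(self) -> None:
        clean = {}
        for chrom, (starts, ends, values) in self.data.items():
            starts = np.asarray(starts, dtype=np.int64)
            ends = np.asarray(ends, dtype=np.int64)
            values = np.asarray(values, dtype=float)
            order = np.argsort(starts)
            starts, ends, values = starts[order], ends[order], values[order]
            if (ends <= starts).any():
                raise ValueError(f"empty/negative interval on {chrom}")
            if (starts[1:] < ends[:-1]).any():
                raise ValueError(f"overlapping intervals on {chrom}")
            if (values < 0).any():
                raise ValueError(f"negative signal on {chrom}")
            clean[chrom] = (starts, ends, values)
        self.data = clean

    @classmethod
    def from_bedgraph(cls, path: str | Path) -> "SignalTrack":
        df = pd.read_csv(
            path, sep="\t", comment="#", header=None,
            names=["chrom", "start", "end", "value"],
            dtype={"chrom": str},
        )
        data = {
            str(chrom): (g["start"].to_numpy(), g["end"].to_numpy(), g["value"].to_numpy())
            for chrom, g in df.groupby("chrom", sort=True)
        }
        return cls(data=data)

    def to_bedgraph(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for chrom in sorted(self.data):
                starts, ends, values = self.data[chrom]
                for s, e, v in zip(starts, ends, values):
                    fh.write(f"{chrom}\t{s}\t{e}\t{v:.6g}\n")


def tss_window_signal(track: SignalTrack, tss: TSSRecord, halfwidth: int = 1000) -> float:
    """Overlap-weighted signal sum over [tss − halfwidth, tss + halfwidth]
    (1-based closed; strand-independent). Windows running off the
    chromosome start are clipped."""
    if tss.chrom not in track.data:
        raise KeyError(f"unknown chromosome {tss.chrom!r}")
    starts, ends, values = track.data[tss.chrom]
    # user window 1-based closed -> 0-based half-open
    lo = max(tss.tss - halfwidth - 1, 0)
    hi = tss.tss + halfwidth
    overlap = np.minimum(ends, hi) - np.maximum(starts, lo)
    overlap = np.clip(overlap, 0, None)
    return float((values * overlap).sum())


def classify_targets(
    chip: SignalTrack,
    input_track: SignalTrack,
    tss_set: list[TSSRecord],
    fold_threshold: float = 10.0,
    input_floor: float = 1.0,
    halfwidth: int = 1000,
) -> pd.DataFrame:
    """Per-gene enrichment E = chip / max(input, floor) over the TSS window;
    a gene is a target iff E > fold_threshold (strict)."""
    if not tss_set:
        raise ValueError("empty TSS set")
    if input_floor <= 0:
        raise ValueError("input_floor must be > 0")
    rows = []
    for rec in tss_set:
        chip_sum = tss_window_signal(chip, rec, halfwidth)
        input_sum = tss_window_signal(input_track, rec, halfwidth)
        enrichment = chip_sum / max(input_sum, input_floor)
        rows.append(
            {
                "gene": rec.gene,
                "chip_signal": chip_sum,
                "input_signal": input_sum,
                "enrichment": enrichment,
                "is_target": enrichment > fold_threshold,
            }
        )
    return pd.DataFrame(rows)


def reduction_filter(
    calls_a: pd.DataFrame,
    calls_b: pd.DataFrame,
    reduction_threshold: float = 0.40,
    input_floor: float = 1.0,
) -> pd.DataFrame:
    """Between-condition regulated-target calls.

    ρ = 1 − chipB/chipA on the ChIP window signal (floored denominator);
    regulated iff the gene is a condition-A target AND ρ > threshold
    (strict). Both calls must cover the same gene universe.
    """
    a = calls_a.set_index("gene")
    b = calls_b.set_index("gene")
    if set(a.index) != set(b.index):
        missing = set(a.index) ^ set(b.index)
        raise ValueError(f"gene universe mismatch between conditions: {sorted(missing)[:5]}")
    b = b.loc[a.index]
    rho = 1.0 - b["chip_signal"].to_numpy() / np.maximum(a["chip_signal"].to_numpy(), input_floor)
    out = a.reset_index()[["gene", "chip_signal", "input_signal", "enrichment", "is_target"]].copy()
    out.rename(columns={"chip_signal": "chip_signal_a"}, inplace=True)
    out["chip_signal_b"] = b["chip_signal"].to_numpy()
    out["reduction"] = rho
    out["is_regulated"] = out["is_target"].to_numpy() & (rho > reduction_threshold)
    return out


def read_tss_bed(path: str | Path) -> list[TSSRecord]:
    """6-column BED → TSS records: TSS = start+1 for + strand, end for −."""
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None,
        names=["chrom", "start", "end", "name", "score", "strand"],
        dtype={"chrom": str, "name": str},
    )
    recs = []
    for row in df.itertuples(index=False):
        tss = row.start + 1 if row.strand == "+" else row.end
        recs.append(TSSRecord(gene=row.name, chrom=row.chrom, tss=int(tss), strand=row.strand))
    return recs
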