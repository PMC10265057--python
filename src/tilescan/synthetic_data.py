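"""Seeded synthetic screens and ChIP tracks with known ground truth.

The tiling-screen generator emulates the study design every downstream
stage expects: a ~194-guide library tiling a ~1.4 kb CDS plus negative and
positive control guides, three replicates sequenced at day 0 and day 16,
and depletion driven by a planted per-residue essentiality landscape.

Mechanics (fixed contract):

* day-0 library proportions ``p0`` ~ symmetric Dirichlet(10);
* per-guide realized effect ``ē_i = clip(effect(residue_i)·η_i, 0, 1)``
  with multiplicative efficacy noise ``η_i ~ Normal(1, σ)`` truncated at 0;
  negative controls ``ē = 0``, positive controls ``ē = 1``;
* per-doubling fitness ``w_i = 2^(−δ·ē_i)``; after G population doublings
  day-16 proportions ∝ ``p0_i · w_i^G``;
* each timepoint × replicate is an independent Multinomial(depth) draw.

Expected raw log10 fold change of guide i (before renormalization across
the pool) is therefore ``−G·δ·ē_i·log10(2)`` — analytically tractable, which
is why this growth model was chosen.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from tilescan.chip_targets import SignalTrack, TSSRecord
from tilescan.library_design import (
    CodingSequence,
    SgRNALibrary,
    attach_controls,
    build_tiling_library,
)
from tilescan.quantify import CountTable, SampleMeta

_STOPS = {"TAA", "TAG", "TGA"}


@dataclass
class EssentialityProfile:
    """Planted per-residue effect in [0, 1]; 0 neutral, 1 maximal depletion.

    ``effects[r-1]`` is the effect at 1-based residue r; the profile covers
    every residue of the target protein exactly once.
    """

    effects: np.ndarray

    def __post_init__(self) -> None:
        self.effects = np.asarray(self.effects, dtype=float)
        if self.effects.ndim != 1 or self.effects.size == 0:
            raise ValueError("effects must be a non-empty 1-D array")
        if ((self.effects < 0) | (self.effects > 1)).any():
            raise ValueError("effects must lie in [0, 1]")

    @property
    def n_residues(self) -> int:
        return self.effects.size

    def effect_at(self, residue: int) -> float:
        if not 1 <= residue <= self.n_residues:
            raise ValueError(f"residue {residue} outside profile (1..{self.n_residues})")
        return float(self.effects[residue - 1])

    @classmethod
    def neutral(cls, n_residues: int) -> "EssentialityProfile":
        return cls(np.zeros(n_residues))

    @classmethod
    def boxcar(
        cls, n_residues: int, start: int, end: int, effect: float = 1.0
    ) -> "EssentialityProfile":
        """Constant ``effect`` on residues [start, end] (1-based closed)."""
        e = np.zeros(n_residues)
        e[start - 1 : end] = effect
        return cls(e)

    @classmethod
    def exponential_peak(
        cls,
        n_residues: int,
        peak: int = 108,
        decay: float = 12.0,
        window: tuple[int, int] | None = (63, 135),
    ) -> "EssentialityProfile":
        """Unimodal planted peak: effect = exp(−|r−peak|/decay), optionally
        supported only on a closed residue window (0 outside).

        The exponential shape keeps a nonzero, symmetric gradient at the
        apex, so the peak location stays identifiable after kernel
        smoothing — a flat-topped bump would leave the argmin of the
        recovered profile undetermined at the smoother's resolution.
        """
        r = np.arange(1, n_residues + 1)
        e = np.exp(-np.abs(r - peak) / decay)
        if window is not None:
            e[(r < window[0]) | (r > window[1])] = 0.0
        return cls(e)

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"residue": np.arange(1, self.n_residues + 1), "effect": self.effects}
        ).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "EssentialityProfile":
        df = pd.read_csv(path, sep="\t").sort_values("residue")
        if not (df["residue"].to_numpy() == np.arange(1, len(df) + 1)).all():
            raise ValueError("profile must cover residues 1..N exactly once")
        return cls(df["effect"].to_numpy())


@dataclass
class ScreenSimConfig:
    """Study-design knobs for the tiling-screen simulator.

    Defaults follow the emulated design: 3 replicates, day 0 and day 16
    timepoints, G = 12 population doublings over the 16-day culture, and a
    maximal per-doubling depletion δ = 0.4 so fully essential guides drop
    ≈30-fold — the raw range implied by anchoring positive controls at −1.
    """

    n_replicates: int = 3
    depth_day0: int = 1_000_000
    depth_day16: int = 1_000_000
    doublings: float = 12.0
    max_depletion_per_doubling: float = 0.4
    guide_efficacy_sd: float = 0.2
    n_neg_controls: int = 30
    n_pos_controls: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ValueError("need >=1 replicate")
        if self.depth_day0 <= 0 or self.depth_day16 <= 0:
            raise ValueError("sequencing depths must be positive")
        if not 0 < self.max_depletion_per_doubling <= 1:
            raise ValueError("max_depletion_per_doubling must be in (0, 1]")
        if self.guide_efficacy_sd < 0:
            raise ValueError("guide_efficacy_sd must be >= 0")


def synthetic_cds(n_residues: int = 456, seed: int = 0, gc: float = 0.53) -> CodingSequence:
    """Random in-frame CDS: ATG start, TAA stop, no internal stops, base
    composition set by ``gc``.

    At gc ≈ 0.53 a 456-codon CDS carries ≈190–200 NGG protospacers across
    both strands — the ~7 bp/guide tiling density of a saturating design.
    """
    rng = np.random.default_rng(seed)
    p_gc = gc / 2
    p_at = (1 - gc) / 2
    probs = [p_at, p_gc, p_gc, p_at]  # A C G T
    bases = np.array(list("ACGT"))
    codons = ["ATG"]
    while len(codons) < n_residues - 1:
        c = "".join(rng.choice(bases, size=3, p=probs))
        if c not in _STOPS:
            codons.append(c)
    codons.append("TAA")
    return CodingSequence(id=f"synthetic_cds_{n_residues}aa", sequence="".join(codons))


def random_spacers(n: int, rng: np.random.Generator, exclude: set[str] | None = None) -> list[str]:
    """``n`` distinct random 20-mers avoiding ``exclude``."""
    exclude = set(exclude or ())
    bases = np.array(list("ACGT"))
    out: list[str] = []
    while len(out) < n:
        s = "".join(rng.choice(bases, size=20))
        if s not in exclude:
            exclude.add(s)
            out.append(s)
    return out


def synthetic_tiling_library(
    n_residues: int = 456,
    config: ScreenSimConfig | None = None,
    seed: int | None = None,
    gene: str = "synthetic",
) -> tuple[CodingSequence, SgRNALibrary]:
    """A full synthetic screen library: tiling guides over a random CDS plus
    the configured numbers of negative/positive control guides."""
    config = config or ScreenSimConfig()
    seed = config.seed if seed is None else seed
    cds = synthetic_cds(n_residues=n_residues, seed=seed)
    lib = build_tiling_library(cds, gene=gene)
    rng = np.random.default_rng(seed + 1)
    test_spacers = {g.spacer for g in lib.guides}
    neg = random_spacers(config.n_neg_controls, rng, exclude=test_spacers)
    pos = random_spacers(config.n_pos_controls, rng, exclude=test_spacers | set(neg))
    return cds, attach_controls(lib, neg=neg, pos=pos)


def _realized_effects(
    library: SgRNALibrary, profile: EssentialityProfile, config: ScreenSimConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    effects = np.empty(len(library.guides))
    planted = np.array(
        [profile.effect_at(g.cut_residue) if g.category == "test" else 0.0
         for g in library.guides]
    )
    if config.guide_efficacy_sd > 0:
        eta = stats.truncnorm.rvs(
            a=(0.0 - 1.0) / config.guide_efficacy_sd,
            b=np.inf,
            loc=1.0,
            scale=config.guide_efficacy_sd,
            size=len(library.guides),
            random_state=rng,
        )
    else:
        eta = np.ones(len(library.guides))
    effects = np.clip(planted * eta, 0.0, 1.0)
    for i, g in enumerate(library.guides):
        if g.category == "neg_ctrl":
            effects[i] = 0.0
        elif g.category == "pos_ctrl":
            effects[i] = 1.0
    return effects


def simulate_tiling_screen(
    library: SgRNALibrary,
    profile: EssentialityProfile,
    config: ScreenSimConfig,
    return_truth: bool = False,
) -> CountTable | tuple[CountTable, dict]:
    """Simulate a day0/day16 pooled screen; deterministic given the seed.

    With ``return_truth=True`` also returns the pre-sampling ground truth:
    day-0 proportions, realized effects, and day-16 proportions.
    """
    for g in library.test_guides:
        if g.cut_residue is None or not 1 <= g.cut_residue <= profile.n_residues:
            raise ValueError(
                f"guide {g.guide_id} cut residue {g.cut_residue} not covered by profile"
            )
    cats = library.category_counts()
    if cats["neg_ctrl"] < config.n_neg_controls or cats["pos_ctrl"] < config.n_pos_controls:
        raise ValueError("library carries fewer controls than the config requires")

    rng = np.random.default_rng(config.seed)
    n = len(library.guides)
    p0 = rng.dirichlet(np.full(n, 10.0))
    effects = _realized_effects(library, profile, config, rng)
    w = 2.0 ** (-config.max_depletion_per_doubling * effects)
    day16_mass = p0 * w**config.doublings
    p16 = day16_mass / day16_mass.sum()

    samples: list[SampleMeta] = []
    cols: list[np.ndarray] = []
    for timepoint, props, depth in (
        ("day0", p0, config.depth_day0),
        ("day16", p16, config.depth_day16),
    ):
        for r in range(1, config.n_replicates + 1):
            samples.append(SampleMeta(f"{timepoint}_rep{r}", timepoint, r))
            cols.append(rng.multinomial(depth, props))
    counts = CountTable(
        guide_ids=[g.guide_id for g in library.guides],
        samples=samples,
        counts=np.stack(cols, axis=1),
    )
    if return_truth:
        return counts, {"p0": p0, "effects": effects, "p16": p16, "fitness": w}
    return counts


def expected_log10_fold_change(
    effects: np.ndarray,
    config: ScreenSimConfig,
    p0: np.ndarray | None = None,
    renormalize: bool = True,
) -> np.ndarray:
    """Closed-form pre-sampling log10 fold change.

    On the abundance scale (``renormalize=False``) this is
    ``G·log10(w) = −G·δ·ē·log10(2)`` exactly; with renormalization the
    pool-wide day-16 mass ``Z = Σ p0·w^G`` is subtracted, which is what the
    measured frequency ratio converges to at infinite depth.
    """
    effects = np.asarray(effects, dtype=float)
    w = 2.0 ** (-config.max_depletion_per_doubling * effects)
    lfc = config.doublings * np.log10(w)
    if renormalize:
        if p0 is None:
            raise ValueError("renormalized expectation needs day-0 proportions")
        z = float((np.asarray(p0) * w**config.doublings).sum())
        lfc = lfc - np.log10(z)
    return lfc


# ---------------------------------------------------------------------------
# FASTQ emission


def emit_fastq(
    counts: CountTable,
    library: SgRNALibrary,
    read_length: int = 50,
    seed: int = 0,
    out_dir: str | Path | None = None,
) -> dict[str, Path] | dict[str, list[str]]:
    """One read per unit of count: random stuffer + CACCG + spacer + GTTT +
    random stuffer, constant quality.

    With ``out_dir`` set, writes one FASTQ per sample and returns the paths;
    otherwise returns in-memory read sequences per sample. A sample with
    zero total counts yields a valid empty FASTQ.
    """
    cassette_len = 5 + 20 + 4
    if read_length < cassette_len:
        raise ValueError(f"read_length must be >= {cassette_len}")
    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    spacers = {g.guide_id: g.spacer for g in library.guides}
    out: dict = {}
    for j, sample in enumerate(counts.samples):
        reads: list[str] = []
        for i, gid in enumerate(counts.guide_ids):
            cassette = "CACCG" + spacers[gid] + "GTTT"
            for _ in range(int(counts.counts[i, j])):
                pad = read_length - cassette_len
                off = int(rng.integers(0, pad + 1)) if pad else 0
                left = "".join(rng.choice(bases, size=off))
                right = "".join(rng.choice(bases, size=pad - off))
                reads.append(left + cassette + right)
        if out_dir is None:
            out[sample.sample_id] = reads
        else:
            path = Path(out_dir) / f"{sample.sample_id}.fastq"
            with open(path, "w") as fh:
                for k, seq in enumerate(reads):
                    fh.write(f"@{sample.sample_id}:{k}\n{seq}\n+\n{'I' * len(seq)}\n")
            out[sample.sample_id] = path
    return out


# ---------------------------------------------------------------------------
# Toy ChIP tracks


def simulate_chip_tracks(
    genes: list[TSSRecord],
    planted: dict[str, tuple[float, float]],
    noise_sd: float = 0.0,
    seed: int = 0,
    bin_size: int = 50,
    baseline: float = 1.0,
    halfwidth: int = 1000,
) -> tuple[dict[str, SignalTrack], pd.DataFrame]:
    """Two-condition ChIP/input track quartet with planted window signals.

    The input tracks sit at a constant per-base baseline; each gene's TSS ±
    ``halfwidth`` window is scaled by the planted enrichment in condition A
    and by enrichment × (1 − reduction) in condition B. Interval breaks are
    forced at window edges so noiseless tracks recover the planted values
    exactly. Returns the tracks and a truth table (enrichment, reduction).
    """
    for g in genes:
        if g.gene not in planted:
            raise ValueError(f"no planted values for gene {g.gene}")
        enr, red = planted[g.gene]
        if enr <= 0:
            raise ValueError(f"enrichment must be > 0 (gene {g.gene})")
        if red < 0:
            raise ValueError(f"negative reduction (gene {g.gene})")
    by_chrom: dict[str, list[TSSRecord]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    for chrom, recs in by_chrom.items():
        recs.sort(key=lambda r: r.tss)
        for a, b in zip(recs, recs[1:]):
            if b.tss - halfwidth <= a.tss + halfwidth:
                raise ValueError(f"overlapping TSS windows on {chrom}: {a.gene}/{b.gene}")

    rng = np.random.default_rng(seed)
    tracks: dict[str, dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]] = {
        k: {} for k in ("chip_A", "input_A", "chip_B", "input_B")
    }
    for chrom, recs in by_chrom.items():
        chrom_len = max(r.tss for r in recs) + halfwidth + bin_size
        # breakpoints: regular grid plus exact window edges (0-based half-open)
        edges = set(range(0, chrom_len + bin_size, bin_size))
        windows = []
        for r in recs:
            lo = max(r.tss - halfwidth - 1, 0)
            hi = min(r.tss + halfwidth, chrom_len)
            windows.append((lo, hi, r.gene))
            edges.update((lo, hi))
        bounds = np.array(sorted(e for e in edges if e <= chrom_len))
        starts, ends = bounds[:-1], bounds[1:]
        mids = (starts + ends) / 2
        scale_a = np.ones(starts.size)
        scale_b = np.ones(starts.size)
        for lo, hi, gene in windows:
            enr, red = planted[gene]
            inside = (mids > lo) & (mids < hi)
            scale_a[inside] = enr
            scale_b[inside] = enr * (1.0 - red)
        for name, values in (
            ("chip_A", baseline * scale_a),
            ("input_A", np.full(starts.size, baseline)),
            ("chip_B", baseline * scale_b),
            ("input_B", np.full(starts.size, baseline)),
        ):
            if noise_sd > 0:
                values = values + rng.normal(0.0, noise_sd, size=values.size)
            tracks[name][chrom] = (starts, ends, np.maximum(values, 0.0))

    truth = pd.DataFrame(
        {
            "gene": [g.gene for g in genes],
            "enrichment": [planted[g.gene][0] for g in genes],
            "reduction": [planted[g.gene][1] for g in genes],
        }
    )
    return {k: SignalTrack(data=v) for k, v in tracks.items()}, truth
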