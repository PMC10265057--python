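# Methods

## Scan-score model

A pooled tiling screen measures, for every guide *i*, counts at day 0 and
day 16 in *R* replicates. Counts are converted to pseudocounted relative
frequencies `f = (c + 0.5) / Σ(c + 0.5)` per sample; the pseudocount
(default 0.5) keeps zero-count day-16 guides finite and is negligible at
typical per-guide depths (10³–10⁴ reads). Guides whose mean day-0
frequency is below 5% of the library-average frequency are excluded
before any scoring ("under-represented"); the filter is evaluated on
day 0 because that is the guide's representation in the library as
delivered, but the timepoint is configurable.

The raw score is `s_i = (1/R) Σ_r log10(f_i,day16,r / f_i,day0,r)` —
replicates are averaged on the log scale so each contributes equally
regardless of sequencing depth (pooling counts would weight deep
replicates more; both conventions are defensible, this one is the
package's default and only behavior).

Normalization is a two-point affine anchoring: with `m_neg`, `m_pos` the
medians of the kept negative/positive control raw scores,
`S_i = (s_i − m_neg) / (m_neg − m_pos)` is the unique affine map with
`median(S_neg) = 0` and `median(S_pos) = −1`. These two medians are
therefore exact (to floating rounding) on every dataset — that is the
point of the construction, and the acceptance script demonstrates it
rather than estimating it. The map is equivariant under any affine
transformation of the raw scores, so global multiplicative or additive
distortions of the fold changes cancel.

Gene-panel screens summarize each gene by the **impact score**: the 25th
percentile of its guides' raw log10 fold changes, with linear
interpolation between order statistics (`h = 0.25(n−1)`, zero-based —
the default convention of the major statistical environments; quartile
definitions differ across software, hence it is pinned here). The first
quartile is deliberately pessimistic: a gene is called essential when its
best quarter of guides deplete, which is robust to inactive guides.

## Residue profiling

Kept test guides carry a cut coordinate: the blunt SpCas9 cut between
protospacer positions 17 and 18 (3 bp 5′ of the PAM), expressed as the
coding-strand base 5′ of the cut; the cut residue is the codon containing
that base. Normalized scores are interpolated along the CDS by
Nadaraya–Watson regression with a Gaussian kernel in **nucleotide**
coordinates, evaluated at every CDS position, then averaged over each
codon's three nucleotides to give one score per peptide position.

Smoothing operates on the normalized scores (the anchored scale on which
the control lines sit at 0 and −1), not raw fold changes. Bandwidth
default is **h = 10 nt** (≈3.3 codons sd): wide enough to pool the ~7 bp
inter-guide spacing of a saturating library, narrow enough to resolve
~10-residue motifs (e.g. a Walker A box). Positions where the total
kernel mass falls below `min_weight = 1e-3` are reported NA rather than
extrapolated into guide deserts; NA residues break depleted-region runs.
A codon with at least one covered nucleotide averages its covered
nucleotides only.

Depleted regions are maximal runs of residues with smoothed score at or
below a user threshold; the top depleted residue is the profile argmin
(ties to the smallest index). Structure export offers two routes: a UCSF
Chimera "define attribute" file (`attribute/match mode/recipient` header,
TAB-prefixed `:resnum.chain` selectors, `%.4f` values, NA residues
omitted) and direct B-factor replacement via gemmi (score × 100, clamped
to ±999.99, NA → 0). Note the PDB B-factor field is 6 characters wide, so
magnitudes ≥100 lose one decimal of precision; use mmCIF output when that
matters. An offset parameter reconciles author residue numbering with
1-based CDS residues.

## Library design conventions

PAM enumeration reads NGG on the coding strand and CCN footprints for the
opposite strand, keeping overlapping sites; coordinates are 1-based
closed. Guides whose 20-nt protospacer would run past the CDS are dropped
by default (`edge=context` extends into supplied genomic flanks instead);
guides whose *cut* falls outside the CDS are always dropped, as they
disrupt no codon. Duplicate spacer sequences are collapsed to the first
site and tallied. Targeting density is defined as CDS length / number of
test guides, exactly. The package works in spliced CDS coordinates;
guides spanning genomic exon junctions are a documented limitation.

## ChIP target classification

"Signal" is the overlap-weighted **sum** of the normalized pileup over
the TSS ± 1 kb window (2001 bp, 1-based closed; bedGraph's 0-based
half-open intervals are converted in one place). Sum and mean are
equivalent up to the fixed window width. Enrichment is
`E = chip / max(input, floor)` with an input floor of 1 read-equivalent
per window to guard empty input windows; a gene is a target iff
`E > 10` (strict, "more than tenfold"). The between-condition reduction
is computed on the ChIP window signal itself, `ρ = 1 − chipB/chipA`
(floored denominator), and a target is regulated iff `ρ > 0.40`
(strict). Regulated calls are by construction a subset of target calls.

## Synthetic-data generator

The generator emulates the study design end to end: a saturating tiling
library over a 456-codon (1368-nt) random CDS, 30 negative + 30 positive
controls, 3 replicates at day 0 and day 16, and 10⁶ reads per sample.
The random CDS is codon-sampled (ATG start, TAA stop, no internal stops)
with G/C base fractions of 0.265 each, which by the binomial expectation
`L·(p_G² + p_C²)` yields ≈190–210 two-strand NGG guides over 1.4 kb —
the ~7 bp/guide density of a saturating design.

Screen mechanics: day-0 proportions from a symmetric Dirichlet
(concentration 10, i.e. mild library imbalance); per-guide realized
effect `ē_i = clip(effect·η_i, 0, 1)` with multiplicative efficacy noise
`η ~ N(1, σ=0.2)` truncated at 0 (guide activity varies substantially in
practice; one multiplicative factor captures this without extra
parameters); fitness `w = 2^(−δ·ē)` per doubling with δ = 0.4 over
G = 12 doublings, so fully effective guides deplete ≈30-fold (raw
log10FC ≈ −1.45, consistent with positive controls anchoring at −1);
each timepoint × replicate is an independent multinomial draw. The
expected raw fold change is `−G·δ·ē·log10 2` up to a pool-renormalization
constant `−log10 Σ p0·w^G`; that constant is why, in a pool containing
depleting positive controls, neutral guides show a small *positive* raw
fold change — which the negative-control anchoring removes.

The planted essentiality landscape used for recovery testing is a
symmetric exponential peak `e(r) = exp(−|r−108|/12)` supported on
residues 63–135. The shape is deliberate: recovery of the peak location
by an argmin is only well-posed if the planted optimum is unique and has
nonzero gradient at the apex. Flat-topped profiles (boxcars, wide
Gaussian bumps) leave the argmin undetermined at the smoother's
resolution, and asymmetric tents bias the smoothed apex toward the
shallow side. With this landscape the full pipeline relocates the peak
within ±3 residues in ≥95 of 100 seeds at depth 10⁶.

ChIP track simulation plants per-gene (enrichment, reduction) pairs over
TSS ± 1 kb windows on constant-baseline tracks, forcing interval breaks
at window edges so noiseless tracks reproduce the planted values exactly;
Gaussian bin noise (floored at 0) is optional.

What the generator does **not** model — and hence what passing tests do
not establish about real data: PCR amplification bias and chimeras,
sequencing errors inside the spacer (reads are error-free, so exact
matching is lossless here but would under-count on real data), multiplicity
of infection and clonal drift, guide-position-dependent editing outcomes
(in-frame repair near domain boundaries), and ChIP fragment-size effects.

## Problem sizes and numerics

Default test and acceptance runs use the 456-codon screen (≈270 guides
including controls) at depth 10⁶ with 3 replicates, and 100-seed
ensembles for recovery rates — sizes chosen so that a full suite run
completes in seconds while the multinomial noise floor stays well below
the effects being measured. All random processes take explicit integer
seeds (numpy `default_rng`); equal config + seed gives bit-identical
output. Degenerate inputs fail loudly: zero-mass samples, missing
timepoints, missing or degenerate control anchors (`m_neg = m_pos`),
all-NA profiles, overlapping ChIP windows.

## Known limitations

Exact spacer matching (optionally Hamming-1) replaces aligner-based
mapping; real screens with sequencing errors need the mismatch option or
an upstream aligner. The under-representation filter's timepoint is a
convention, not a ground truth. The kernel bandwidth and the
nucleotide-vs-residue smoothing space are exposed options; results at
single-residue granularity depend on both. Real-data target counts from
ChIP classification depend on the TSS annotation set and pileup
normalization used upstream, which this package deliberately does not
re-implement.
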