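# Methods

## Model and procedure

The toolkit measures the correlation between AT and GC compositional
biases along a replicon. All statistics are built from cumulative base
counts *A<sub>n</sub>, C<sub>n</sub>, G<sub>n</sub>, T<sub>n</sub>*
accumulated from the deposited start of the sequence, stored as exact
int64 arrays of length *N* + 1 (index 0 is all zeros). The three Z-curve
components *x, y, z* and the disparity tracks *a* = *A* − *T*,
*b* = *G* − *C* follow algebraically; because *x* + *y* = 2(*A* − *T*)
and *x* − *y* = 2(*G* − *C*), the halvings in the disparity definitions
divide evenly and every track is integer-valued, so the defining
identities can be (and are) asserted exactly in tests.

The **ZCC index** is Pearson's *r* between *a* and *b* over positions
1…*N*. The correlation index set excludes the *n* = 0 origin point —
both tracks are identically zero there and the accumulation range of the
counters, not the correlation, is what starts at 0; at genome scale its
inclusion changes *r* below any reported precision. *r* is computed by
centring both tracks in float64 and forming the cross/square sums with
vectorised dot products; this avoids the catastrophic cancellation of the
raw-moment formula, and the implementation agrees with an independent
pure-Python textbook oracle (and scipy) to 1e−12 in the test suite. When
either track has zero variance (homopolymers, A/T-free sequences) the
index is undefined: lenient mode returns NaN with a `degenerate` flag that
downstream summaries respect, strict mode raises. The value is never
silently reported as 0.

The **RY–MK index** is the same correlation applied to *x* and *y*. The
package follows the component definitions above, where *y* is amino
minus keto; an `mk_sign=-1` option negates *y* for the keto-over-amino
reading (this exactly flips the sign of *r*).

### Replichore inference

On a circular chromosome with G-enriched leading strands, the cumulative
G−C track rises from origin to terminus on each replichore, so the curve
plotted from the origin is an inverted V peaking at the terminus. The
estimator therefore detrends the GC disparity by subtracting the chord
from (0, *b*<sub>0</sub>) to (*N*, *b*<sub>N</sub>) — which makes the
extremum positions equivariant under rotation of the deposited start —
and reports **ori = argmin, ter = argmax** of the detrended curve. (The
opposite max→ori pairing circulates in the literature's prose; it is
inconsistent with the inverted-V geometry of the G−C curve under a
G-rich leading strand, and the geometry-consistent convention is used
here.) A flat curve is a no-signal error; the reported confidence is the
detrended amplitude per base, clipped to [0, 1], about 2·δ<sub>G</sub>
for a clean two-replichore genome with per-base G−C drift δ<sub>G</sub>.
Estimates on sequences shorter than 1 kb emit a warning. When a curated
oriC interval is supplied instead, ori is its integer midpoint (ties
broken downward) and ter is taken from the detrended extremum farther
from ori.

Genes are assigned by midpoint: a midpoint on the half-open arc
[ori, ter) (increasing coordinates, wrapping) is leading iff the gene is
on the forward strand, and conversely on [ter, ori). Midpoints landing
exactly on ori or ter are decided by the same half-open rule. Midpoint
membership was chosen over overlap-fraction rules because it is a single
deterministic arc test and genes spanning a boundary are rare at genomic
scale. The SGD fraction is the share of assignable genes on the leading
strand; genes on other replicons are skipped with a warning and an
all-skipped input is an error rather than a 0/0.

Internally all replichore coordinates are 0-based half-open on the
circle; every external file is 1-based inclusive and converted exactly
once at the module boundary.

### Cohort statistics

Per-phylum summaries report sign counts, percentages (one decimal, over
sign-carrying genomes), mean and sample SD (ddof = 1) of non-degenerate
ZCC values, and the majority-sign group label (P-ZCC / N-ZCC; an exact
tie is flagged unclassified rather than broken arbitrarily). A ZCC of
exactly 0 — possible on toy inputs, measure-zero on real genomes —
carries no sign and is tallied separately. Phyla are included only when
they hold strictly more than `min_n` genomes (default 15), mirroring the
small-sample exclusion used in survey practice.

Outliers use Tukey fences Q1 − 1.5·IQR, Q3 + 1.5·IQR with strict
inequality, quartiles by numpy's linear-interpolation rule. The source
surveys do not state their quartile convention; borderline outlier sets
can differ between conventions, so the numpy `method` is exposed as a
parameter. The polymerase cross-tab assigns any PolC-bearing genome to
the PC group regardless of its DnaE complement (all DnaE subtypes are
united), the rest to DE; genomes without metadata or with unknown PolC
status are excluded from the cross-tab only, and a second variant drops
the Tukey outliers.

## Synthetic genomes

The generator emulates exactly the feature the statistics measure: a
circular chromosome with two replichores and first-order strand
composition bias. Each position is sampled independently; on the arc
where the forward strand is leading, base *b* has probability
*p<sub>b</sub>*; on the other arc the forward strand is lagging, so *b*
has the probability of its complement (the reverse-complement strand
there is leading with the same composition). Regime presets put the
enrichment δ on A and G (positive-ZCC, purine asymmetry) or on G and T
(negative-ZCC); δ defaults to 0.05 per base, i.e. leading-strand
probabilities (0.30, 0.20, 0.30, 0.20), which yields |ZCC| ≈ 0.998 at
200 kb and a detrended-extrema ori error around 0.003 % of N. Genes are
non-overlapping intervals placed one per equal-sized slot around the
circle with a configurable probability `p_leading` (default 0.78) of
being on the leading strand of their arc; truth files record the
intended class of every gene and the true ori/ter.

What the generator does **not** emulate: dinucleotide/codon structure,
deamination gradients, transcription-coupled repair, gene-length and
intergenic-length distributions, plasmids, or multiple origins. Passing
tests therefore demonstrate correctness of the statistics under the
two-replichore first-order model, not robustness to every biological
confounder; on real genomes the ZCC magnitude and ori accuracy depend on
skew strength and local anomalies (prophages, rearrangements).

## Problem sizes and numerical choices

The simulation-backed tests use 200 kb genomes (20 seeds per regime) for
sign recovery, 500 kb (20 seeds) for ori recovery, 1000 genes for SGD
recovery, and a 2 × 20-genome cohort at 50 kb for the end-to-end
pipeline — sizes at which the expected skew signal (δ = 0.05) dominates
sampling noise by a wide margin while the whole suite stays fast enough
to run habitually. Equality tolerances against oracles are 1e−12
(relative for the streaming-vs-naive comparison); integer identities are
asserted exactly. Ambiguous IUPAC residues advance the position counter
but no base counter, preserving coordinate alignment with annotations;
they are excluded from the GC-content denominator. Multi-record FASTA
files are analyzed per record, with `--longest-only` to select the
chromosome from assemblies carrying plasmids.

## Known limitations

- Single-origin circular replicons only; no multi-origin or linear
  replication models, and no segmentation/wavelet refinement of the
  extremum estimator.
- ZCC is computed on the sequence as deposited by default; rotating to
  the origin first (supported via `--rotate-to-ori`) generally changes
  the value slightly, and which convention a given published survey used
  is usually unstated.
- PolC/DnaE presence is taken as metadata, never called from sequence.
- No significance testing of *r*: the index is descriptive.
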