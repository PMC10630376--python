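# Methods

This note records the statistical model, the coordinate and offset conventions, the
simulator design, and the reasoning behind every tunable default. Everything here is
implemented in `src/termarrest/` and exercised by the test suite.

## 1. Signal model

A metabolically installed propargyl group, once clicked to a bulky adduct, terminates
reverse transcription. For a modified base at transcript position *m* (0-based), the
reverse transcriptase synthesizes 3′→5′ along the template and stops **before**
copying the modified base, so the 5′-most sequenced position of the truncated cDNA is
*m* − 1 in transcript coordinates. This one-nucleotide offset is the package constant
`ARREST_OFFSET = 1`, shared by the simulator and the caller, so localization (shifting
each call one nucleotide toward transcript-3′; +1 genomic on the plus strand, −1 on
the minus strand) is exact by construction and verified end to end by the
localization tests.

Per position and sample:

- coverage *c* = number of reads covering the position (a truncated read covers its
  stop position),
- arrest count *a* = number of reads whose transcript-5′ terminus was assigned to the
  position by a termination event,
- arrest rate *r* = 100·*a*/*c*, undefined (skipped, not scored as 0) when *c* = 0.

The calling score is Δ = *r*(treated) − *r*(control) in percentage points.
Natural read ends (library fragmentation, full-length cDNA) are counted as coverage
but not as arrests in the simulator's pileup construction; an optional alignment-based
pathway counting every read 5′ terminus would add a constant background absorbed by
the control subtraction, and is out of scope here.

## 2. Filters

Thresholds are **exclusive** (strictly greater than):

| tier | treated coverage | Δ |
|---|---|---|
| HS | > 35 | > 20 |
| LS | > 20 | > 15 |

so HS calls are a strict subset of LS calls (property-tested on random tracks).
Coverage gates the treated sample by default (`coverage_on="treated"`); the control
enters only through its rate. A minimal-evidence prefilter requires ≥ 4 reads summed
across both samples (`min_coverage_mode="summed"`; a per-sample variant is provided).
Rates are compared unrounded. Positions within 5 nt of the transcription start site
on the transcript-5′ side are excluded (one-sided margin: a TSS *downstream* of a
site cannot produce a cap-proximal artifact at it). All of these appear as explicit
`FilterConfig` fields rather than constants so the variants can be compared.

## 3. Coordinates

Internally everything is 0-based, half-open. GTF input/output converts from/to
1-based inclusive at the boundary; BED is natively 0-based half-open. When several
transcript isoforms share a locus, sites are assigned to the longest (spliced)
transcript, with lexicographic transcript ID as the deterministic tie-break.

## 4. Simulator

`SimulationConfig` defaults: 20 transcripts of 600 nt (100 nt 5′UTR, 300 nt CDS,
200 nt 3′UTR), read length 150, mean coverage 60×, background stop probability 0.001
per nucleotide, DRACH anchors planted every 50 nt (and TACAGA contexts between them,
giving a centered ACAGA 5-mer inside a METTL16-like UACAD context). Sizes were chosen
so that a planted site with ≥ 0.4 arrest penetrance comfortably clears the HS coverage
threshold at 60× while keeping the full test suite in seconds.

Per read: a 3′ start is drawn (uniform over the transcript, or fixed at the 3′ end
for noise-free localization experiments), the maximal 5′ extent is start − read
length + 1, and each modification between those bounds independently terminates the
read with its per-sample arrest probability; a geometric background stop competes.
The realized stop is the **maximum** (most 3′) candidate position — the exact law of
competing risks for a 3′→5′ polymerase, since the first obstacle encountered wins.
If nothing fires, the read ends at its natural 5′ limit and contributes coverage but
no arrest.

Class semantics: m6A/m5C stop at offset −1 with probability *p* in the treated sample
only; Nm (2′-O-methyl) stops at −1 with *p·s* and at −2 with *p·(1−s)* (default split
*s* = 0.5, which equalizes the expected arrest *rates* at the two offsets because a
read stopped at −1 never covers −2); m1A stops at −1 with equal probability in both
samples (RT arrest without metabolic labeling). This produces the three diagnostic
signatures downstream: precise, stepwise, and both-samples termination.

A deliberate emergent property (not a bug): with several penetrant sites on one
transcript, 5′ sites lose treated coverage to truncation at 3′ sites within a read
length. The benchmark experiments therefore plant one site per transcript, which is
also the majority case observed for real m6A call sets.

## 5. Signatures

For each candidate site the signature vector is the treated-minus-control arrest-rate
difference at offsets −3…+2 relative to the modified position (positions with < 4
reads in either sample are skipped and reported). Vectors are clustered with
average-linkage agglomerative clustering on Euclidean distance
(`scipy.cluster.hierarchy`) and cut at 2 clusters; cluster medians are classified as
**precise** (secondary/primary peak ratio < 0.3) or **stepwise** (two adjacent peaks)
— median rather than mean for robustness to the occasional starved profile. Average
linkage was chosen over Ward because the two classes differ in shape, not just scale;
the clustering is permutation-invariant (tested). Sites with control arrest rate
> 20 % are flagged as m1A-like regardless of cluster.

## 6. Metatranscript axis

cDNA position *x* maps to segment-relative thirds: 5′UTR → *x*/len₅, CDS →
1 + (*x* − len₅)/len_CDS, 3′UTR → 2 + (…)/len₃, so the CDS start maps exactly to 1.0
and the stop boundary to 2.0 (asserted to equality, not tolerance). Densities use a
Gaussian kernel (bandwidth 0.05 in scaled units) with **reflection at 0 and 3**
(mirror sources at −*x* and 6 − *x*), so the density integrates to 1 on [0, 3] within
1e−3 despite the hard domain edges. Bandwidth 0.05 resolves the UTR–CDS boundary
structure without oversmoothing at the benchmark site counts (hundreds).

## 7. Motifs

Motif work uses the RNA alphabet internally; minus-strand k-mers are
reverse-complemented into transcript orientation first. The hierarchy is
DRACH ⊂ NRACN over central-A 5-mers: D = A/G/U, R = A/G, H = A/C/U, N = any, giving
3·2·1·1·3 = 18 DRACH and 4·2·1·1·4 = 32 NRACN 5-mers (verified by exhaustive
enumeration against an independent set-membership oracle). Non-A centers raise an
error rather than silently classifying. The METTL16-like context is UACAD with the
modified A in fourth position, i.e. the centered 5-mer is ACAGA/ACAAA/ACAUA with a U
immediately 5′ of it. Position frequency matrices are 5×4 row-stochastic tables.

## 8. Attribution

A site is attributed to an enzyme only if it is reproducible (exact
reference/position/strand intersection of two replicates) in **both** the in vitro and
the metabolic experiment; in vitro-only sites are reported as putative reaction
off-targets. Exact matching is the default; a ±*w* window variant exists for
cross-dataset comparisons where pipelines may disagree by a nucleotide.

## 9. Reproducibility

`scripts/acceptance.py` recomputes every headline quantity from a single `--seed`,
deriving independent sub-streams via `numpy.random.SeedSequence`; no state is read
from disk. All benchmark experiments live in `termarrest.experiments` and are shared
verbatim between the acceptance script, the analysis drivers and the test suite.

## 10. Limitations

- Transcript-coordinate simulation only: the genomic/splicing machinery is exercised
  by the annotation and metatranscript modules, not by the read simulator.
- No sequencing error, PCR duplication, or mappability model; background stops are
  i.i.d. geometric.
- m1A flagging at ~50 % penetrance in both samples is robust at HS stringency; at LS
  stringency an occasional sampling fluctuation of the rate difference (SD ≈ 8
  percentage points at 80×) can clear the 15-point threshold.
- The 2-cluster signature cut assumes the call set contains both precise and stepwise
  sites; degenerate inputs are detected and flagged rather than classified.
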