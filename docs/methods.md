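# Methods

This note records the models, parameter choices and numerical conventions
behind `mirdeg`, and what the synthetic-data validation does and does not
demonstrate about real data.

## Read processing

A 3′ adapter occurrence at read position *p* compares `read[p:p+ov]` with
`adapter[:ov]`, `ov = min(len(adapter), len(read) − p)`; it is accepted when
`ov ≥ 19` and the mismatch fraction is ≤ 10% (cutadapt's spirit; exact mode
via `max_mismatch_rate=0`). The leftmost occurrence wins and trimming is
iterated to a fixed point, which makes `trim(trim(x)) = trim(x)` hold
unconditionally — a single leftmost pass can strand a residual adapter
prefix when a long partial match fails the full-overlap mismatch threshold.
Retention requires an identified adapter and insert length strictly > 13 nt.
Quality values are ignored throughout: the generator emits constant
qualities and no quality-based filter is defined.

RPM is `raw × 10⁶ / (retained reads in the library)`; RPM sums to 10⁶ per
library by construction. Internally all coordinates are 0-based half-open;
GFF3/BED reports follow their own conventions (1-based inclusive, 0-based
half-open).

## Clustering

Tags are placed at every exact genomic match on both strands (a
`max_mismatches` knob exists but exact matching is the default and the only
mode exercised). Same-chromosome, same-strand placements sorted by start are
chained while `next.start − cluster.end ≤ max_gap` (default 100 nt); this
equals single-linkage on the pairwise interval-gap relation, which the test
suite verifies against a brute-force transitive closure. Clusters are
strand-specific; multi-mapped tags are counted in every cluster they touch
but flagged, and flagged tags never seed a discovery candidate (avoiding
double discovery). Unmappable tags are reported in an unplaced bin so
read accounting reconciles exactly.

## Hairpin validation

Candidate windows extend an abundant, uniquely-mapped tag (≥ 20 reads by
default) by 200 nt on both sides, reverse-complemented for minus-strand
clusters. Folding goes through a single engine contract
(`fold(seq) → (dot-bracket, energy)`): ViennaRNA MFE when importable,
otherwise a bundled Nussinov-style maximum-base-pairing folder with simple
stacking weights whose pseudo-energy is explicitly non-thermodynamic. MFE
ties are whatever the engine reports first; the stored structure is always
re-derivable because the excised precursor is re-folded and that fold is
what is kept.

Acceptance rules: ΔG < 0; the mature lies entirely on one stem arm (all
pairing partners on one side); ≤ 4 unpaired mature bases; no one-sided
bulge > 2 nt (symmetric internal loops are limited only by the unpaired
rule). The miRNA* span is the partner interval of the mature shifted 3′ by
2 nt on both ends — the canonical Dicer 2-nt 3′ overhang geometry — with
unpaired terminal mature bases extrapolated through the nearest paired
position. Both thresholds follow common plant-miRNA annotation practice and
are config-exposed; calls whose star is absent from the read set are kept
but flagged rather than discarded.

When one cluster contains a second abundant tag (≥ 10% of the seed) lying
fully on the opposite arm of the same hairpin, it is emitted as a second
mature against the same precursor id — the two-miRNAs-one-precursor case.
The scan runs on the unrefined window (before precursor excision) so the
opposite arm is still present; the final precursor covers both duplexes.

Novelty cutoffs against the catalog (full-length, ungapped, ±2 nt handled
by sliding): 0 mismatches = known, 1–2 = homologue, > 2 = novel. Families
join miRNAs with edit distance ≤ 3 (edlib) that share at least one target
transcript. Both are package decisions, not literature constants.

## Spliced pri-miRNA alignment

MIR gene models come from an exact colinear chain of exon blocks (≥ 20 nt)
on one genomic strand whose gaps are introns ≥ 60 nt beginning GT and
ending AG (U2 type). Exon boundaries back off by up to 10 nt to find a
GT donor; the full pri sequence must be covered. A non-GT…AG gap (e.g. a
GC–AG intron) surfaces as a failure whose diagnostics name the non-U2
donor, rather than as a silently wrong model. The precursor-bearing exon
index is reported in transcript order ("second exon" = second exon of the
spliced pri).

## Degradome analysis

Tag 5′ ends are counted per exact transcript match; normalisation is per
million *mapped* tags (unmapped tags are reported but excluded from the
denominator — the formula is a package decision). Multi-placed tags
increment every pileup but count once in the mapped total, so
Σ raw + unmapped = input tags. Cutting power is the normalised count at a
position; ranking is by descending normalised count, ties by raw count,
then by the 5′-most position.

The compliance score treats 0 as perfect ("lowest score first" ranking);
the per-position penalties (mismatch 2, wobble 1, bulge 2, doubled at
positions 2–13, capped at 18) are integers chosen to span exactly 0–18 in
the spirit of standard plant target-prediction scoring, and are
config-exposed. `DuplexAlignment.inverted_score` (18 − S) is provided for
reports preferring the opposite polarity. The aligner is a banded (±3)
global DP; the tests pin it to an unbanded exhaustive oracle on windows
≤ 25 nt of the realistic near-complementary class (pathological sequences
could in principle reward paths outside the band, but such duplexes score
far above any acceptance cutoff anyway).

A target call requires a peak of rank ≤ 3 (operationalising "one of the
first positions") whose position is exactly the target residue paired to
miRNA nt 10 — i.e. cleavage between the residues paired to nt 10 and 11 —
with S ≤ 7. Near-misses are returned with the failed rule for diagnostics.
T-plot tables are dense (every transcript position, zeros included).

## Expression statistics

Differential testing is a two-sided Welch t-test on log2(value + 0.25)
per feature, no multiple-testing correction: with a handful of planted
features the FDR machinery would only obscure the planted effects, and the
choice is config-visible. Identical constant groups are defined to give
log2FC = 0, p = 1. Stars: `**` for p ≤ 0.01, `***` for p ≤ 0.001.
qPCR quantification is 2^−ΔΔCt with a condition-invariant reference gene;
it is invariant to any global Ct shift.

**Compositional caveat.** Library sampling is per-feature Poisson with
means proportional to absolute abundance at a fixed nominal depth, so
planted condition effects act directly on expected counts (a 0.25× factor
gives a 0.25 count ratio). RPM, in contrast, renormalises to the library
total; when every miRNA moves the same direction — the drought design —
total-count normalisation absorbs part of the shift (with 30% background a
true 0.25× appears as ≈ 0.53× in RPM). `differential(..., values="raw")`
therefore drives the effect-recovery validation, and RPM-based fold changes
under global shifts should be read as compressed. This mirrors the real
compositional limitation of total-count-normalised sRNA libraries.

## Synthetic-data model and its limits

The generator plants: perfect-stem precursors with two engineered G:U
wobbles (or mismatches where the sequence allows no wobble) opposite each
mature — real stems are imperfect, and without this every mature would map
to both arms and be discarded as a multi-mapper; one two-arm precursor;
U2 GT…AG introns (80 nt) with the precursor in the second exon for two
genes; 21-nt matures with small 3′-end length variants (84/7/6/3% at
0/−1/+1/−2 nt); miRNA* at 10% of miRNA; 30% background reads, of which 98%
come from ~30 discrete 500-nt "noise loci" (rRNA/degradation-like hotspots)
and 2% are uniform genomic 18–26-mers — fully uniform background at desk
scale is so dense it chains entire chromosomes into single clusters, which
no real genome exhibits. Target sites are exact complements placed mid
transcript; PARE signal tags (60 per link) start exactly at the slicer
position over a Poisson background (~20 per transcript). Drought factors
(miRNA 1/0.5/0.25/0.6; targets reciprocal) mimic the qualitative
down-miRNA/up-target pattern only — the magnitudes are generator choices,
not measured values. Replicate noise is lognormal (sd 0.1 in log2 units);
qPCR noise is Gaussian on Ct (sd 0.1).

Consequently, passing tests demonstrate the pipeline's rules and plumbing
— not performance on real libraries: there are no sequencing errors, no
isomiR 5′ heterogeneity, no repeat-derived multi-mapping families, no
imperfect target sites, and the genome is orders of magnitude smaller than
a real one. Problem sizes in the shipped tests (genomes 12–50 kb, 3–6 MIR
genes, 8–30 k reads, 10 seeds for the end-to-end properties, 500–1000
Monte-Carlo draws for the statistical checks) were chosen so the whole
suite runs in a few minutes on one CPU.

## Degenerate inputs and tie-breaks

Empty clusters, empty catalogs, unknown conditions, non-ACGU/N symbols,
missing reference-gene measurements and sub-2-replicate designs raise
`ValueError`/`KeyError` rather than returning defaults. Deterministic
tie-breaks: modal length → smaller length; peak ranking → higher raw count,
then 5′-most position; collapsed tags → higher count, then lexicographic;
family ids → lexicographically smallest member. All simulators are
deterministic for a fixed (config, seed), with independent sub-streams per
library derived from `numpy.random.SeedSequence`.
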