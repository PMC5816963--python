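# Methods

## The model

`coremic` identifies a *core microbiome*: the set of taxa statistically
associated with a habitat of interest, defined operationally as taxa that are
(i) present in at least a threshold fraction of interest-group ("in-group")
samples and (ii) significantly enriched in presence relative to an out-group
of comparison habitats, at a controlled false discovery rate.

The method deliberately discards abundance magnitude.  For each taxon *t*,
counts are binarized to presence/absence per sample (present iff count ≥
detection threshold, default 1 — the zero/nonzero rule for integer counts),
and the samples are cross-tabulated:

|            | present | absent |
|------------|---------|--------|
| in-group   | a       | b      |
| out-group  | c       | d      |

The evidence for enrichment is the one-tailed Fisher's exact p-value, the
upper tail of the hypergeometric law with all margins fixed:

    p_t = P(X ≥ a),  X ~ Hypergeom(N = a+b+c+d, K = a+c, n = a+b).

It is computed by direct tail summation in log-space (log-gamma binomial
coefficients + log-sum-exp), which is exact to floating precision and
overflow-free for any group size.  The p-values of **all** merged taxa are
then adjusted by the Benjamini–Hochberg step-up procedure
(q(i) = min_{j≥i} p(j)·m/j, clipped at 1).  A taxon is flagged core when

    q < alpha  AND  a/(a+b) ≥ min_in  AND  c/(c+d) ≤ max_out  AND  informative.

Working on presence/absence makes the test robust to the large depth and
platform differences that dominate cross-study meta-analyses, at the cost of
ignoring abundance shifts; the documentation recommends complementing it with
an abundance-based differential test when within-study effects matter.

## Pipeline order and why it matters

The pipeline order is fixed:

1. **Collapse** each study's table: rows with identical canonical taxonomy
   are summed per sample (per-sample totals are conserved exactly).
2. **Merge** studies by intersecting canonical taxonomies; any taxonomy not
   observed in every study is dropped, and sample sets are concatenated
   (sample ids must be disjoint — collisions error rather than rename, since
   silent renaming would corrupt the group mapping).
3. Optional **depth filter**: samples with total counts below `min_depth`
   are removed and logged.
4. Optional **normalization** (see below).
5. **Binarize** at the detection threshold.
6. **Fisher p for every merged taxon**, then **BH across that full
   p-vector**, then the presence filters, then the informativeness filter.

BH runs *before* the presence filters: filtering first would shrink the
multiple-testing family and change what the q-values control.  Likewise the
uninformative-lineage filter is applied last, so it never alters the FDR
family.  Taxa absent from every sample get p = q = 1 and can never be core;
they remain in the family (a conservative choice — excluding them could only
make q-values smaller).

Presence thresholds are compared on unrounded fractions; the percentages in
reports are rounded half-up to one decimal (28/31 → 90.3) for display only,
avoiding threshold artifacts near the boundary.

## Taxonomy handling

Lineages are Greengenes-style rank-prefixed strings
(`k__Bacteria;p__Proteobacteria;…;s__`).  Canonicalization strips whitespace
and accepts both single- and double-underscore prefixes, normalizing to the
double-underscore Greengenes convention; trailing empty ranks are preserved
(so `k__Bacteria` and `k__Bacteria;p__` stay distinct keys).  "Identical
taxonomy" in collapse and merge always means identical canonical strings.

A lineage is *informative* when at least `min_named_ranks` (default 2) ranks
carry names: `k__Bacteria;p__;c__;o__;f__;g__;s__` is filtered out, while a
taxon named only down to order (e.g. `o__B97`) is retained — unresolved
deeper ranks are common and still biologically reportable.

Readers never merge rows: duplicate taxonomies in one file are kept,
disambiguated by an internal ordinal suffix, so that the collapse step is
explicit, observable and testable.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `alpha` | 0.05 | q-value (BH-adjusted p) cutoff |
| `min_in_pct` | 90 | minimum in-group presence, percent |
| `max_out_pct` | 100 | optional out-group presence ceiling, percent (100 = no ceiling; exposed because out-group presence is a legitimate user criterion, but the default imposes none) |
| `detection_threshold` | 1 | minimum count for "present" |
| `min_depth` | 0 | drop samples with fewer total counts |
| `normalization` | none | `none`, `total_sum`, `rarefy` |
| `min_named_ranks` | 2 | informativeness cutoff |

Normalization defaults to `none` because binarization at threshold 1 is
scale-invariant: `total_sum` (columns divided by their totals) cannot change
presence calls, and is provided for users who export relative abundances or
raise the detection threshold.  `rarefy` subsamples each sample without
replacement to a fixed depth using `numpy`'s multivariate hypergeometric
sampler, seeded and exactly depth-preserving; it *can* flip rare cells to
absent and is provided for parity with standard 16S workflows.

The enrichment direction is fixed: presence greater in the in-group.  To
test the opposite direction, swap the group labels — a deliberate design
that avoids sign-convention ambiguity.

## Synthetic data generator

`coremic.synth` emulates the statistical structure of a two-study 16S
meta-analysis so the whole pipeline is testable offline:

- two sample groups (defaults 30 + 30) split round-robin across two studies;
- study-specific mean depths (2,000 vs 10,000) standing in for the
  shallow-454 vs deep-Illumina heterogeneity of real multi-study data;
- 10 planted core taxa with occurrence probability 0.95 in-group / 0.15
  out-group among 300 background taxa at 0.5 everywhere;
- 70% of taxa shared across studies (planted taxa always shared), the rest
  private to one study so the intersection merge is exercised;
- presence drawn Bernoulli per taxon × sample; counts conditional on
  presence drawn 1 + negative binomial (dispersion r = 2, mean tied to the
  study depth).  Only the presence structure matters to the test, so the
  count law is a documented free choice.

Everything derives from one seeded `numpy` Generator, so datasets are fully
reproducible.  The generator does **not** model ecological correlation
between taxa, phylogenetic signal, compositional closure, or sequencing
noise/chimeras; passing recovery tests therefore demonstrates correctness of
the statistical machinery under independent-Bernoulli presence, not
performance on real communities.

Recovery is scored as sensitivity (planted taxa flagged / planted) and
empirical false discovery proportion (non-planted flagged / flagged, defined
as 0 when nothing is flagged).  Under the default planted-effect settings the
test suite requires mean sensitivity ≥ 0.9 and mean FDP ≤ 0.05 over 100
seeded replicates, and a near-null configuration to flag on average at most
5% of tested taxa.  Replicate counts (100) and table sizes (~310 taxa × 60
samples) were chosen as the smallest scales at which the binomial noise on
these averages is well inside the asserted bands.

## Numerical and degenerate-input choices

- Fisher tail: log-space summation; `a + c = 0` (taxon absent everywhere)
  returns p = 1 exactly; the tail that covers the whole support returns 1.
- BH: stable sort; ties share identical q; output returned in input order.
- Percent rounding: decimal half-up (not banker's), one decimal.
- Collapse/merge preserve first-occurrence row order internally, but
  `identify_core` sorts its results by canonical taxonomy and the results
  writer sorts by (q, p, taxonomy), so outputs are invariant to input row
  and sample order.
- Rarefaction drops samples below the target depth with a logged warning
  rather than erroring, matching common practice.
- All-zero sample columns make `total_sum` undefined → hard error.
- BIOM support is v1 JSON only (dense and sparse); HDF5 files are detected
  by magic bytes and rejected with a message naming the conversion path.
  Floating-point counts are accepted unchanged (real exports contain them;
  binarization makes them harmless).

## The taxonomy tree

The reported "tree" is a trie over rank paths of the core taxa's lineages —
a taxonomy tree, not an inferred phylogeny (no branch lengths, no sequence
information).  Paths end at the deepest named rank.  Exports are Newick
(internal labels = rank tokens; each leaf carries its full sanitized lineage
in a bracket comment that standard parsers skip; metacharacter-containing
labels are quoted) and an indented text rendering in which a numeric
q-value annotation per leaf substitutes for the color coding of graphical
viewers.  An out-group core set (computed by swapping group labels) can be
unioned into the same tree for comparison.

## Replicating the original switchgrass case study

The motivating two-study analysis (switchgrass rhizosphere vs. other grasses
and forbs; 678 shared OTUs, 31 vs 28 samples, five core OTUs) cannot be
reproduced from this repository alone: it requires downloading the raw 16S
data from the European Nucleotide Archive / NCBI SRA under accessions
**PRJEB6704** and **PRJNA320123**, quality-filtering reads (cutadapt,
quality ≥ 25, length ≥ 150), and open-reference OTU picking at 97% identity
against Greengenes 13.8 (QIIME 1 uclust) to obtain taxonomy-labelled OTU
tables.  A user with those two BIOM tables and a mapping file assigning
samples to `Swg` / `NonSwg` can then run:

    coremic run --data jesus2016.biom --data rodrigues2017.biom \
        --mapping map.tsv --group-column Plant --interest Swg --outgroup rest \
        --alpha 0.05 --min-presence-interest 90 --out results/

Two samples with total counts below ~1,150 should be removed first
(`--min-depth 1150` reproduces that filter).  Raw-read QC and OTU picking
are out of scope for this package, so exact numerical agreement additionally
depends on reproducing that upstream pipeline version-for-version.

## Known limitations

- Presence/absence discards abundance information entirely; taxa with large
  abundance shifts but ubiquitous presence are invisible to this test.
- The intersection merge discards taxa absent from any study, biasing the
  candidate set toward well-shared taxa — intended behavior for
  meta-analysis, but worth remembering when a study has shallow coverage.
- FDR control is over presence-enrichment hypotheses under independence
  assumptions; strong positive correlation between taxa can make the
  realized FDP noisier than the nominal level.
- The synthetic generator's independence assumptions (see above) mean green
  tests do not certify performance on real, correlated communities.
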