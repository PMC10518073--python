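# Methods

This note documents the models, defaults, and design choices behind
screpkit, and what the simulator-based tests do and do not demonstrate
about real data.

## Data model

The central object, `RepertoireProject`, joins three slots on the key
`(sample_id, barcode)`: per-sample lists of paired receptor chains
(`CellReceptor`), an optional genes × cells count matrix, and a free-form
cell-metadata table carrying at least `has_vdj`/`has_gex` flags. Cells
present in only one modality are kept and flagged rather than dropped —
VDJ-only cells still count for repertoire statistics, GEX-only cells for
expression work; no silent intersection happens at load time.

Chain pairing: loci are split into a VDJ class (IGH, TRB, TRG, TRD) and a
VJ class (IGK, IGL, TRA). After filtering (productive-only and
high-confidence-only, both on by default; zero-UMI contigs always drop),
each cell keeps at most one chain per class: highest UMI count wins, ties
broken by read count then lexicographic contig id. Cells where extra
chains were dropped are labelled `multi_resolved` instead of being
discarded: true doublet removal belongs to expression-side QC, and the
flag lets downstream users exclude them if they wish. Cellranger lane
suffixes (`-1`) are stripped from barcodes by default (overridable) so
VDJ and GEX libraries from multi-lane runs match.

Coordinates are 0-based half-open internally; the AIRR writer emits
standard AIRR Rearrangement columns plus `consensus_count` and a
`high_confidence` extension column so that write→read round trips are
field-exact. Rows without `cell_id` cannot be linked to a cell and are
skipped with a logged count. A missing constant-region call is stored as
an empty string and surfaces as `unknown` in isotype summaries.

## Clonotyping

Three strategies, all producing a partition of the retained cells:

* `cdr3_nt_exact` (default): exact match of the (heavy, light) CDR3
  nucleotide pair. A missing chain is encoded as a distinct token, so
  orphan-chain cells form their own groups instead of vanishing.
* `cdr3_aa_exact`: the same on amino acids; merges synonymous variants,
  and every nucleotide-level clonotype is a subset of an amino-acid one.
* `vj_cdr3_homology`: bucket by (heavy V, heavy J, light V, light J,
  CDR3 lengths), then single-linkage within buckets, linking two cells
  when matching positions across the concatenated CDR3s ÷ total positions
  ≥ the threshold (default 0.8, a community-typical junction-identity
  cutoff). Identity is computed on amino acids; single linkage means
  chains of intermediates merge, mirroring how hypermutation actually
  connects variants.

Clonotype ids are assigned by descending size with lexicographic
consensus-CDR3 tie-breaks, so output order is deterministic. Isotype
composition is read from the IGH constant-region call only.

## Diversity and rarefaction

All metrics consume a clone-size vector. Shannon entropy is reported in
nats (base-2 available via an argument); Pielou evenness of a single-clone
repertoire is defined as 1, and the Gini coefficient of one clone as 0
(degenerate but finite). Rarefaction uses the exact hypergeometric
expectation computed through log-gamma to avoid overflow at realistic
depths; default depths are ten evenly spaced values from 10% to 100% of
the total. The curve hits observed richness exactly at full depth, which
is both a correctness check and the "have we sampled enough" read-out:
a curve still rising at full depth means richness is under-sampled.
Asymptotic richness estimators (Chao1 and relatives) and the Hill-number
continuum are deliberately out of scope. Between-sample overlap offers
presence/absence Jaccard and abundance-weighted Morisita–Horn; vectors
align on clonotype labels when both carry them, else positionally.

## Similarity networks

The distance kernel is Levenshtein (via edlib's banded alignment),
Hamming, or length-normalized Levenshtein; default threshold 1 on CDR3
amino acids gives conservative, sparse networks. Candidate pairs are
pruned by sequence length alone — `|len(a) − len(b)| > t` already implies
the edit distance exceeds `t` — so the optimized construction is exactly
the brute-force graph, verified against an independent dynamic-programming
oracle in the tests. No approximate k-mer prefilter is used, precisely to
keep that equivalence exact. By default identical sequences collapse into
one node carrying their summed clone weight. Statistics (components,
largest-component fraction, mean degree, transitivity, degree histogram)
come from networkx. The CLI builds one network per sample by default,
`--pooled` for a joint one.

## Lineage reconstruction

The mutation kernel is Hamming for equal-length pairs (intraclonal
variants of a non-indel simulator are position-aligned by construction)
and Levenshtein otherwise; no multiple-sequence-alignment stage is run,
which is adequate for near-identical intraclonal variants but will
under-count around real indels. Germline inference takes a V/J reference
FASTA when available (segments chosen by fewest mismatches against the
modal member sequence over the aligned prefix/suffix window, concatenated)
and otherwise falls back to a per-position majority-rule consensus with
alphabetical tie-breaks, flagged as a proxy.

Trees are built by neighbor-joining over the unique variants plus the
germline: classical Q-criterion, ties broken on the smallest taxon-index
pair, negative branch lengths clamped to zero with the deficit moved to
the sister branch so the joined pair's distance is preserved. The
unrooted result is rooted at the germline node, which therefore appears
as the labelled root of the Newick output with deterministic sibling
order — identical inputs give byte-identical Newick. NJ was chosen over
parsimony/likelihood methods for determinism and speed at desk scale;
rooting on the germline terminal edge (rather than treating germline as
an outgroup only) makes root-to-tip path lengths directly interpretable
as mutation loads.

## Pseudobulk differential expression

Counts are summed over cells within each (sample × cluster) unit; units
under `min_cells` (default 10) are excluded with a log entry, and column
sums conserve the member cells' counts exactly. Per unit, counts are
normalized to counts-per-million (library size = unit column sum) and
transformed as log2(x + 1); per gene, Welch's unequal-variance t with
Welch–Satterthwaite degrees of freedom gives a two-sided p, and
Benjamini–Hochberg step-up FDR is applied across genes within one cluster
contrast only. Genes with zero counts in every unit are removed before
testing. Genes with zero variance in both groups get statistic 0 and
p = 1 when means agree. At least two replicate units per group are
required — with fewer there is no within-group variance to estimate.
Welch-on-log-CPM was chosen as a dependency-light, well-calibrated
baseline; negative-binomial GLMs with dispersion shrinkage are out of
scope, so power on low-replicate designs is conservative relative to
dedicated bulk RNA-seq packages.

## Simulator

The simulator is first-class code: it defines the conditions under which
every pipeline is validated.

* **Clone sizes**: Zipf(α), default α = 2.0 (heavy-tailed clonal
  expansion typical of immune repertoires), drawn until the cell budget
  is filled, the last clone truncated so sizes sum to `n_cells` exactly;
  or a uniform law for even repertoires.
* **Receptors**: a built-in synthetic pool of 10 V (~300 nt) and 5 J
  (~50 nt) segments per chain, generated once from a fixed internal seed
  so it is identical across runs and never downloaded. Each clone draws
  V and J per chain plus a random in-frame stop-free junction; the
  founder V+junction+J is the clone germline.
* **Mutation**: per cell and chain, Poisson(shm_rate × length)
  substitutions at distinct positions, each changing the base. Default
  shm_rate 0.005/site (a few mutations per chain, typical of early
  germinal-center output). Sampling positions without replacement
  sacrifices back-mutation realism but makes the ledger exact: the
  introduced count *is* the Hamming distance to germline, which is what
  turns downstream mutation counting into an exact test.
* **Isotypes**: multinomial, default {IGHM 0.5, IGHG1 0.25, IGHG2C 0.15,
  IGHA 0.1} — an unswitched-majority naive/early-response profile.
* **Expression**: negative-binomial (mean 5, shape 2 — overdispersed at
  the level of typical UMI counts) over 250 genes, with one 10-gene
  marker block per cluster shifted by 2^marker_log2fc (default +1 log2)
  in that cluster's cells, 3 clusters. This is deliberately minimal: it
  exercises pseudobulk aggregation and DE, not a full scRNA-seq
  simulator (no library-size gradients, batch effects, or zero-inflation
  beyond NB).

Outputs are a 10x-shaped contig CSV (with a non-standard `sequence_nt`
column, since the real annotation CSV carries no assembled sequence), an
AIRR TSV, a MatrixMarket triplet, a metadata TSV, and a JSON ground-truth
ledger; the same seed reproduces all files byte-identically.

What passing these tests shows: the algorithms are internally correct —
exact against closed forms, enumeration oracles, and the simulator's
ledger. What they do not show: robustness to real-data pathologies the
generator omits (indels, chimeric contigs, ambiguous V calls, doublets,
batch effects), which is why the filtering layer keeps its flags rather
than making silent decisions.

The power-law exponent estimator maximizes the zeta-normalized discrete
likelihood over α ∈ [1.01, 6] to 1e-6 (bounded Brent); inputs with fewer
than two sizes or non-positive sizes are rejected, and estimates at a
bracket edge or from a single distinct size trigger a non-power-law
warning.

## Problem sizes and numerical choices

The test suite validates on simulations of 300–2,000 cells, and the
acceptance script on 10,000-cell repertoires, 10,000-replicate
Monte-Carlo rarefaction, 200-node network oracles, and 2,000-gene null DE
— sizes at which every check runs in seconds while the stochastic bounds
(±0.02 isotype fractions, ±0.2 on α, 3 standard errors on rarefaction)
are tight. Tolerances: diversity closed forms to 1e-12; NJ path lengths
and Newick round trips to 1e-9; frequency tables sum to 1 within 1e-12.
All randomness flows through explicitly passed numpy Generators; nothing
seeds global state.

## Known limitations

* Clonotype homology clustering is O(n²) within a V/J/length bucket —
  fine for single-cell scale, not for bulk repertoires of millions.
* Lineage trees ignore indels' positional information (distance-only) and
  do no ancestral-state reconstruction or selection analysis.
* DE has no covariate adjustment; one contrast, two groups.
* The simulator's GEX realism is intentionally minimal (see above).
* Networks offer no community detection or layout; export to GraphML is
  the hand-off point to dedicated graph tools.
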