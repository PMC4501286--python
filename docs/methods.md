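# Methods

This note records the models, conventions and design choices behind
`epitopescan`, in the order data flows through the tool.

## Sequence ingestion

Proteomes are read from GenBank flat files (preferred) or protein FASTA.
From GenBank, one protein record is created per CDS feature; the identifier
is the `locus_tag` qualifier, falling back to `gene` and then to a generated
`CDS0001`-style id, so ingestion never fails on sparse annotation.  A CDS
without a `translation` qualifier is translated from its coding span with the
standard codon table (trailing stop stripped); only a CDS whose span is
invalid (not a codon multiple, internal stop) is skipped, with a warning.
Duplicate locus tags are a hard error — silently suffixing them would corrupt
downstream per-protein bookkeeping.  From FASTA, the id is the first
whitespace token of the header and the proteome is labelled `other` unless a
genome id is given; duplicate ids and characters outside the 20-residue
alphabet plus `X` are hard errors.

Prediction results use one standard table everywhere: `protein_id, method,
allele, start, peptide, score`, with 1-based starts and `peptide` occupying
residues `[start, start + len - 1]`.  Results persist as one CSV per
(protein, method) so a single protein's results load without scanning a run;
scores are serialized at full precision (`repr` round-trip), making
write→read the identity.

## MHC class II matrix scoring

The `tepitope` predictor scores every 9-mer of every protein against
per-allele 9×20 position-specific scoring matrices: the peptide score is the
sum of per-position residue scores.  Nine residues is the canonical MHC-II
binding-core length; the matrix text format nevertheless carries an explicit
length so other core lengths parse.  `X` (unknown residue) scores 0 at any
position — a neutral, documented convention that keeps proteome scans total.
Raw matrix sums are reported without rescaling; calibration is the threshold
module's job, which only needs scores to be comparable within one allele.

Matrices are runtime data, not package data: the loader accepts plain-text
tables (`#allele <name> n <length>` header, rows of 20 cells in the fixed
residue order `ACDEFGHIKLMNPQRSTVWY`), so published TEPITOPE-style
pocket-profile matrices can be dropped in as files.

## B-cell propensity scoring

The `bcell-scale` predictor averages a 20-residue propensity scale over a
sliding window (default 7, the common choice for hydrophilicity-type scales;
must be odd).  The score is assigned to the *window start*, not its centre,
so all predictors share one positional convention.  `X` contributes 0 to the
window sum while the divisor stays the full window length — a window of
unknowns is scored 0 rather than dropped.  Proteins shorter than the window
are skipped with a warning.

## Predictor contract

Every predictor — built-in or an adapter around an external tool — is a
`PredictorSpec`: a name, a peptide length, an allele list and a
`predict(proteome, alleles)` callable that emits the standard table with its
own name in the method column.  Downstream analysis never inspects which
predictor produced a table; the test suite exercises a mock adapter through
thresholding and promiscuity to enforce this.  Executing external binaries is
out of scope — only the contract is provided.

## Proteome-wide thresholds

For each allele, scores are pooled across the entire proteome and the binder
cutoff at level *t* is the empirical quantile at fraction `q = 1 - t/100`,
with linear interpolation between order statistics (with N sorted scores and
`h = (N-1)q + 1`, the cutoff is `x_⌊h⌋ + (h-⌊h⌋)(x_⌊h⌋+1 - x_⌊h⌋)` — the
"type 7" estimator, the numpy default).  Pools larger than `sample_cap`
(default 1,000,000 scores per allele) are reduced by seeded uniform
subsampling, keeping calibration reproducible at any proteome size.
Selection is inclusive (`score ≥ cutoff`): ties err toward discovery, which
is the right direction for a screening tool.  Cutoffs are non-increasing in
*t* and the binder set at a smaller *t* is always a subset of the set at a
larger *t*; both laws are property-tested.

## Promiscuity, clusters, rankings

Promiscuous binders group threshold-passing rows by *(protein, start,
peptide)* — position-resolved, so the same peptide string at two loci counts
twice, matching a per-protein track view — and keep groups hit in ≥ *k*
distinct alleles, with the mean score taken over qualifying alleles.

Clusters chain a protein's promiscuous binders in start order: a binder joins
the open cluster when the gap between its start and the running span end is
≤ *g* residues, where binders occupy `[start, start+8]`.  For 1-D intervals
this single-linkage sweep is exactly connected-component clustering of the
"gap ≤ g" interval graph (verified against an exhaustive oracle).  Defaults
`g = 10`, `m = 3`: overlapping 9-mers chain naturally while isolated pairs
are not called clusters; both are CLI flags.  Density is binders per spanned
residue, in (0, 1].

Protein rankings report promiscuous binders per 100 residues (a readable
unit for proteins of typical bacterial lengths), cluster counts and peak
cluster density; proteins with no binders still appear with zeros.

## Conservation

Ortholog sets are supplied as FASTA (the query itself identified by
`--query-id`); retrieval from remote BLAST services is deliberately out of
scope so the tool runs offline and deterministically.  Subjects are
deduplicated (first occurrence kept) and gated by global percent identity to
the query — computed over a global alignment with BLOSUM62 scores and affine
gap penalties, open −11 applied to a gap's first residue and −1 to each
extension, counting gap columns in the alignment-length denominator.  The
identity gate is inclusive (≥).

Epitope matching is *ungapped*: the best window of the epitope's length in
each subject, scored as matching residues over epitope length.  For 9–15-mer
epitopes gapped matching adds parameters without adding signal, and the
ungapped rule is deterministic and oracle-checkable
(`best identity = 100 ⟺ the epitope is a substring`).  Conservation at
identity level *v* is the fraction of filtered subjects with best window
identity ≥ *v*; the default level grid is 0, 5, …, 100 %.  The query is not
counted in the denominator unless it also appears among the subjects.

## Synthetic data

The generators emulate the inputs the analyses consume, and they are what
the test suite and the acceptance script measure against:

* **Random proteomes** — i.i.d. residues from a 20-vector of frequencies
  (uniform by default), lengths uniform on a range (default 100–500, typical
  of bacterial proteins; minimum 9, the scan window).  Default study size 50
  proteins.
* **Planted motifs** — a 9-mer written over non-overlapping random positions
  of chosen carrier proteins (default 3 copies per carrier), with the true
  positions returned/written as a truth table.  Paired with matrices whose
  motif cell is set just above each row's background maximum (margin 0.1),
  which makes the motif the strict top-scoring peptide while leaving
  partial-motif peptides inside the background score range.
* **Simulated orthologs** — i.i.d. per-site substitution of a query at rate
  μ (default 0.05), each substituted site drawn uniformly from the 19 other
  residues.  Under this model a fixed *n*-mer is unmutated in a subject with
  probability (1−μ)ⁿ, giving closed-form expectations for parameter-recovery
  tests (e.g. conservation ≈ 63 % at the 100 % level for n = 9, μ = 0.05).

What these fixtures do *not* emulate: real proteomes are not i.i.d. (domain
structure, composition bias, low-complexity regions), real binding matrices
have correlated pocket preferences, and real strain variation is neither
site-independent nor uniform over residues (indels, hypervariable regions).
Passing tests therefore demonstrate the *machinery* — scoring, calibration,
counting, ranking, conservation arithmetic — not predictive accuracy on real
antigens, which is entirely inherited from the matrices and scales the user
supplies.

## Numerical choices and degenerate inputs

Scores are float64 throughout; test comparisons use 1e-12 relative tolerance
for scoring identities and 1e-9 for quantile-oracle agreement.  Sequences
shorter than the scan window yield zero rows (a warning where a caller could
be surprised).  An empty result table round-trips as zero files.  All
randomness flows through explicit integer seeds (`numpy.random.default_rng`);
there is no global random state.  Determinism of every CLI command given
(inputs, config, seed) is tested bytewise.

## Problem sizes

The shipped test-suite and acceptance-script runs use 50-protein proteomes
(lengths 100–500) with 3 alleles and 10–20 replicate seeds for
planted-signal recovery, 500 simulated subjects for conservation recovery,
and 100–200 random instances per oracle-equivalence property — sizes at
which the binomial acceptance bands (3 standard errors) are tight enough to
detect real defects while a full run stays in the tens of seconds.

## Known limitations

* Only matrix- and scale-based predictors are built in; neural-network, HMM,
  proteasome-cleavage, TAP and TCR models are not implemented (the adapter
  contract is the extension point).
* Ortholog retrieval, taxon-restricted queries and e-value filtering are the
  user's responsibility; the identity filter is the only in-scope gate.
* Per-residue conservation breakdowns are not produced — only per-epitope
  fractions and curves.
* Cluster detection operates on promiscuous binders, not on all
  threshold-passing binders; with `k = 1` the two coincide.
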