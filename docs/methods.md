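# Methods

## Data model

The pipeline's primary measurement is the per-run isotopic-label ratio of an
endogenous plasma peptide in a post-induction group (1 h, 3 h, 6 h, 12 h,
24 h) versus a common control channel. Ratios arrive pre-normalised from the
search engine; the control group is implicit with ratio 1 and never appears
as a group row. Unidentified runs carry presence/absence information only:
they enter the run-frequency statistic (percent of a group's MS runs in
which the peptide sequence was identified) but contribute no ratio. Peptide
sequences are uppercased on ingest and I/L ambiguity is not collapsed, since
distinct I/L-variant peptides from different actin isoforms are biologically
distinct here. All term and gene identifiers are opaque strings; no online
identifier mapping is attempted — offline files are the contract.

## Differential-regulation screen

Each (peptide, group) cell with at least one identified observation is
tested with a two-sided one-sample Wilcoxon signed-rank test against the
null effect of 1. Deviations are taken on the log scale by default
(`test_scale="log_ratio"`): multiplicative ratio noise is symmetric around 1
on the log scale, which makes the null exactly location-zero and gives the
exact reciprocal symmetry — replacing every ratio $r$ by $1/r$ flips up and
down calls and preserves the p-value bit-for-bit. The raw-ratio scale is
available for users who want the literal convention.

The exact null distribution is used whenever the effective sample size is at
most 25 and zero handling permits. Ties among absolute deviations are
handled exactly as full sign-assignment enumeration would: midranks are
doubled to integers and the distribution of the positive-rank sum is built
by subset-sum dynamic programming, so the exact path covers tied data too
(e.g. n identical ratios give $p = 2/2^n$). Beyond n = 25, or under the
Pratt zero policy with zeros present, the normal approximation with tie and
continuity correction (scipy) is used. Observations exactly at the null are
dropped before ranking by default (classic Wilcoxon); the Pratt method is
available. All-null cells return p = 1 with zero effective observations.

A cell is called **up** when the group median ratio is $\ge$ `fold_up`
(default 2.0, inclusive) and $p \le \alpha$ (default 0.05); **down** when
the median is $\le$ `fold_down` (default 0.5, inclusive) and $p \le \alpha$;
otherwise unchanged. The group center is the geometric median under the log
scale — exp of the median log-ratio, i.e. the geometric midpoint of the two
central order statistics for even n (median of {2, 8} is 4, not 5) — which
is the convention consistent with the reciprocal symmetry above. No
multiple-testing correction is applied by default, mirroring the raw
$p \le 0.05$ reporting convention of the screen; per-group
Benjamini–Hochberg adjustment is available (`multiple_testing="bh"`).

A note on sample size: with five tie-free same-sign observations the exact
two-sided minimum p is $2/2^5 = 0.0625 > 0.05$, so a five-animal group can
only reach significance through multiple MS runs/labels per animal. The
synthetic generator therefore defaults to 10 observations per group.

## SLiM scanning and selection

Motifs are ELM-style entries: a regex pattern over the amino-acid alphabet,
a class code (LIG, DOC, MOD, DEG, TRG, CLV), annotated-instance taxa and
associated pathway terms. The supported pattern dialect is the subset shared
by POSIX ERE and ELM patterns — character classes, quantifiers, anchors,
alternation — with no backreferences. Scanning enumerates **all** match
start positions including overlaps (the scan restarts one residue after each
match start), with 1-based inclusive peptide-local coordinates. Selection
keeps motifs of the docking and ligand classes with an annotated *Mus
musculus* instance (both configurable) that matched at least one regulated
peptide of the comparison; matches are pooled across the comparison's
regulated peptides and deduplicated to a presence/absence set, because the
downstream question is which SLiMs are represented, not how often.

## SLiM over-representation

The reference universe is the set of class/taxon-filtered motifs annotated
to at least one pathway term — not the full motif database — so the test
asks about over-representation within the annotatable, filter-passing
reference. Per term, the 2×2 table (selected/annotated) is tested with
Fisher's exact test, one-sided for enrichment by default ($p =
\sum_{k \ge a} P[K=k]$ under the hypergeometric null); two-sided is a flag.
The magnitude is the sample odds ratio $ad/bc$; when any cell is zero the
Haldane–Anscombe correction adds 0.5 to every cell and the result is
flagged, keeping magnitudes finite for bubble-plot reporting. The simple
sample estimator is preferred over the conditional MLE as the plain reading
of "odds ratio" and because its zero-cell-corrected form is monotone and
bounded. Reporting marks, per comparison, the five lowest-p significant
terms (ties broken by larger odds ratio, then term id); no multiple-testing
correction by default, BH optional.

## Active subnetworks

Each gene encoding the source protein of at least one regulated peptide in
a comparison becomes a seed with p equal to the minimum peptide p-value and
node score $z = \Phi^{-1}(1-p)$, clamped to $|z| \le 10$ to avoid
infinities; genes absent from the input score 0. From each significant seed
a deterministic greedy search grows a connected set, at each step absorbing
the neighbour that maximises $\sum z_i / \sqrt{k}$ and stopping when no
single addition strictly improves the score; ties break by higher z, then
lexicographic symbol. This replaces the genetic/simulated-annealing searches
of interactive active-subnetwork tools with a reproducible procedure that an
exhaustive connected-subgraph oracle can bound on small graphs — a
deliberate simplification, adequate for seed sets of a handful of genes, and
knowingly suboptimal on bridge topologies where a zero-scoring connector
separates two high-scoring nodes (documented in the test suite).

Resulting subnetworks are deduplicated by gene set and their union forms the
enrichment query: per pathway term of size K in a background of N genes
(default: the PIN node count), the overlap k out of the query size n is
tested with the hypergeometric upper tail and reported as fold enrichment
$(k/n)/(K/N)$, with the same background in test and magnitude. Terms
overlapping fewer than two query genes are dropped. The reported support
count is the number of original input (regulated-peptide) genes in the term,
distinct from the overlap used in the test.

## Synthetic data

The generators emulate the statistical shape of the study inputs, not the
spectra: ratios are direction-median × $e^{N(0,\sigma)}$ (log-normal
multiplicative noise, the standard model for MS ratio data) with defaults
up-median 4.0, down-median 0.25, null 1.0, $\sigma = 0.15$ and 10 runs per
group. Under these defaults a planted 'up' cell has practically unit
probability of passing both gates (the median of 10 log-normal draws around
log 4 sits ~11 noise-SDs above the log 2 threshold, and 10 same-sign
deviations give exact $p = 2/2^{10} \approx 0.002$), so the packaged
direction pattern — ten peptides from eight proteins, regulated counts
1/1/4/8/4 across the five time points — is recovered essentially always.
Motif databases plant literal-substring motifs (guaranteed hits) among
random 5-mer decoys whose per-peptide hit probability is well under 5%;
networks plant a clique module in an Erdős–Rényi background (edge
probability 0.05) with spanning-tree augmentation guaranteeing
connectivity. All generators are pure functions of their seed.

What passing tests on these data do **not** show: real plasma peptidomics
has run-to-run normalisation structure, missingness correlated with
abundance, shared variance between peptides of one protein, and motif/term
annotations with heavy overlap — none of which the generators model. The
planted-recovery results demonstrate correctness of the inference chain, not
field performance on real LC-MS/MS output. Pathway identities reported on
synthetic bundles are labels of planted structure, not biology.

## Numerical choices and scale

Exact-vs-approximate switch at n = 25; p-values clamped to (0, 1];
frequency percentages computed over distinct run ids; even-n medians by the
geometric midpoint (log scale) or arithmetic midpoint (ratio scale);
deterministic sort orders on every output table so identical configurations
reproduce byte-identical files. Test-suite oracles run at deliberately small
sizes — 2^n sign enumeration up to n = 12, exact rational hypergeometric
tails up to N = 60, exhaustive connected-subgraph search up to ~10 nodes,
and 20-seed recovery sweeps on 40-node networks with 60-motif databases —
sizes at which brute force is feasible while still exercising every code
path of the production implementation.

## Known limitations

- The greedy subnetwork search is not globally optimal (see above); scores
  are upper-bounded by the exhaustive oracle only on small graphs.
- The SLiM→term reference mapping is taken as an input file; the pipeline
  does not construct it from instance proteins' pathway memberships.
- No ELM probability, conservation or disorder-context filtering of motif
  matches; a regex hit on a short peptide is weaker evidence than a full
  ELM prediction.
- Frequency emulation matches per-peptide mean identification rates only,
  not their group-wise dispersion.
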