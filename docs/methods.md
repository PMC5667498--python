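# Methods

## The dating model

The clock assumes a provirus integrates with identical LTR copies and that
both copies (and the internal genes) subsequently evolve neutrally at a
constant rate `r` (default 0.2 %/nt/My, the human neutral substitution rate).
Ages are linear transforms of divergence: `T = D%/r` for comparisons against a
group majority-rule consensus (the consensus approximates the ancestral state,
and only the member's branch accumulates changes) and `T = D%/r/2` for the
5'LTR-vs-3'LTR comparison, because there both copies accumulate changes.
The halving is applied by `age_from_ltr_pair` and is switchable
(`--halve-ltr/--no-halve-ltr`): published per-locus LTR-pair ages in this
domain are sometimes reported on the unhalved scale — the packaged reference
age table is internally consistent only on that scale (its LTR-column mean of
17.9 My times 0.2 equals the quoted 3.6 % mean divergence with no factor of
2) — so the conversion is explicit, not hidden.

Divergence measurement:

* **p-distance with pairwise deletion.** Columns with a gap or `N` in either
  row are excluded; `D% = 100 · mismatches / sites_used`. Zero usable sites is
  an error (`UndefinedDistanceError`), not a zero.
* **CpG masking.** Methylated CpG dinucleotides deaminate to TpG/CpA far above
  the neutral rate, inflating D. Before measuring, any C followed by G in
  *either* row (adjacency judged on each row's non-gap residues, so gaps do
  not hide a CpG) has both columns replaced by `N` in both rows. Masking both
  rows at sites flagged by either member is deliberately conservative; a
  consensus-defined mode can be had by masking against the consensus row only.
* **Bootstrap dispersion.** Alignment columns are resampled with replacement
  (default 1000 replicates, seeded); the SD of replicate `D%` values is the
  component's dispersion. A component is excluded from the per-locus mean when
  its coefficient of variation `sd/D` exceeds `cv_threshold` (default 0.20).
  A relative threshold is used because an absolute 20-point SD would never
  trigger at single-digit divergences. A locus with every component excluded
  is flagged undatable rather than raising.
* **Majority-rule consensus.** Per column the most frequent symbol among
  `{A,C,G,T,-}` wins; `N` never wins; gap-majority columns are dropped, so the
  consensus is ungapped. Ties break alphabetically (A<C<G<T), with letters
  beating the gap — a deterministic convention, nothing more.
* **Partial-gene windows.** Consensus comparisons of *pol* and *env* are meant
  for the conserved windows on the reference frame (1277–2571 and 4103–5810);
  the pipeline's simulated gene alignments are cut from the feature map
  directly, and external alignments should be windowed the same way.

Reported ages are rounded half-up to 1 decimal at the table boundary
(`round1`); full precision is carried internally.

## The simulator, and what it does and does not emulate

`default_template()` builds a 6358-nt provirus on the group reference frame:
5'LTR 1–548 and an identical 3'LTR 5811–6358, gag 698–1314, pol 1316–3786,
env 3801–5780, a lysine PBS at 552–569 (3 nt after the LTR), a polypurine
tract at 5786–5798, and TATA/SV40-enhancer/PolyA motifs at their reference
offsets inside both LTRs. Background composition is A-biased
(A 33 / T 28 / C 21 / G 18 %), matching the group's purine skew. Subtype I
templates carry a ~70 %-AT stretch in the pol-3'/env-5' window (3159–4130);
subtype II templates have ordinary composition there. The template is a
deterministic constant (fixed internal seed), so fixtures are reproducible.

The clock substitutes each site independently with probability
`p = 1 − exp(−(r/100)·t)` — a Poisson process thinned to at most one realized
substitution per site — choosing uniformly among the three alternative bases.
With `cpg_multiplier > 1` the scan runs 5'→3' on the current sequence and the
deamination target (C→T on the C of a CpG, G→A on the G) has its per-target
probability multiplied, capped so totals stay below 1. Indels (off by
default) have geometric lengths with mean 3 and are recorded in the
ground-truth pairwise alignment, whose coordinate maps satisfy
template→mutant→template identity away from indels.

Consequences worth knowing:

* **The linear estimator is slightly downward-biased.** Two independently
  mutated copies coincide at a site with probability `p²/3`, so the expected
  inter-LTR p-distance is `2p(1−p) + (2/3)p² = 2p − (4/3)p²`, not `2rt`. The
  mean halved LTR-pair estimate is therefore ≈ 9.8 My at a true age of 10,
  ≈ 19.1 at 20, and ≈ 32.3 at 35: the bias grows quadratically and passes 1 My
  between 20 and 25 My of true age. This is a property of the `T = D/r/2`
  estimator itself (no multiple-hit correction), faithfully reproduced — not a
  simulator artifact to be calibrated away.
* What the simulator does **not** model: selection, rate heterogeneity across
  lineages or sites (beyond CpG), recombination between non-identical
  proviruses (solo-LTR formation is the only recombination product), ancestral
  polymorphism, or gene conversion between LTRs. Passing the recovery tests
  therefore shows the estimators are correct under their own assumptions, not
  that real loci meet those assumptions — the published table's LTR-vs-LTR
  ages running ~15 My younger than consensus-based ones is exactly such an
  assumption failure.
* The indel process is a plain stand-in (no empirical length spectrum) and is
  excluded from dating validation; dating tests run substitution-only.

`simulate_locus_set` places events on chromosomes with probability
proportional to length times an optional per-chromosome enrichment
multiplier; solo LTRs are emitted as single-LTR records (the internal region
between the LTR copies deleted by recombination). `simulate_msa_from_consensus`
mutates a consensus to requested expected p-distances (valid below the 0.75
saturation bound) and records realized distances.

## Distribution statistics

Expected counts are `E_c = L_c · N / ΣL`. The overall test is
`X² = Σ(O−E)²/E` with `df = k−1` and an upper-tail chi-square p-value;
chromosomes with zero expectation are excluded with a warning and the df
adjusted. Per-chromosome tests use the 1-df two-cell partition
`{c, all others}` — an explicit construction choice, exposed in the output —
with no continuity correction by default and no multiple-testing correction
(a Bonferroni option exists). Calibration checks use 500 insertions per
simulated set so the smallest GRCh37 chromosome's expectation stays above 5,
the standard validity rule for the chi-square approximation. Duplicated loci
sharing one ancestral integration can be collapsed to a single event via a
name-mapping argument.

## Phylogenetics

K2P distance: with transition proportion `P` and transversion proportion `Q`
over pairwise-deleted sites, `d = −½·ln((1−2P−Q)·√(1−2Q))`; a non-positive
log argument raises a saturation error naming the pair. Neighbor-Joining
follows Saitou–Nei: join the pair minimising
`Q(i,j) = (n−2)·d(i,j) − r_i − r_j`, allocate pendant lengths
`l_i = d/2 + (r_i−r_j)/(2(n−2))`, reduce with
`d(u,k) = (d(i,k)+d(j,k)−d(i,j))/2`. Ties (within 1e-12) break on the
lexicographically smallest pair of node labels, internal nodes carrying the
smallest leaf label beneath them, so output is platform-independent and
taxon-order-independent. Negative branch lengths are reported raw in a
diagnostics list and clamped to zero only on Newick output. Bootstrap
resamples alignment columns (not distance entries), rebuilds the tree per
replicate, skips (and counts) replicates with saturated pairs, and annotates
each internal edge of the full-data tree with the percentage of successful
replicates containing the same bipartition. Cluster membership assigns each
query to the exemplar set with which it forms a supported monophyletic group
(both sides of every supported edge are candidate groups; smallest wins;
default threshold 70).

## Motif scanning

Protein patterns use the Betaretroviral definitions — dUTPase `DSDYxGEIQ`,
Gag NC zinc finger `C-x2-C-x4-H-x4-C`, G-patch `GY-x2-G-x-GLG-x4-G-xn-G` —
with `x` any residue except a stop and the G-patch run bounded to n = 1–15
(configurable; unbounded would be degenerate). Overlapping hits are all
reported; nucleotide input is translated in the three forward frames (a
both-strands flag exists). PBS detection reads a window 3 nt after the 5'LTR
end at lengths 17–19, scoring ungapped identity at 18 and best single-indel
identity at 17/19 against each library entry; maximal identity wins, ties
going to the earlier library entry and the indel-free length. The packaged
library is a small synthetic stand-in (lysine entry first, plus decoys) —
any TSV with `trna`/`pbs` columns can replace it, and the identity score is
always reported alongside the call. A/T-rich stretches are maximal merged
runs of qualifying fixed-length windows (defaults: 800 nt, ≥0.67 AT); in the
rare case a merged union dips below threshold, the best single window is
reported so every output interval satisfies the threshold. Subtype calls read
the 3159–4130 reference window: ≥600 unambiguous bases at ≥0.67 AT → type I,
otherwise type II, window absent → unassigned (thresholds chosen from the
67–73 % range over ~830 nt reported for this family, with slack for noise).
ORF integrity walks a codon-aware pairwise alignment in the reference frame:
stop codons before the final reference codon are internal stops (reported by
residue), gap runs of non-multiple-of-3 length are frameshifts (reported at
the preceding codon boundary), and `intact` means neither occurred.

## Numerical and interface conventions

Coordinates are 1-based fully inclusive everywhere; en dash and hyphen both
parse as coordinate separators and thousands separators are stripped; strand
is metadata (explicit `reverse_complement` only). `N` counts as missing data
and is excluded by pairwise deletion. All randomness flows from explicit
seeds; the pipeline derives per-stage seeds from one run seed via
`SeedSequence` spawn keys, and reruns are byte-identical. Tables are TSV,
trees Newick, summaries JSON.

## Known limitations

The chromosomal-distribution module models length-proportionality only — no
gene density, recombination rate or insertion-site preference. The dating
module offers no maximum-likelihood or Bayesian alternative and no rate
calibration from outgroups. The phylogeny module is distance-based NJ only.
The PBS library and the provirus template are synthetic stand-ins for
unpublished reference resources; analyses of real loci should supply their
own library and alignments.
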