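# Methods

## Model and assumptions

The encoder treats a protein family as a bag of conserved substrings
(motifs) and a substitution matrix as the complete description of which
residue replacements are tolerated. Three quantities are derived from a
20×20 integer matrix `S`:

* **Residue conservation** `P(x) = S(x,x) / Σ_{y: S(x,y)>0} S(x,y)`.
  "Positive" means strictly `> 0`; zero scores contribute nothing to the
  denominator. Under BLOSUM62 exactly C, G and P have `P(x) = 1` (their
  rows have no off-diagonal positive entry; H and W do not qualify — they
  gain positives from N/Y and F/Y respectively).
* **Motif mutation probability** `P_m(M) = 1 − Π P(M[i])`, the chance
  that at least one position mutates. It lies in `[0, 1)` and is 0 iff
  every residue of the motif is fully conserved.
* **Substitution probability** `SP(M, M') = S_m(M, M') / S_m(M, M)` with
  `S_m` the positionwise score sum. Normalising by `S_m(M, M)` (rather
  than `S_m(M', M')`) makes every motif its own best substitute with
  `SP(M, M) = 1`; both normalisations reproduce the worked clustering at
  T = 0.5, and this one was chosen because self-substitution being
  maximal is the property the calculus leans on.

`M` can substitute `M'` iff the lengths agree, every positionwise score
is ≥ 0, and `SP(M, M') ≥ T`. Note the relation is not symmetric in
general (the denominator differs), which is why a motif can be absorbed
by one cluster while heading another.

## Clustering and filtering

Motifs are sorted descending by length, then by `P_m`, ties broken
lexicographically (ascending) for cross-platform determinism. Each motif
is assigned to the candidate substitute with the highest `P_m`, the
candidate set always containing the motif itself so the assignment is
total; equal `P_m` again resolves to the lexicographically smaller
motif. Clusters are the fibers of this assignment with the main motif
always included as a member. Filtering retains the distinct main motifs
in sorted order. Two guarantees follow and are property-tested: the
retained set is never larger than the input, and every removed motif is
substitutable by some retained main motif (so the substitute-aware
context loses no presence information).

The implementation is the direct O(n²·k) candidate scan; an exhaustive
enumeration oracle checks it on random motif sets up to n = 10.

## Parameters

| parameter | meaning | default | note |
|---|---|---|---|
| matrix | substitution matrix | BLOSUM62 | the matrix most alignment tools default to |
| T | substitution probability threshold | 0.9 | worked examples use 0.5; any T ≤ 5/9 reproduces the nine-motif example |
| α | minimum within-family containment rate of a DD feature | 0 | coverage condition |
| β | maximum containment rate in any other family | 0 | exclusivity; β = 1 disables the cross-family check entirely |
| N | N-gram length | 3 | |
| min_length / max_length | repeat length bounds for DD | 3 / 10 | repeat = substring present in ≥ 2 distinct sequences of a family (≥ 2 occurrences for a single-sequence family) |
| activity % | Active-Motif sequence-match fraction | 25 | matching is Hamming-only (no indels) |
| feature cap | hard limit on generated features | 200 000 | exceeded → explicit "too many attributes" error rather than truncation |

Probabilities compared at printed precision are **truncated** (floored)
to two decimals, not rounded: 0.87654 prints as 0.87.

Characters outside the 20 standard residues (B, Z, X, U, \*) act as motif
separators everywhere: no extracted motif, window or match spans one.
Matrix files bundle the NCBI rows for B/Z/X/\* but those are dropped at
parse time.

## Synthetic data generator

`generate_fixture` emulates a set of distinct, distant families: uniform
random background residues with one or more family-specific motifs
implanted in every sequence at random positions (disjoint blocks when a
family has several motifs, so implants never overwrite each other).
Background strings are rejected if they contain any family's implanted
motif, making implants family-exclusive by construction. A fraction
`variant_rate` of implants is replaced by a variant drawn from a small
per-motif pool (default 2 variants, sampled once), each variant built by
substituting positions with non-negative scores and accepted only if the
original can substitute it at the configured T; an impossible request
(e.g. a motif of fully conserved residues at high T) raises. Pooling
matters: a substituted form of a conserved pattern recurs across family
members in real data, and only recurring variants can become repeats for
the DD miner to find.

What the fixtures do **not** emulate: realistic residue composition
(uniform background, not Robinson–Robinson frequencies), length
variation, indels inside motifs, overlapping or gapped patterns, and
shared homology between families. Passing fixture tests therefore shows
the pipeline's mechanics (recovery, collapse, coverage) — not
classification performance on real protein families.

The feature-collapse demonstration (variant rate 0.5 → DDSM features <
DD features) extracts repeats at the implant length (min = max = 6) with
10 sequences per family: at the default min_length = 3, minimality keeps
3-mers from different positions of the implant, and two 3-mers differing
at a substituted position need not pass the threshold at T = 0.8. The
condition was fixed after checking it holds across 30 generator seeds.

## Evaluation baselines

MAV (minimum accepted value) is the majority-class accuracy, truncated
to one decimal. The reference classifier for contexts is a deliberately
plain leave-one-out 1-nearest-neighbour on binary vectors (Hamming or
Jaccard distance), ties broken toward the earlier instance in input
order so repeated runs are bit-identical. It exists to compare encodings
under a fixed, deterministic learner — not to reproduce any particular
classifier's published accuracies, which depend on external datasets and
tool internals and are out of scope here.

## Numerical and design choices

* All score arithmetic is exact integer; probabilities are IEEE doubles
  formed from small integer ratios, so equality tests against closed
  forms like 5/9 are safe with standard float tolerance.
* Repeat extraction grows candidates length by length with apriori
  pruning (every substring of a repeat is a repeat) instead of the
  classical label-doubling scheme; an oracle test pins it to brute-force
  substring enumeration. Active-Motif extraction enumerates observed
  substrings rather than building a generalized suffix tree, equally
  pinned to brute force.
* ARFF output encodes presence as nominal `{0,1}` attributes (not
  numeric) with the class as the final nominal attribute; round-trips
  are verified with an independent ARFF parser. CSV follows RFC 4180.
* Test contexts reuse the learning context's frozen feature list; motifs
  unseen at training time are ignored.
* Problem sizes throughout the tests and examples (2–3 families, 5–10
  sequences of ~60 residues, 6-residue implants) are desk-scale choices
  that keep every oracle comparison exhaustive and exact.

## Known limitations

* Clustering is exact and quadratic in the motif count — appropriate for
  the tens-of-thousands range the feature cap allows, not for millions.
* Mutation-tolerant Active-Motif matching is substitution-only; indels
  would require edit-distance matching.
* The worked-example motif RF: its published mutation probability (0.72)
  disagrees with the definition, which gives 0.625 — the printed value
  duplicates RV's and is treated as a transcription slip. Its cluster
  assignment (main motif RI) is unaffected and is reproduced.
* The DD discrimination semantics (coverage ≥ α inside, ≤ β outside,
  then substring-minimality) and the repeat definition are fixed,
  documented choices; alternative readings exist and would change
  attribute counts on real data.
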