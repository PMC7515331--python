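# Methods

`apchip` implements clustering-based planted (l, d) motif discovery for
ChIP-Seq peak sets: given t DNA sequences of which q carry an approximate
copy (≤ d substitutions) of an unknown length-l motif, report the motif as
a PWM/consensus together with its occurrences. The pipeline has four
stages: probabilistic threshold selection, cluster-subset construction and
filtering, cannot-link-constrained affinity propagation, and
information-content ranking with consensus refinement.

## Model and assumptions

* **Background** is i.i.d. uniform over {A, C, G, T}; the chance that two
  unrelated l-mers mismatch at a given position is 3/4. All closed forms
  below assume this. GC-biased or Markov backgrounds are out of scope; the
  empirical base composition of the input is however used as the PWM
  background for information content.
* **Instances** are copies of the motif in which d designated positions
  were redrawn uniformly over the four bases, so the realised mutation
  count is Binomial(d, 3/4) and any two instances of one motif are within
  Hamming distance 2d of each other. The simulator implements exactly this
  law (a "uniform over the radius-d ball" alternative exists for
  sensitivity checks).
* **ZOOPS occupancy**: q of the t sequences carry exactly one instance;
  the remaining sequences are pure background. α = q/t.

## Threshold calculus (`apchip.probability`)

Three closed forms drive the thresholds:

* `background_neighborhood_prob(l, k)` = Σ_{i≤k} C(l,i)(3/4)^i(1/4)^{l−i},
  the chance two random l-mers lie within Hamming distance k. Evaluated
  with exact integer binomials (no overflow to l ≈ 30). `p2d` — the same
  quantity at k = 2d — grades instance difficulty: weak instances (large
  p2d) have background l-mers that mimic instances.
* `motif_pair_prob(l, d, k)` — the chance two instances of one motif lie
  within k. The default `model="overlap"` conditions on the realised
  mutation counts (α, β) of the two instances and scores "within k" by a
  hypergeometric overlap sum (overlap > ⌊(α+β−k)/2⌋ of the two mutated
  position sets); this is the form whose published threshold table we
  reproduce digit-for-digit. It slightly understates the true probability
  because it treats overlapping mutations as always cancelling;
  `model="exact"` additionally conditions on character agreement at
  overlapping positions (probability 1/3 each) and is the law validated
  against Monte-Carlo simulation in the test suite (e.g. at l=18, d=5,
  k=7 the two give 0.7414 vs 0.7623).
* `occurrence_frequency(l, d, p_mut)` — the chance a random sequence
  position carries a degenerate motif occurrence; `p_mut` defaults to d/l,
  the expected per-position mutation rate of an instance. Two readings of
  the published expression are implemented; the default "neighborhood"
  reading Σ_i Binom(i; d, p_mut)·C(l,i)3^i/4^l keeps the derived
  per-sequence hit threshold max(1, ⌈p_occf·(n−l+1)⌉) in a usable range
  (the "literal" reading has a dominant (1−p_mut)^d term whose threshold
  exceeds any attainable hit count; it is retained behind a mode switch).

**Radius selection.** `choose_k` returns the smallest k in (d, 2d] whose
pair probability reaches a floor (default 0.7), the smallest radius that
still captures most instances — for (18, 5) this yields k = 7. The
pipeline additionally raises the floor to (q−1)/(t−1) so that the expected
number of supporting sequences, (t−1)·pk_motif + 1, reaches q; with full
occupancy (q = t) this forces k = 2d, the only radius at which a
true-instance reference is guaranteed to capture every other instance.
Without this raise, the support filter below rejects true references with
probability ≈ 1 − pk_motif^{t−1} and the search returns nothing at q = t.
`support_aware_k=False` restores the bare floor; `k=` overrides outright.

## Candidate generation (`apchip.candidates`)

Every l-mer of the first h = t − q + 1 sequences is a reference (under
ZOOPS at least one of them is a true instance); duplicates by text are
skipped. The cluster subset of a reference holds all l-mers of the other
sequences within radius k, found by a vectorized mismatch scan over
2-bit-encoded windows (positions containing non-ACGT characters are masked
out of enumeration; sequences shorter than l contribute nothing). A
sequence supports the reference when it contributes at least the
occurrence threshold of members (evaluated with that sequence's own length
when lengths differ, as in real peak sets); a subset becomes a candidate
when at least q sequences — counting the reference's own — support it.
The reverse strand is ignored by default; `both_strands=True` also tests
each window's reverse complement and records flipped members.

## Constrained affinity propagation (`apchip.ap`)

Similarity between two cluster-subset members is −ρ·d_H with ρ = R1 on
distances in (0, k] and ρ = R2 on (k, 2k] (published ranges R1 ∈ (1, ∞),
R2 ∈ (0, 1]; defaults 2.0 and 1.0; the larger weight on the *closer* band
is as published). Same-sequence pairs — and the unreachable (2k, 4k]
band — receive a finite "forbidden" sentinel 10^6 times the largest finite
magnitude, the cannot-link constraint that enforces one occurrence per
sequence; keeping it finite keeps message arithmetic finite while the pair
can never win an argmax.

Messages follow the standard responsibility/availability recursion with
damping λ = 0.9 (synchronous updates, new = λ·old + (1−λ)·update), at most
1000 iterations, terminating when the exemplar decision vector has been
stable for 50 consecutive iterations *after* at least one exemplar has
emerged (under heavy damping the all-negative transient would otherwise
satisfy any stability window). The shared preference is the median of the
finite similarities; `"min"` or a number gives coarser/finer partitions.
No random jitter is used: a deterministic preference tilt of relative size
10^-8, decreasing with point index, breaks the exact symmetry of duplicate
points (which otherwise pins every r+a diagonal at zero) and implements
lowest-index tie-breaking, so identical runs are bit-identical.

After convergence each non-exemplar point joins the admissible exemplar of
highest similarity. Because the sentinel constrains only point–exemplar
pairs, two same-sequence points can still pick the same exemplar; the
extraction step keeps the closer one and spills the other to a singleton,
so extracted clusters never contain two l-mers from one sequence (asserted
on every run).

On small instances AP attains the exhaustively-verified optimal net
similarity when groups are separated by more than 2k and duplicate-free;
instances with groups at exactly 2k or with duplicated points are
inherently ambiguous for affinity propagation (reference implementations
with random restarts return varying partitions there), and the property
suite tests the separated regime only.

## Refinement and ranking (`apchip.refine`, `apchip.pipeline`)

For each candidate, the cluster containing the reference is the
candidate's refined cluster (`cluster_scope="all"` scores every cluster).
Three further steps turn it into a reported motif:

1. **Consensus re-anchoring** (`consensus_polish`, ≤ 4 rounds or until
   fixed): recompute the column-majority consensus of the current members,
   then re-select from each sequence the subset member closest to it;
   finally drop members farther than d from the consensus (an instance
   lies within d of the motif by definition). Anchoring membership on a
   single exemplar l-mer loses an instance whenever a background l-mer
   happens to sit closer to that exemplar — in benchmark measurements this
   caps mean nucleotide accuracy near 0.85–0.90 — while consensus
   re-anchoring (the predictive-update step familiar from EM and Gibbs
   motif finders) recovers the planted occurrences essentially exactly.
   `polish_rounds=0` disables it.
2. **Size validation and trimming**: a cluster with at most t − q members
   cannot represent a q-of-t motif and is dropped; one with more than t
   members is trimmed to exactly t by greedy growth from the exemplar,
   adding at each step the member with the largest summed string
   similarity |LCS|/(|x|+|y|−|LCS|) to the selected set (LCS = longest
   common substring; a suffix–prefix overlap variant is available).
   Finally, a reported model must retain at least q supporting sequences
   (`min_support`, default q): this is the defining constraint of the
   search problem, and without it tiny, perfectly conserved background
   clusters would outrank the true motif whenever q = t makes the size
   window vacuous.
3. **Information content**: clusters are summarised as 4×l PWMs and ranked
   by IC = Σ_m Σ_w p_{w,m} log2(p_{w,m}/p_{w,0}) against the dataset's
   base composition (`uniform_background` forces 1/4). The
   `information_content` operation itself uses raw frequencies with
   0·log 0 ≡ 0, so a fully conserved column contributes exactly 2 bits
   against a uniform background; the *pipeline* ranks with a Laplace
   pseudocount of 1 per base per column, which makes IC size-aware (a
   2-occurrence cluster no longer ties a 20-occurrence one at the
   maximum). Ties break toward the lexicographically smaller consensus and
   duplicate consensus strings collapse to their best-scoring instance.

The consensus string emits a single base when its column frequency is
≥ 0.5 and leads the runner-up by ≥ 0.15, otherwise the IUPAC code of all
bases at frequency ≥ 0.35 (falling back to the top base). Output formats:
plain-text report, MEME minimal motif format, and an occurrence TSV.

## Simulation and evaluation (`apchip.simulate`)

`simulate_dataset` draws t i.i.d. uniform sequences of length n, a uniform
random motif, and plants q mutated instances (law above) at uniform
offsets in q distinct sequences, overwriting the background; everything is
reproducible from one integer seed, and `run_trials` spawns recorded
per-trial child seeds from a master seed. Accuracy is the nucleotide-level
performance coefficient nPC = |K ∩ P| / |K ∪ P| over (sequence, base)
positions covered by true and predicted occurrences.

What the generator does *not* emulate: non-uniform genomic composition,
multiple or overlapping occurrences per sequence, variable peak widths,
strand mixtures, or positional bias of binding sites inside peaks. Passing
the simulated benchmarks therefore demonstrates correct behaviour under
the planted-motif model, not performance on real peak sets.

## Problem sizes used

The repository's own checks run at desk scale on one CPU: the simulation
benchmarks use t = 20 sequences of n = 600 bases with full occupancy,
averaged over five seeded trials ((12,2) and (15,3) instances); the
supporting property and recovery tests use t ≤ 30, n ≤ 200. The published
large-sequence-set experiments (t = 600–1000) are represented by a
scaled-down difficulty check at t = 12, n = 100 comparing an easy (12,3)
against a hard (19,7) instance; at that scale the method saturates near
nPC 1.0 on both, so the check guards against an accuracy inversion rather
than reproducing a gradient. Candidate subsets larger than `max_ap_points`
(default 4000) are capped to the members closest to the reference before
message passing; this bounds the dense-matrix cost on very weak instances
and is the only approximation active at large scale.

## Numerical choices and degenerate inputs

* Exact integer/rational arithmetic for all combinatorial sums; floats
  only at the final division.
* d = 0 is fully supported (k = 0; subsets are exact-copy families).
* Empty results are returned as an empty list plus actionable diagnostics
  (stage counts; suggestion to lower the occurrence threshold or q), never
  an exception; the CLI maps this to exit code 3 and parameter errors to 2.
* All coordinates are 0-based half-open internally and 1-based inclusive
  in reports.

## Known limitations

* The support-aware radius makes k = 2d whenever q = t; for weak instances
  (large p2d) this admits large background neighborhoods and the run time
  is dominated by message passing over them.
* The cannot-link spill (singleton fallback) can slightly over-fragment
  clusters in data where one sequence holds several near-copies.
* Ranking assumes a single planted motif; co-occurring motifs surface in
  the top-N list but their relative IC depends on support and conservation
  jointly.
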