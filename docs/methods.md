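# Methods

## Model overview

The package implements a two-system loop. A feedforward cortical stack
(PAC → STG → STR) of rank-order-coding (ROC) neurons categorizes a stream of
12-dimensional MFCC frames, and a basal-ganglia actor (GP) inverts that
mapping: given a desired striatal category, it searches for the input vector
that makes the category fire, using an accept/reject stochastic descent on
the unit's prediction error ("free-energy" minimization).  Everything is
discrete-time; one tick processes one input frame.

### Rank-order coding

A frame is encoded purely by the *ordering* of its component amplitudes:
component with rank *i* (0 = largest) receives `f(i)`, a strictly decreasing
map into (0, 1].  Two parameterizations are provided — the harmonic form
`f(i) = 1/(1+i)` (default) and a power law of the normalized descending
argsort, `f(i) = ((M−i)/M)^p`.  Activation is the dot product of the code
with a weight row.  Because weight rows are themselves (convex combinations
of) rank codes, the rearrangement inequality makes the self-match
`Y_max = Σ f(i)²` the exact attainable maximum, so ROC neurons behave as
receptive fields over orderings.

**Consequence (identifiability).**  The entire stack sees a frame only
through its ordering.  Any two inputs with the same amplitude ordering are
the *same stimulus*; conversely, no signal anywhere in the loop constrains
amplitudes.  This has three knock-on effects used throughout the package:

* the actor's error landscape `E(I)` is piecewise constant on the 12!
  ordering cones, so repeated evaluations of one ordering are memoized
  exactly during optimization;
* retrieval can recover a prototype's ordering cone but never its component
  amplitudes; reconstruction errors measured on the MFCC value scale bottom
  out at the nearest-random-candidate floor (≈ 0.24 normalized for 50
  candidates), and per-period refinement is therefore measured in rank-code
  space (`reconstruction_error(space="code")`);
* synthetic "distinct prototypes" must be distinct *as orderings*:
  `make_prototypes(max_code_sim=...)` rejects candidates whose rank code
  exceeds a normalized similarity cap with an accepted prototype.  About 3%
  of random 12-dim vector pairs exceed 0.9 similarity (they share their
  dominant components), so the cap is practical only for small banks.

### Weight initialization and plasticity

Rows are initialized as *random permutations of the f values* rather than
i.i.d. uniform.  With uniform rows, an untrained row's expected activation
on a code (`0.5·Σf`) exceeds the trained self-match bound (`Σf²`) whenever
`Σf > 2Σf²` (true for both f families at M ≥ 12), so the WTA would
permanently prefer untrained high-norm rows and learning could never
stabilize.  Permutation rows have equal norm and make self-match the exact
argmax from the first presentation.

Learning rates decay multiplicatively per win (`α ← max(α_min, γα)`): a
unit that has claimed a category becomes progressively harder to overwrite
(no catastrophic forgetting) while unused units stay plastic.  Defaults:
striatum `α₀ = 0.9, γ = 0.98` (each unit sees its own item rarely and must
snap fast); cortical layers `α₀ = 0.5, γ = 0.9` (50 units face many more
distinct frames; they must anneal quickly into stable receptive fields —
with a slow-decaying high rate their rows chase the most recent input
forever and the downstream codes never stabilize).

### STG temporal context

The STG adds, to the PAC drive, a recurrent term driven by the rank code of
the elementwise mean of its last 20 activation vectors (ring buffer; unfilled
slots read zero; window = 0 disables context entirely and makes the stack a
static classifier).  The recurrent term is scaled by a *context gain*
(default 0.25).  The two printed update equations for this layer are
mutually inconsistent (the recurrence is defined over a 20-step sum of
50×20 weights while the learning rule trains a 50×50 matrix against ranked
PAC activity), so the reconciliation is necessarily a design choice: a
single 50×50 matrix applied to the ranked buffer mean, scaled so that the
context *modulates* the frame-specific feedforward drive.  Unscaled, the
trained recurrent term's across-unit spread dominates the codes (measured:
mean pairwise code similarity rises from 0.29 to 0.65 of self-match) and
striatal discrimination collapses.  Output is clipped to `2·Y_max` as a
recurrent-growth guard (rarely binding).

### Stimulus presentation: stride-free blocks

All benchmark pipelines present stimuli in blocks: each item is held at the
input for one full STG window (20 ticks) with the buffer reset at stimulus
onset, in training, candidate evaluation and recall alike.  This mirrors
the no-overlap (25 ms stride) framing in which every sample is judged from
its own settled dynamics and makes the three phases see *identical*
dynamics, so retrieval can be verified deterministically.  In the
per-tick streaming regime the recurrent context at recall is generated by
the emissions themselves; retrieved candidates that fire in the probe
context perturb the context downstream, and because rank codes flip
discretely under small perturbations the recall accuracy degrades
chaotically (measured 0.5–0.8).  The streaming regime remains available
(`dwell=1`, contextual evaluation with buffer snapshots) but is not the
benchmark default.

For 1:1 "orthogonal representation" benchmarks (one striatal unit per item)
the striatum is trained with the serial teaching signal that bypasses its
WTA (`str_targets`).  Pure unsupervised WTA with as many units as items
stalls at 40–60% distinct winners — the classic dead-unit problem: a row
captured by one item still beats every unused random row for similar items,
and mixtures hog multiple items.  PAC and STG always remain unsupervised.

## The actor's search

`E = 1 − Y_STR[target]/Y_max`, clamped to [0, 1].  Proposals are Gaussian
per component (σ = 0.05 of the dynamic range [0, 1200]), with two
heavy-tailed complements: with probability 0.2 one component is redrawn
uniformly (kick), with probability 0.2 two components exchange values
(swap — the natural unit move in ordering space; Gaussian steps essentially
never reorder components whose values are far apart).  Acceptance requires
strict improvement; ties are rejected, keeping traces deterministic given
the RNG.  Reinforcement of the GP→STR weights fires exactly on kept
candidates.

Three mechanisms keep the search effective within a 2000-evaluation budget:

* **Memoization with novel proposals.**  `E` depends only on the
  candidate's ordering, so each ordering is evaluated once per (unit,
  context), and each iteration redraws its proposal (up to 20 times)
  against the memo table so that the budget is spent on *novel* orderings —
  re-evaluating a known ordering can only repeat a rejection.
* **Patience resets with greedy sweeps.**  After 400 consecutive
  rejections, the 1-swap neighbourhood (66 swaps) of the current candidate
  is swept repeatedly until no improving swap remains (a greedy descent to
  a 1-swap-local optimum); if the first sweep finds nothing the candidate
  is redrawn uniformly (the GP reset marked by dashed lines in optimization
  traces).  All evaluations count against the budget; accepted errors are
  monotone within each reset cycle; the best candidate seen is restored at
  the end.
* **Firing trigger.**  In serial benchmarks convergence means the error is
  below threshold *and* the candidate makes the unit win the WTA ("fires
  maximally"), and any evaluated sub-threshold candidate that fires is
  adopted even off the accepted path.  This is necessary, not cosmetic:
  strict descent frequently overshoots *past* the firing region into a
  deeper cone that excites a near-twin unit more, and can never climb back
  (measured: units with `E* < E(true frame)` and the wrong winner).

Babbling differs from the forced regime only in who chooses the unit: the
GP holds one continuously evolving candidate; each cycle the striatal WTA
picks the unit that candidate excites most, the loop optimizes that unit
until the cycle threshold, and the next cycle starts from a noise
perturbation of the current candidate (resets are rare marked events).
Starting every cycle from a fresh uniform candidate instead makes babbling
cover a 100-unit repertoire *better* than forced cold starts (WTA
warm-starting) and inverts the forced-vs-babble comparison; the wandering
form is both closer to continuous GP dynamics and the form under which the
forced regime's efficiency advantage is visible at desk scale.

## Audio front-end

25 ms Hamming frames, 10 or 25 ms stride (`T = ⌊(duration − frame)/stride⌋
+ 1`), pre-emphasis 0.97, 26 triangular mel filters, DCT-II; coefficients
1–12 (the energy-like c0 is excluded).  Raw cepstra are affinely mapped to
[0, 1200] (the mapping is stored in the sequence metadata).  Inversion is
best-effort: zero-padded inverse DCT (c0 = 0 — per-frame gain is
unidentifiable from 12 coefficients), ridge-regularized pseudo-inverse of
the filterbank, 32 Griffin–Lim iterations with a seeded initial phase.  The
contract is cepstral round-trip fidelity (mean normalized error ≤ 0.15 on
tones), not perceptual quality.

## Synthetic data

The generator emulates the structure the experiments assume: K prototype
vectors uniform in [0, 1200]¹² with enforced Euclidean separation (default
`d_min = 300`, loose at this dimension) and optional ordering separation;
label paths where each prototype dwells a fixed number of frames before a
random transition (`balanced=True` cycles through permutations of the whole
bank, emulating a corpus that covers all syllables); additive Gaussian frame
noise (sd as a fraction of the range, default 0.02 where noise is wanted);
and affine speaker transforms (gain, offset, and a smooth per-coefficient
warp held constant over time) standing in for pitch/timbre differences
between voices.  What it does *not* emulate: the spectral correlations,
manifold structure and temporal coarticulation of real speech — real MFCC
streams occupy a low-dimensional manifold on which orderings are far from
uniform, so passing these benchmarks shows the mechanics of the loop, not
speech-level performance.

## Benchmark problem sizes and knobs

* Serial recall: n = 1200 items, one unit each, ≤ 10 training periods,
  budget 2000/unit, threshold 0.3; the reported quantity is the longest run
  of consecutive recalled winners matching the goal sequence (the trained
  stack's own categorization of the stream, read out by a settled probe —
  items whose orderings collide share a categorizing unit, and the goal
  sequence absorbs this rather than pretending identity).
* Planted retrieval: k = 100, same budget/threshold.
* Per-period refinement: k = 50, four periods, 40 evaluations per unit per
  period so the accumulation of conversions spans the periods (with a large
  per-period budget the whole process completes within the first period and
  the curve is flat at the floor).
* Forced vs babble: k = 100 at 60 evaluations per unit equivalent — the
  efficiency difference between the regimes is only visible when the budget
  is scarce; with a generous budget both saturate at 1.0.
* Speaker matching: k = 60 prototypes, three unheard "speakers" (gain
  jitter 0.08, offset 3% of range, warp 5% of range).

## Numerical conventions

Ties everywhere (ranking, WTA, nearest neighbour) break to the lowest
index; runs are bit-reproducible from a single seed (child seeds via
`numpy` seed spawning, all below 2³¹).  Distances on the MFCC scale are
Euclidean normalized by `range·√M`; rank-code distances are normalized by
the maximal code distance (reversed ordering).  Histograms are normalized
to unit mass.  Degenerate inputs (empty vectors, non-finite frames,
out-of-range indices, zero budgets) are rejected with diagnostics rather
than coerced.

## Known limitations

* Amplitude unidentifiability is intrinsic to pure rank coding: retrieved
  vectors match their targets in ordering, not value.  Value-faithful
  retrieval would require an amplitude-sensitive code or an articulatory
  decoder, both out of scope.
* There are no inhibitory weights or neurons; striatal suppression of
  non-desired actor units is approximated by the accept/reject signal only.
* The per-tick streaming regime supports context-sensitive categorization
  but not reliable long serial recall (chaotic sensitivity of discrete
  re-ranking); lossless recall is demonstrated in the block-presentation
  regime.
* The correspondence benchmark uses affine/warped synthetic speakers; real
  cross-speaker variability is not affine in cepstral space.
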