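# corticobasal

A computational model of early vocal learning in the cortico–basal-ganglia
loop: rank-order-coded spiking layers that categorize MFCC audio streams, and
a basal-ganglia actor that *retrieves*, by noise-driven free-energy
minimization, the input vectors that cause desired striatal categories.  The
package is aimed at computational neuroscientists and speech-development
modellers who want a compact, fully seeded implementation of the
categorize-then-retrieve loop — including motor-babbling exploration, forced
serial learning and recall, and correspondence matching across speakers.

## The model

**Sensory stack (PAC → STG → STR).**  A 12-dim MFCC frame *X* is encoded by
its amplitude *ordering*: component *i* receives `f(rank of X_i)` where `f`
is a strictly decreasing rank function with values in (0, 1] (worked default
`f(i) = 1/(1+i)`).  A rank-order neuron's activation is the dot product of
this code with its weight row,

    Y_n = Σ_m rank(X)_m · w_nm ,    w ∈ [0, 1],

which is maximal, at `Y_max = Σ_i f(i)²`, exactly when the input ordering
matches the stored one.  The primary auditory cortex (PAC, 50×12) codes each
frame; the superior temporal gyrus (STG, 50×50) adds a recurrent term driven
by the rank code of the mean of its own last 20 activation vectors (a
20-step temporal window); the striatum (STR, one unit per category) encodes
the STG state.  Learning is winner-take-all with a per-neuron adaptive rate:

    Δw_bm = α_b (target_m − w_bm),   α_b ← max(α_min, γ·α_b) on each win,

with targets rank(X), rank(Y_PAC) and rank(Y_STG) for PAC, STG and STR.  A
PFC-like teaching signal can bypass the striatal WTA to designate the unit
that learns (serial supervised mode).

**Actor loop (STR ⇄ GP).**  For a desired striatal category, the prediction
error of a candidate input *I* is `E = 1 − Y_STR[target]/Y_max ∈ [0, 1]`.
The globus pallidus perturbs its candidate with Gaussian noise (plus
occasional component kicks and value swaps), keeps perturbations iff the
error strictly decreases, and reinforces its link weights toward the
observed striatal pattern on every accepted step:

    Δw_GP = β (Y_STR − w_GP) · δ₁ ,   I(t+1) = I(t) + noise · δ_ΔE .

A unit converges when its error is below threshold *and* the candidate makes
it win the WTA (the unit "fires maximally").  Forced mode optimizes units in
serial order; babbling mode lets the WTA itself pick which unit the evolving
candidate trains.

## Worked example

```bash
python examples/04_serial_recall.py
```

```
sequence length:         300
goal units converged:    100.0%
recalled frames correct: 100.0%
longest lossless run:    300
```

A bank of 300 distinct 12-dim vectors is presented stride-free (each held
for one STG window); the stack learns one striatal unit per item; the actor
then retrieves every unit's input vector by free-energy search (budget 2000
evaluations per unit, threshold 0.3) and the whole sequence is recalled by
driving the stack with the retrieved vectors.  All 300 recalled winners
match their goals, so the longest lossless run equals the sequence length.

Other examples: `01_rank_coding.py` (codes and WTA learning),
`02_categorize_stream.py` (stream categorization), `03_free_energy_retrieval.py`
(error densities after retrieval), `05_speaker_matching.py` (correspondence
matching across synthetic speakers — exact matches ≈ 28× chance),
`06_audio_roundtrip.py` (WAV → MFCC → WAV, round-trip error ≈ 0.12).

A thin CLI mirrors the pipeline: `corticobasal synth | train | optimize
--mode forced|babble | recall | eval`, each reproducible bit-for-bit from a
seed and a YAML config.

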