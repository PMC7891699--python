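"""Rank-order coding basics: codes, activations, winner-take-all learning.

Builds a small layer of rank-order neurons, trains it on a handful of
synthetic spectral prototypes, and shows that each prototype captures its
own neuron whose weights converge to the prototype's rank code.
"""

import numpy as np

from corticobasal import RankFunction, ROCLayer, rank_transform, train_layer

f = RankFunction()
x = np.array([0.9, 0.1, 0.5])
print("input:            ", x)
print("rank code:        ", rank_transform(x, f))
print("self-match bound: ", f.self_match(3), "(activation of a matching row)")

from corticobasal import make_prototypes

rng = np.random.default_rng(0)
# prototypes distinct in the space the neurons perceive: their orderings
protos = make_prototypes(10, seed=0, max_code_sim=0.8).vectors
layer = ROCLayer.create(20, 12, f, rng=rng)
winners = train_layer(layer, protos, periods=5)
print("\ndistinct winners after training:", len(set(winners[-1].tolist())), "of 10")
err = max(
    np.abs(layer.weights[winners[-1][i]] - rank_transform(p, f)).max()
    for i, p in enumerate(protos)
)
print(f"max |winner row - prototype code|: {err:.2e}")
print("-> each prototype owns one neuron whose weights equal its rank code.")
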