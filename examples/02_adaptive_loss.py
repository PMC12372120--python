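"""The misclassification-aware adaptive loss (MAAL) weight schedule.

Feeds a scripted sequence of per-class error counts through the weight rule
and shows how error shares become exponential class weights after the
warm-up delay.
"""

import numpy as np

from macnet import ClassWeightState, cross_entropy, maal, update_weights

state = ClassWeightState(n_classes=3, update_delay=60)

# before the delay nothing happens, however lopsided the errors are
update_weights(state, [0, 40, 25], epoch=10)
print("epoch 10 weights:", state.weights.tolist())

# after the delay the error shares are exponentiated: w_i = exp(share_i)
update_weights(state, [0, 40, 25], epoch=60)
print("epoch 60 weights:", np.round(state.weights, 4).tolist(),
      " (exp of error shares [0, 0.615, 0.385])")

# the weighted loss now penalizes mistakes on the error-prone classes more
probs = np.array([[0.2, 0.6, 0.2], [0.2, 0.2, 0.6]])
labels = np.array([1, 2])
print(f"plain CE      : {cross_entropy(probs, labels):.4f}")
print(f"MAAL weighted : {maal(probs, labels, state.weights):.4f}")
print("-> same predictions, larger loss: gradient pressure shifts toward "
      "the classes the model currently gets wrong.")
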