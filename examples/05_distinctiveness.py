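"""How individually distinct is a call type, and does it predict response?

For one focal bird's playback set — 3 exemplars from each of the 3
opposite-sex callers — the 14 spectral features are reduced to two
principal components and a linear discriminant tries to re-assign each
stimulus to its caller.  High misassignment = weakly individualized
call type.  We compare indistinguishable callers with well-separated
ones.
"""

from softcalls._rng import split_rng
from softcalls.distinctiveness import distinctiveness_index
from softcalls.studies import _identity_features

rng = split_rng(3, "example", "distinctiveness")

# three callers with identical voice distributions (chance level = 2/3)
X_same, ids_same = _identity_features(rng, [600.0, 600.0, 600.0], n_per_identity=3)
# three callers 300 Hz apart in fundamental (strongly individual)
X_sep, ids_sep = _identity_features(rng, [500.0, 800.0, 1100.0], n_per_identity=3)

for name, X, ids in (("identical voices", X_same, ids_same), ("separated voices", X_sep, ids_sep)):
    res = distinctiveness_index(X, ids)
    print(f"{name}: misassigned {res.proportion_incorrect:.2f} of {res.n_stimuli} stimuli")
print()
print("With 9 stimuli per bird/call type the index is coarse (steps of")
print("1/9); across many birds the mean misassignment separates weakly")
print("from strongly individualized call types. Chance is 2/3 here.")
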