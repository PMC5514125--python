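"""Synthesize calls of three types and recover them by clustering.

Builds 30 renditions each of a short tonal tet, a long downsweeping
distance call and a harmonically rich hat, computes the sorting
parameters (average/modal/fundamental frequency, Wiener entropy,
duration and their per-window SDs) and clusters them with k-means.
"""

from sklearn.metrics import adjusted_rand_score

from softcalls._rng import split_rng
from softcalls.acoustics import cluster_calls, compute_sorting_features
from softcalls.synth import BirdProfile, CallTimbre, generate_call_waveform

TYPES = {
    "tet": CallTimbre(fundamental_hz=500, duration_s=0.06, n_harmonics=2, noise_floor=0.03),
    "distance": CallTimbre(fundamental_hz=700, duration_s=0.13, n_harmonics=5, noise_floor=0.03, fm_glide=-0.15),
    "hat": CallTimbre(fundamental_hz=900, duration_s=0.07, n_harmonics=8, noise_floor=0.03, fm_glide=0.20),
}

rng = split_rng(7, "example", "cluster")
features, truth = [], []
for label, timbre in TYPES.items():
    bird = BirdProfile(bird_id="demo", sex="F", calls={label: timbre})
    for _ in range(30):
        seg = generate_call_waveform(bird, label, seed=int(rng.integers(2**31)))
        features.append(compute_sorting_features(seg))
        truth.append(label)

assignment = cluster_calls(features, k=3, seed=7)
ari = adjusted_rand_score(truth, assignment.labels)
print(f"calls synthesized : {len(features)}")
print(f"noise-flagged     : {int(assignment.is_noise.sum())}")
print(f"adjusted Rand     : {ari:.3f}")
print("ARI of 1.0 means the k-means partition matches the planted call")
print("types exactly; values above 0.9 indicate reliable sorting.")
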