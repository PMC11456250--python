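"""Factorize a zero-inflated count tensor and compare noise models.

Builds a small rank-3 tensor with known Gamma(3, 0.3) factors, corrupts it
with zero-inflated Poisson noise (60% excess zeros), fits both the ZIP and
the plain Gamma-Poisson model, and scores each reconstruction against the
noiseless ground-truth mean tensor.
"""

from ziptf import ModelSpec, explained_variance, fit, reconstruct, simulate_zip_tensor

sim = simulate_zip_tensor(shape=(8, 10, 60), rank=3, phi=0.6, seed=42)
print(f"tensor {sim.tensor.shape}, zero fraction {sim.zero_fraction:.2f} "
      f"(excess-zero probability {sim.phi})")

for model in ("zip", "gamma_poisson"):
    spec = ModelSpec(noise_model=model, rank=3, prior_shape=1.0, prior_rate=0.3)
    res = fit(sim.tensor, spec, max_iter=800, seed=1)
    recovery = explained_variance(
        sim.mean_tensor.data, reconstruct(res.point_estimate).data, squared=True
    )
    print(f"{model:>14}: explained variance vs ground truth = {recovery:.3f}")

# The ZIP fit recovers the mean tensor almost perfectly because the gate
# absorbs the excess zeros; the Poisson fit shrinks toward (1 - phi) times
# the truth and explains far less of its variance.
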