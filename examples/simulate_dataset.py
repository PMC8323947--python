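"""Generate a synthetic annual conflict dataset and inspect its structure.

The generator produces everything the state-space analysis assumes: a
slowly warming temperature-like covariate, a noisier rainfall-like
covariate, a monument (exposure) series that is sparse early and peaks
late, and conflict counts drawn from the Poisson model around a latent
autocorrelated log-rate path.  Ground truth comes back with the data.
"""

import numpy as np

from countflux import SyntheticConfig, generate_dataset, write_dataset

config = SyntheticConfig(n_years=400, seed=1)  # the package's reference scenario
dataset, truth = generate_dataset(config)

print(f"years {dataset.start_year}-{dataset.end_year} ({dataset.n_years} rows)")
print(f"total conflicts: {dataset.conflicts.sum()}, "
      f"total monuments: {dataset.monuments.sum()}")
first_active = int(np.argmax(dataset.monuments > 0))
print(f"first year with any monuments: {dataset.years[first_active]} "
      f"(the {first_active}-year head of zeros exercises zero-exposure handling)")
print(f"true temperature effect: {truth['beta']['temperature']} per unit "
      f"(log-link scale); true rho={truth['rho']}, sigma={truth['sigma']}")
print(f"latent path range: [{truth['delta'].min():.2f}, {truth['delta'].max():.2f}]")

path = write_dataset(dataset, "synthetic_conflicts.csv")
print(f"wrote {path} (columns: year, conflicts, monuments, temperature, rainfall)")
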