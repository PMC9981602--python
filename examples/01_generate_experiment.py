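"""Generate a synthetic host-parasitoid exposure experiment.

Builds the factorial design (replicates x daily host ages x seed
qualities), simulates each host's development and its 24-h parasitoid
exposure, and prints the design arithmetic and parasitism summary.
"""

import numpy as np

from parastage import DesignConfig, generate_exposure_dataset

config = DesignConfig(n_replicates=12, age_start=5, age_stop=60, qualities=(90, 95, 100), seed=1)
data = generate_exposure_dataset(config)

print(f"exposure units: {len(data)} "
      f"({config.n_replicates} replicates x {len(config.ages)} ages x {len(config.qualities)} qualities)")
usable = data[~data.host_died.astype(bool) & ~data.host_emerged.astype(bool)]
print(f"usable hosts (alive, still in seed): {len(usable)}")
print(f"parasitized: {usable.parasitized.mean():.1%} of usable hosts")
print("\nparasitism by observed stage at attack (parasitized hosts only):")
print(data.groupby("stage_at_parasitism", observed=True).size())
# Stage is recorded only for parasitized hosts (head-capsule counts at
# dissection); unparasitized hosts have a missing stage by design - that
# missingness is what the imputation machinery exists for.
print("\nstage missing exactly when unparasitized:",
      bool((data.stage_at_parasitism.notna() == data.parasitized).all()))
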