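"""Estimate age -> stage probability tables and impute missing stages.

A reference development data set gives, for each seed quality and host
age, the probability the host is in each developmental stage.  Those
distributions fill in the unobserved stages of unparasitized hosts.
"""

import numpy as np

from parastage import (
    DesignConfig,
    HostDevelopmentParams,
    estimate_stage_distribution,
    generate_exposure_dataset,
    generate_reference_table,
    impute_stages,
)

rng = np.random.default_rng(2)
dev = HostDevelopmentParams()

reference = generate_reference_table(dev, n_per_cell=40, rng=rng)
table = estimate_stage_distribution(reference)
print(f"reference records: {len(reference)}; estimated cells: {len(table.cells)}")
print("P(stage | quality=90, age=20):",
      dict(zip(("L1", "L2", "L3", "L4", "P", "A"), table.lookup(90, 20).round(3))))

data = generate_exposure_dataset(DesignConfig(n_replicates=6, seed=2), dev_params=dev)
usable = data[~data.host_died.astype(bool) & ~data.host_emerged.astype(bool)]
staged = impute_stages(usable, table, rng, nearest_age_fallback=True)
print(f"\nimputed stages for {(~usable.parasitized.astype(bool)).sum()} unparasitized hosts")
print("stage counts after imputation:")
print(staged.stage_at_parasitism.value_counts())
# Parasitized hosts keep their dissected (head-capsule) stage; only the
# unobserved stages are drawn from the probability table.
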