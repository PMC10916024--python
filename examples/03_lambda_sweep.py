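"""Sweep the shrinkage weight lambda and watch the driver count respond.

lambda = 1 keeps each gene's own GLM background estimate (no shrinkage);
lambda = 0 replaces it entirely with the inverse-distance-weighted score of
its FIS-circle neighbors. The fitted model and circles are computed once
and reused across the sweep.
"""

import tempfile
from pathlib import Path

from driverfis import RunConfig, SimulationConfig, run_lambda_sweep, simulate_cohort

cohort = simulate_cohort(
    SimulationConfig(n_genes=400, n_samples=80, n_drivers=4, seed=2)
)
paths = cohort.write(Path(tempfile.mkdtemp()))

table = run_lambda_sweep(
    RunConfig(maf=paths["maf"], fis_table=paths["fis_table"],
              features=paths["features"]),
    lambdas=[i / 10 for i in range(11)],
)
print(table.to_string(index=False))
print("\nn_drivers is the number of genes called at q <= 0.05 for each "
      "blend weight;\nthe 4 spiked drivers dominate every setting, while "
      "borderline genes come and go.")
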