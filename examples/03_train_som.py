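"""Train a single self-organizing map and read its quality errors.

Standardizes the 15 input variables, sizes the map from n and the leading
covariance eigenvalues (12 x 6 for this cohort), trains a batch SOM with a
gaussian neighborhood, and prints the quantization error (mean distance to
the best-matching unit, in z-score units) and topographic error (fraction
of cases whose two best units are not lattice neighbors; 0 = perfect
topology preservation).
"""

import somprofiler as sp
from somprofiler.pipeline import Standardizer, export_component_planes

cohort = sp.generate_study_cohort(seed=1, with_outcomes=False)
X = Standardizer().fit_transform(cohort[list(sp.INPUT_VARIABLE_NAMES)].to_numpy())

grid = sp.HexGrid(*sp.map_size(len(X), sp.eigenvalue_ratio(X)))
print(f"auto-sized grid: {grid.height} x {grid.width} hexagonal units")

schedule = sp.default_schedule(grid, len(X), mode="batch",
                               neighborhood="gaussian", init="linear", seed=1)
som = sp.train_som(X, grid, schedule, variable_names=sp.INPUT_VARIABLE_NAMES)
print(f"quantization error: {som.quantization_error:.4f}")
print(f"topographic error:  {som.topographic_error:.4f}")
print(f"selection score (QE x TE): {som.score:.6f}")

planes = export_component_planes(som)
print(f"\ncomponent planes exported: {len(planes)} (one per input variable)")
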