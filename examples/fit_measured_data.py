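"""Co-refine reflectivity data files across contrasts and conditions.

Shows the workflow for measured data stored as ASCII column tables
(Q [1/A], R, dR, optional dQ): read one file per contrast per condition,
attach a structure to every condition with the substrate/SAM block shared
between them, and refine simultaneously.  To stay self-contained the
script first writes simulated files to a scratch directory; point
``data_dir`` at real exported reflectivity tables to fit an experiment.
"""

import tempfile
from pathlib import Path

import refloat as rf
from refloat.fitting import assemble_problem, fit
from refloat.model import Parameter, ffb_structure
from refloat.synthetic import default_qgrid

data_dir = Path(tempfile.mkdtemp(prefix="refloat_demo_"))

# --- stand-in for an experiment: write one file per contrast/condition ---
grid = default_qgrid(60)
for condition in ("CaCl2_initial", "NaCl"):
    truth = rf.measured_fixture("POPC", condition)
    for ds in rf.simulate_condition(truth, grid=grid, seed=42):
        rf.write_dataset(ds, data_dir / f"{condition}_{ds.contrast.name}.dat")

# --- the actual workflow: read, build shared structures, co-refine ------
datasets = [rf.read_dataset(p) for p in sorted(data_dir.glob("*.dat"))]
print(f"read {len(datasets)} datasets from {data_dir}")

sam_apm = Parameter(22.0, "sam_apm", (19.0, 26.0), vary=True)  # shared
structures = {}
for condition in ("CaCl2_initial", "NaCl"):
    distance = Parameter(30.0, f"distance[{condition}]", (1.0, 120.0), vary=True)
    roughness = Parameter(8.0, f"roughness[{condition}]", (0.5, 40.0), vary=True)
    structures[condition] = ffb_structure(
        "POPC", condition, distance, roughness,
        sam_area_per_molecule=sam_apm,
    )

problem = assemble_problem(datasets, structures)
print("free parameters:", problem.names)
summary = fit(problem, seed=1, n_steps=800,
              optimizer_options=dict(maxiter=12, popsize=8, tol=0.01))

for name in problem.names:
    m, lo, hi = summary.parameter(name)
    print(f"  {name:>22}: {m:8.2f}  [{lo:.2f}, {hi:.2f}]")
print("chi^2 =", round(problem.chi_squared(), 1), "over", problem.n_points, "points")
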