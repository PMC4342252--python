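"""Recover kinetic parameters from a noisy synthetic study.

Generates a dataset with 5% replicate noise from the reference truth, then
runs the two estimation stages: per-equation decoupled fitting (regulators
taken from data interpolants) followed by a coupled-system refinement.
"""

from floranet import (
    SynthConfig,
    fit_decoupled,
    generate_dataset,
    refine_full_system,
    reference_parameters,
)

config = SynthConfig(seed=11, noise_cv=0.05, replicates=2)
dataset = generate_dataset(config, params=reference_parameters())
print(f"dataset: {len(dataset.table)} rows, max {dataset.table['abundance'].max():.0f} nM")

problem = dataset.fit_problem()
params1, diag1 = fit_decoupled(problem, starts=12, seed=1)
print("\nstage 1 (decoupled) NRMSE per gene [%]:")
print({g: round(100 * v, 1) for g, v in diag1.per_gene_nrmse.items()})

params2, diag2 = refine_full_system(problem, params1, max_nfev=60)
print("\nstage 2 (coupled refinement) NRMSE per gene [%]:")
print({g: round(100 * v, 1) for g, v in diag2.per_gene_nrmse.items()})
print(f"\nestimated FT transport delay: {params2.delta:.2f} d (truth {dataset.truth.delta:.2f} d)")

# Stage-1 errors reflect single-equation fits against data-interpolated
# regulators; stage 2 scores the fully coupled simulation. NRMSE near the
# noise level (a few percent) means the dynamics are recovered.
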