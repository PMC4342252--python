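"""Model selection for the LFY -> AP1 cooperativity.

Generates noise-free data under Hill coefficients n = 1 and n = 3 and asks
the fitting machinery which cooperativity best explains each dataset: the
NRMSE-versus-n table should bottom out at the generating value.
"""

from floranet import (
    SynthConfig,
    generate_dataset,
    reference_parameters,
    select_hill_coefficient,
)

for gen_n in (1, 3):
    config = SynthConfig(seed=21, noise_cv=0.0, n=gen_n)
    dataset = generate_dataset(config, params=reference_parameters(n=gen_n))
    selection = select_hill_coefficient(
        dataset.fit_problem(), candidates=(1, 2, 3, 4, 5), starts=8, seed=2, refine=False
    )
    table = {n: f"{100 * v:.2f}%" for n, v in sorted(selection.ap1_nrmse.items())}
    print(f"data generated with n={gen_n}: selected n={selection.best_n}")
    print(f"  AP1 NRMSE by candidate: {table}")

# A cooperative (n=3) truth produces a step-like AP1 rise that a non-
# cooperative model cannot track, and vice versa a smooth n=1 rise is
# over-steepened by n>1 — so the fit error is minimised at the true n.
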