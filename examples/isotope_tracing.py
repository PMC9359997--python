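"""Estimate how much lipogenic acetyl-CoA came from a [1-13C] ethanol tracer.

Simulates palmitate mass-isotopomer tables for three tissues with known
enrichments, fits the two ISA parameters (D: tracer fraction of the
lipogenic acetyl-CoA pool; g: fraction of palmitate newly synthesised) per
sample, and prints the recovered tracer contribution in percent.
"""

from acetotrace.isa import fit_mid_table
from acetotrace.simulate import MidSimSpec, generate_mid_dataset

for tissue, d_true in {"plasma": 0.27, "liver": 0.24, "cecum": 0.18}.items():
    spec = MidSimSpec(
        D_true=d_true, g_true=0.6, noise_sd=0.003, n_samples=3, tissue=tissue, seed=1
    )
    mids = generate_mid_dataset(spec)
    fits = fit_mid_table(mids, seed=0)
    print(f"{tissue}: planted D = {d_true:.2f}")
    print(
        fits[["sample", "D", "g", "tracer_contribution_pct"]].to_string(index=False)
    )
    print(
        f"  mean tracer contribution {fits['tracer_contribution_pct'].mean():.1f}% "
        "of lipogenic acetyl-CoA\n"
    )

print(
    "Each fitted D is the fraction of the lipogenic acetyl-CoA pool derived\n"
    "from the tracer in that sample; multiplied by 100 it is the percentage\n"
    "of newly synthesised fatty-acid carbon units traceable to ethanol."
)
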