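"""Descriptor-lifetime correlation on a synthetic structure study.

Generates 12 pseudo-proteins x 10 predicted models whose lifetimes follow
a noisy decreasing function of the pocket dipole magnitude, computes all
five descriptors for every model, and reports the per-model Spearman
correlation (mean +/- sd over models) with a protein-level bootstrap 95%
confidence interval for each descriptor.
"""

from pocketflim import (
    StructureSetSpec,
    compute_all_properties,
    correlation_report,
    properties_table,
    simulate_structure_set,
)

spec = StructureSetSpec(seed=1)  # 12 proteins, 10 models, dipoles 0.5-7.5 e*A
study = simulate_structure_set(spec)

per_protein = {
    pid: compute_all_properties(st, ligand_selector="LIG")
    for pid, st in study.structures.items()
}
props = properties_table(per_protein)
report = correlation_report(props, study.lifetimes, n_boot=10_000, seed=1)

print(report[["descriptor", "rho_mean", "rho_sd", "ci_lo", "ci_hi",
              "significant"]].to_string(index=False, float_format="%.3f"))
print()
print("Only the dipole descriptor should be significantly (and negatively)")
print("correlated with lifetime — the generator builds that relation in —")
print("while the remaining descriptors are expected to be flagged n.s.")
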