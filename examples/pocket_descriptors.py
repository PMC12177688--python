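"""Binding-pocket descriptors of one synthetic protein-ligand complex.

Builds a pseudo-protein with a known pocket dipole of 4.0 e*A around a
fixed dye-like ligand and computes the five pocket descriptors: convex
hull volume and surface area, mean Kyte-Doolittle hydropathy, Shrake-
Rupley solvent-accessible surface area, and the dipole magnitude.
"""

from pocketflim import build_pocket_structure, compute_all_properties

structure = build_pocket_structure(target_dipole=4.0, n_residues=12, n_models=1)
(props,) = compute_all_properties(structure, ligand_selector="LIG", cutoff=5.0)

print(f"pocket residues      : {props.n_residues}")
print(f"hull volume          : {props.volume:.1f} A^3")
print(f"hull surface area    : {props.surface_area:.1f} A^2")
print(f"hydropathy (KD mean) : {props.hydropathy:.2f}")
print(f"SASA                 : {props.sasa:.1f} A^2")
print(f"dipole magnitude     : {props.dipole_magnitude:.3f} e*A "
      f"({props.dipole_magnitude * 4.8032:.2f} D, scheme={props.charge_scheme})")
print()
print("The dipole equals the 4.0 e*A the generator was asked for: the one")
print("Arg(+)/Asp(-) pair is placed at the exact angular separation that")
print("realizes it. The other descriptors follow from the shell geometry.")
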