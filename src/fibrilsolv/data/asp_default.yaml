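# Default atomic solvation parameters (kcal mol^-1 A^-2), five atom classes.
# These are literature defaults in the Eisenberg-McLachlan tradition, shipped
# as a starting point; override with your own file for other conventions.
#
# Sign convention: a residue's stabilization energy is
#     dG = -sum_atoms sigma(class) * buried_area
# so burying apolar carbon (sigma > 0) is stabilizing (negative dG) and
# burying charged nitrogen (sigma < 0) is destabilizing (positive dG).
version: 1
parameters:
  apolar_C: 0.016
  polar_N_O: -0.006
  carboxylate_O_minus: -0.024
  charged_N_plus: -0.050
  sulfur: 0.021
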