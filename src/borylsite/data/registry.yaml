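# Catalyst / ligand / solvent registry with integer encodings.
#
# The codes quoted in the primary literature are reproduced verbatim:
#   [Cp*RuCl2]2 = 1, [Cp*RuCl]4 = 2 (catalysts); none = 1, dtbpy = 2 (ligands).
# The remaining assignments complete the roster of seven Ir/Ru/Rh
# precatalysts and eight ligands in a fixed conventional order; they are a
# package convention, NOT ground truth from the source data.
catalysts:
  "[Cp*RuCl2]2": 1
  "[Cp*RuCl]4": 2
  "[Ir(OMe)(cod)]2": 3
  "[Ir(Cl)(cod)]2": 4
  "[Ir(OH)(cod)]2": 5
  "Cp*Rh(C6Me6)": 6
  "[RhCl(coe)2]2": 7
ligands:
  "none": 1
  "dtbpy": 2
  "tmphen": 3
  "bpy": 4
  "dppe": 5
  "PMe3": 6
  "AsPh3": 7
  "cod": 8
boron_sources:
  "HBpin": 1
  "B2pin2": 2
solvents:
  "neat": 1          # reserved code for solvent-free reactions
  "octane": 2
  "hexanes": 3
  "THF": 4
  "MTBE": 5
  "cyclohexane": 6
  "dioxane": 7
  "benzene": 8
# Active catalyst formed in situ from a (catalyst, ligand) pair.  Distinct
# pairs can converge on the same active tris-boryl complex; the mapping
# below groups pairs by metal and ligand family.  Pairs not listed fall
# back to a deterministic code derived from (catalyst_code, ligand_code).
active_catalysts:
  "[Ir(OMe)(cod)]2|dtbpy": 1
  "[Ir(Cl)(cod)]2|dtbpy": 1
  "[Ir(OH)(cod)]2|dtbpy": 1
  "[Ir(OMe)(cod)]2|bpy": 2
  "[Ir(OMe)(cod)]2|tmphen": 3
  "[Ir(OMe)(cod)]2|none": 4
  "[Ir(Cl)(cod)]2|dppe": 5
  "[Ir(OMe)(cod)]2|PMe3": 6
  "[Cp*RuCl2]2|none": 7
  "[Cp*RuCl]4|none": 7
  "[Cp*RuCl2]2|AsPh3": 8
  "[Cp*RuCl]4|AsPh3": 8
  "Cp*Rh(C6Me6)|none": 9
  "[RhCl(coe)2]2|PMe3": 10
  "[RhCl(coe)2]2|none": 11
  "[Ir(Cl)(cod)]2|AsPh3": 12
  "[Ir(OMe)(cod)]2|cod": 4
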