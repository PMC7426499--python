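"""Convert a tissue mass concentration of 3-hydroxykynurenine to molarity.

μg analyte per g fresh tissue, times tissue density (≈1 g/mL), divided by
the molar mass in g/mol, is exactly mmol/L.
"""
from flysla import MOLAR_MASS_3HOK, tissue_conc_to_molar

level = 396.0  # μg/g fresh weight, the reported cardinal-mutant tissue level
mm = tissue_conc_to_molar(level, MOLAR_MASS_3HOK, density=1.0)
print(f"{level} ug/g of 3-HOK ({MOLAR_MASS_3HOK} g/mol) = {mm:.3f} mM")
print("i.e. roughly 1.7 mM in tissue - far above the micromolar doses that "
      "are neurotoxic in cell culture")
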