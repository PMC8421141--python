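"""Physical constants and package-wide defaults.

All energies are in kcal/mol, distances in nm (images, polymers) or
Angstrom (reaction coordinates), angles in degrees unless noted.
"""

#: Boltzmann constant in kcal mol^-1 K^-1.
K_B_KCAL = 0.0019872041

#: Default simulation / imaging temperature (K).
DEFAULT_TEMPERATURE_K = 300.0

#: Contour length per base pair for surface-deposited DNA (nm/bp).
#: ~10% below the nominal B-DNA rise of 0.34 nm, as observed on mica.
NM_PER_BP = 0.30

#: Default AFM pixel size (nm) and image shape.
PIXEL_NM = 3.9
IMAGE_PX = (512, 512)

#: DNA persistence length in nm (literature-typical).
PERSISTENCE_NM = 50.0
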