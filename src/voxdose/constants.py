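"""Shared physical constants and grid conventions.

Every module uses the same kernel geometry: a 64**3 voxel grid at 3 mm
isotropic spacing (19.2 cm per axis) with the source voxel fixed at
0-based index (32, 32, 32).
"""

# Kernel geometry -----------------------------------------------------------
KERNEL_SHAPE = 64
SOURCE_INDEX = (32, 32, 32)
KERNEL_SPACING_MM = 3.0

# F-18 decay data -----------------------------------------------------------
F18_HALF_LIFE_MIN = 109.77
F18_POSITRON_FRACTION = 0.9673   # beta+ branching; applied at Gy conversion
F18_MEAN_ENERGY_KEV = 242.8      # mean of the implemented beta+ spectrum
F18_ENDPOINT_KEV = 633.5         # spectrum endpoint
ANNIHILATION_KEV = 511.0

# Electron rest mass (keV)
ELECTRON_MASS_KEV = 511.0

# Transport settings --------------------------------------------------------
PHOTON_CUTOFF_KEV = 10.0         # photons below this deposit locally

# Unit conversions ----------------------------------------------------------
MEV_TO_J = 1.602176634e-13
# MeV/cm3 divided by density (g/cm3) -> MeV/g; times MEV_TO_J*1e3 -> J/kg (Gy)
MEV_PER_CM3_TO_GY_PER_DENSITY = MEV_TO_J * 1e3  # = 1.602176634e-10
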