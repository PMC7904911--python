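"""Physical constants and default parameters of the in vitro Y-90 microsphere model.

Energies are in MeV, lengths in micrometres (geometry) or g/cm^2 (transport),
times in hours at the API surface and seconds internally for activity
arithmetic (Bq is s^-1).
"""

# fundamental
ELECTRON_MASS_MEV = 0.51099895          # electron rest energy, MeV
FINE_STRUCTURE = 7.2973525693e-3        # fine-structure constant alpha
HBARC_OVER_ME_FM = 386.15926796         # hbar/(m_e c), fm — electron Compton wavelength / 2pi
MEV_TO_J = 1.602176634e-13              # MeV -> joule

# liquid water (ICRU-recommended composition values)
WATER_DENSITY_G_CM3 = 1.0
WATER_Z_OVER_A = 0.55509                # <Z/A> of water
WATER_MEAN_EXCITATION_MEV = 75e-6       # I = 75 eV
WATER_RADIATION_LENGTH_G_CM2 = 36.08    # X0 of water
WATER_EFFECTIVE_Z = 7.42                # for the radiative stopping-power estimate

# Sternheimer density-effect parameterization, liquid water
WATER_STERNHEIMER = dict(C=3.5017, a=0.09116, m=3.4773, x0=0.2400, x1=2.8004)

# Y-90 -> Zr-90 decay (pure beta-minus, first-forbidden unique)
Y90_ENDPOINT_MEV = 2.27
Y90_MEAN_MEV = 0.93
Y90_DAUGHTER_Z = 40
Y90_MASS_NUMBER = 90
Y90_HALF_LIFE_H = 64.1

# microsphere / plate geometry of the in vitro model
SPHERE_DIAMETER_UM = 32.5               # median resin-sphere diameter
SPHERE_DIAMETER_BAND_UM = (20.0, 60.0)  # manufacturer size band
SPHERE_ACTIVITY_BQ = 55.0               # A0 per sphere at the start of exposure
FOV_WIDTH_UM = 1800.0                   # microscope field of view
FOV_HEIGHT_UM = 1300.0

SECONDS_PER_HOUR = 3600.0
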