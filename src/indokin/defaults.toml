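# Default parameter set for aqueous / ethanol indole photophysics.
# Units are fixed: rates s^-1 (bimolecular M^-1 s^-1), energies eV,
# temperature K, times s, concentrations M, wavelengths nm,
# molar absorptivities M^-1 cm^-1.

[rates]
k_LbLa = 1.25e12         # 1Lb -> 1La transfer, 1/(0.8 ps)
k_rad = 5.0e7            # 1La radiative rate
k_pair_b = 1.0e11        # contact pair -> 1La back transfer (fast pre-equilibrium)
k_gem = 8.3333333e9      # geminate recombination of 200 nm-born pairs, 1/(120 ps)
omega_escape = 0.451     # escape probability of 200 nm-born charges (calibrated, see docs/methods.md)
k_rec2 = 3.0e10          # free-ion bimolecular recombination (diffusion limited)
f_T = 0.65               # branching of free-ion recombination into triplet indole
k_T = 6.6666667e4        # triplet decay, 1/(15 us), deaerated
k_scav_H = 1.0e10        # H+ + separated electron
k_scav_NO3 = 7.6e9       # NO3- + separated electron
k_scav_pair_H = 4.45e9   # H+ + pair-bound electron (fluorescence-lifetime slope)
k_scav_pair_NO3 = 7.6e9  # NO3- + pair-bound electron (fluorescence-lifetime slope)
k_adduct = 1.0e10        # H atom + indole cation -> adduct
dE_sep = 0.2             # 1La -> separated ions endothermicity
dE_pair = 0.03           # 1La -> contact pair endothermicity
T = 298.15

[calibration]
tau_fl_water = 4.56e-9      # TCSPC 1La fluorescence lifetime in water
K_pair = 0.25               # pair/1La equilibrium constant at 298.15 K
phi_electron = 0.2          # separated-electron yield per absorbed photon at the horizon
horizon = 1.0e-6            # s; evaluation horizon for the electron-yield calibration
tau_fl_ethanol = 4.61523e-9 # population decays 15% over the first 750 ps
phi_prompt_200 = 0.55       # prompt-ionization branch at 200 nm in water

[initial]
frac_La_268 = 0.75          # 1La:1Lb = 3:1 at 268 nm
frac_La_292 = 0.5           # equal proportion at 292 nm

[geometry.femto]
path_length = 0.02          # cm
c_exc = 1.2e-4              # excited molar concentration
irf_fwhm = 7.0e-14          # s, 268/292 nm pump
irf_fwhm_200 = 2.4e-13      # s, 200 nm pump
time_zero = 0.0

[geometry.nano]
path_length = 0.01
c_exc = 1.502e-2            # calibrated against the post-IRF triplet growth (see docs/methods.md)
irf_fwhm = 5.0e-9
time_zero = 0.0

# Species band parameterizations: bands = [[center_nm, fwhm_nm, amplitude], ...].
# Centres are nascent positions; species with a solvation shift relax to
# (center - shift_amplitude). Amplitudes are shape stand-ins digitized from
# published transient spectra; the separated-electron amplitude is anchored
# to the re-evaluated extinction coefficient of the aqueous electron.

[spectra.e_separated]
bands = [[750.0, 180.0, 18500.0]]   # relaxes to 720 nm
shift_amplitude = 30.0
shift_tau = 1.0e-12

[spectra.e_pair]
bands = [[675.0, 180.0, 18500.0]]   # pair-bound electron, blue of the separated one; relaxes to 660 nm
shift_amplitude = 15.0
shift_tau = 1.0e-12

[spectra.cation]
bands = [[580.0, 150.0, 3000.0], [340.0, 60.0, 12000.0]]

[spectra.indolyl]
bands = [[330.0, 40.0, 8000.0], [520.0, 120.0, 1500.0]]

[spectra.triplet]
bands = [[440.0, 60.0, 5000.0]]

[spectra.La_esa]
bands = [[360.0, 50.0, 9000.0], [450.0, 120.0, 3500.0], [580.0, 150.0, 2500.0]]

[spectra.Lb_esa]
bands = [[375.0, 60.0, 7000.0]]

[spectra.H_adduct]
bands = [[367.0, 25.0, 4000.0], [400.0, 30.0, 4500.0]]

[masks]
# pump-scatter wavelength windows excluded from synthetic TA matrices, nm
nm_292 = [[560.0, 580.0]]
nm_268_H = [[415.0, 430.0]]
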