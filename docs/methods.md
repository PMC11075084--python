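# Methods

## The kinetic model

Photoexcited indole is described by nine compartments: `Lb`, `La` (the two
low-lying ¹ππ* states), `pair` (the contact ion pair ¹[Ind⁺:e⁻]), `e_sep`
(separated solvated electron), `cation` (separated indole cation),
`triplet`, `H_atom`, `adduct`, and `ground`. Populations are per absorbed
photon. The reactions:

| step | rate law | notes |
|---|---|---|
| ¹Lb → ¹La | k_LbLa·[Lb] | internal conversion, 1/(0.8 ps) |
| ¹La → ground | (k_rad + k_ic)·[La] | radiative + internal conversion |
| ¹La ⇌ pair | k_pair_f, k_pair_b | fast pre-equilibrium, K = k_pair_f/k_pair_b |
| pair → e_sep + cation | k_diss·[pair] | rate-limiting dissociation |
| pair + scavenger | k_scav_pair_X·c·[pair] | removes the bound electron, leaves the cation (+ H• for H⁺) |
| e_sep + scavenger | k_scav_X·c·[e_sep] | pseudo-first order (+ H• for H⁺) |
| e_sep + cation | k_rec2·c_exc·[e][cation] | homogeneous free-ion recombination; branch f_T → triplet, 1−f_T → ground |
| geminate (200 nm only) | λ(t)·min([e],[cation]) | escape-fraction kinetics, see below |
| H• + cation → adduct | k_adduct·c_exc·[H][cation] | |
| triplet → ground | k_T·[triplet] | 1/(15 μs), deaerated |

**Initial conditions.** 268 nm populates ¹La:¹Lb = 3:1; 292 nm populates them
equally; 200 nm in water sends a prompt fraction φ_prompt = 0.55 directly
into separated electron/cation pairs and the remainder into hot ¹Lb.
Ethanol supports no ionization at any wavelength: only ¹La/¹Lb exist, and a
single lifetime (below) governs the decay.

**Population bookkeeping.** A dissociation event turns one `pair` unit into
one `e_sep` *and* one `cation` unit — the two sides of one photoionization
event. Conservation is therefore enforced on the indole-centred ledger
(`Lb + La + pair + cation + triplet + adduct + ground = 1` at all times,
checked to 1e−6); `e_sep` and `H_atom` are electron-side species that mirror
the cation bookkeeping. `ConcentrationMatrix.conservation_defect()` reports
the ledger deviation.

**Bilinear steps.** Free-ion recombination and adduct formation are
second-order; per-photon fractions are scaled by the excited molar
concentration `c_exc` carried by the scheme. Re-formation of the singlet
pair upon re-encounter is excluded: the TCSPC experiments that anchor the
model show no delayed fluorescence component, so recombination branches
only to triplet (f_T) and ground (1−f_T).

**Geminate recombination (200 nm).** Prompt, ballistically separated pairs
recombine with escape-fraction survival S(t) = ω + (1−ω)·exp(−k_gem·t),
implemented as the time-dependent first-order rate λ(t) = −S′/S applied to
the electron and cation compartments (branching f_T/1−f_T like free-ion
recombination, which reproduces the growing 440 nm shoulder in the 200 nm
surfaces). Distance-resolved Smoluchowski/Onsager theory is deliberately out
of scope; the escape-fraction form is the minimal model with the right
phenomenology.

## Default parameters and their calibration

Fixed defaults (in `defaults.toml`, SI units): k_LbLa = 1.25e12 s⁻¹,
k_rad = 5.0e7 s⁻¹, k_pair_b = 1.0e11 s⁻¹ (fast pre-equilibrium),
K_pair = 0.25, k_rec2 = 3.0e10 M⁻¹s⁻¹, f_T = 0.65, k_T = 1/(15 μs),
k_scav_H = 1.0e10, k_scav_NO3 = 7.6e9, k_scav_pair_H = 4.45e9,
k_scav_pair_NO3 = 7.6e9, k_adduct = 1.0e10 M⁻¹s⁻¹, k_gem = 1/(120 ps),
φ_prompt(200 nm) = 0.55, dE_sep = 0.2 eV, dE_pair = 0.03 eV.

Two water parameters are *solved at build time* rather than stored:

1. **k_ic** such that the slow decay eigenvalue of the {¹La, pair}
   subsystem equals 1/τ_fl with τ_fl = 4.56 ns (the TCSPC lifetime);
2. **k_diss** such that the surviving separated-electron fraction at a 1 μs
   horizon — free-ion recombination active at the default femtosecond-regime
   c_exc = 1.2e−4 M — equals Φ_e⁻ = 0.2.

With the defaults this lands at k_diss ≈ 7.7e8 s⁻¹ and k_ic ≈ 3.2e7 s⁻¹,
i.e. ~71% of ¹La decay proceeds through pair dissociation. That dominance is
the point of the mechanism (the fluorescence lifetime is *rate-limited* by
dissociation) and is what makes the temperature behaviour come out right
(below). The implied triplet yield, f_T × (recombined fraction) ≈ 0.31–0.33,
falls inside the 0.23–0.35 range known for aqueous indole.

Remaining calibrated constants, solved once against the full forward model
and stored:

* **ω_escape = 0.451** — chosen so the simulated 633 nm transient in the
  200 nm branch loses 25% of its intensity between 2 and 500 ps. (The naive
  two-species estimate would give ω ≈ 0.75; the full surface also carries
  ¹La/pair ESA from the 45% non-ionized channel, whose pair band grows at
  633 nm and partially offsets the geminate decay.) The long-time prompt
  ionization yield φ_prompt·ω ≈ 0.25 sits at the low edge of the 0.3–0.4
  literature range for deep-UV ionization.
* **c_exc (nanosecond regime) = 1.50e−2 M** — chosen so the simulated
  440 nm band grows by 40% between 10 and 500 ns after the 5 ns IRF.
  Homogeneous second-order kinetics with a diffusion-limited k_rec2
  underestimates the encounter frequency of geminately-correlated ion
  pairs, so reproducing the observed ~100 ns triplet rise requires an
  effective ion-encounter rate k_rec2·c_exc·[e] of order 1e8 s⁻¹ — hence an
  effective concentration well above a realistic excitation density. The
  trade-off (documented, not hidden) is that electron survival in the
  nanosecond simulations is compressed relative to experiment.
* **τ_fl(ethanol) = 4.615 ns** = 750 ps / ln(1/0.85), so the total singlet
  population decays exactly 15% over the first 750 ps.

## Temperature rescaling

`temperature_rescale` moves the default 298.15 K rate set to T ∈
[270, 360] K:

* K_pair follows van't Hoff with the pair endothermicity dE_pair = 0.03 eV
  (applied to k_pair_f);
* k_diss carries an Arrhenius factor with activation dE_sep − dE_pair =
  0.17 eV — the residual uphill step from the pair to the separated ions —
  times the Stokes–Einstein diffusional factor (T/η, from a built-in water
  viscosity table, 273–373 K at 5 K steps, linearly interpolated);
* all diffusion-limited bimolecular constants scale with T/η alone.

The composite K_pair·k_diss therefore follows the full 0.2 eV van't Hoff
factor (×3.20 from 278 to 323 K) on top of diffusion. Because dissociation
dominates the ¹La decay, the predicted fluorescence-quantum-yield ratio
Φ(5 °C)/Φ(50 °C) ≈ 4.9, consistent with the reported factor of ~5. A
viscosity-only rescaling of k_diss (the obvious alternative) predicts a
ratio of only ~1.3–2.6 and was rejected for that reason.

## Species spectra

Each species is a sum of 1–3 Gaussian bands ε(λ) (centre, FWHM, amplitude
in M⁻¹cm⁻¹). Defaults: e_separated (nascent 750 nm, FWHM 180, 18 500 —
amplitude anchored to the re-evaluated extinction coefficient of the
aqueous electron — relaxing to 720 nm), e_pair (nascent 675 → 660 nm, same
width/amplitude; the contact-pair electron absorbs blue of the separated
one — its spectrum is otherwise unmeasured, so the 60 nm offset is a
declared stand-in), cation (580/150/3000 + 340/60/12000), indolyl
(330/40/8000 + 520/120/1500), triplet (440/60/5000), La_esa
(360/50/9000 + 450/120/3500 + 580/150/2500), Lb_esa (375/60/7000),
H_adduct (367/25/4000 + 400/30/4500). These are qualitative digitizations
of published transient spectra: band *centres* carry the physics; absolute
amplitudes are shape stand-ins.

Solvation dynamics: only the electron species shift, with
c(t) = c₀ − A·(1 − e^(−t/τ)), τ = 1 ps, A = 30 nm (separated) / 15 nm
(pair — "more modest shifting"). The shift moves oscillator strength
without creating it (band integral conserved to <0.1%). Spectra are
evaluated over 300–800 nm and extrapolated by the same Gaussians outside
(no clipping). Vibrationally hot states are not separate compartments;
cooling enters only through this spectral shift.

## Forward model

ΔOD(λ,t) = 1000·L·c_exc·Σᵢ εᵢ(λ, t−t_birth,i)·pᵢ(t) in mOD, convolved along
t with a Gaussian IRF on a uniform internal grid (step = FWHM/10, padded
±6σ; `scipy.ndimage.gaussian_filter1d`). A species' solvation clock starts
at its first nonzero population. Pre-zero delay points carry the
IRF-broadened onset. Ground-state bleach and stimulated emission are not
modelled (the analysed regions are ESA/product dominated); `H_atom` and
`ground` absorb nothing in the probe window. No chirp, coherent artifacts
or anisotropy.

TCSPC: the expected rate ∝ k_rad·[¹La](t) (or a supplied decay law) is
IRF-convolved and multinomially sampled to exactly the requested total
counts — seeded and bitwise reproducible.

Stiff integration uses LSODA with rtol 1e−8 / atol 1e−12; populations are
clipped at zero on output (tolerance −1e−12).

## Synthetic data

Default femtosecond grids: 120 wavelengths over 320–750 nm; 150 delays
log-spaced 50 fs–750 ps plus 5 pre-zero points; nanosecond regime: 200
points, 5 ns–100 μs. Default noise: i.i.d. Gaussian, σ = 0.15 mOD (a
typical TA noise floor — a stand-in, like everything about the noise
model: no detector nonlinearity, correlated pump noise, or chirp).
Pump-scatter masks (cells set to NA, never 0): 560–580 nm for 292 nm
excitation; 415–430 nm for the 268 nm + HCl design. One master seed;
per-trace substreams by fixed offsets, so each series member is
individually reproducible. Every dataset carries its generating scheme and
geometry as a TOML-serializable truth sidecar.

TCSPC quenching series construct their truth lifetimes directly from rate
additivity, 1/τ(c) = 1/τ₀ + k_scav_pair·c, with the printed bimolecular
constants as the lifetime slopes (in ethanol the quencher has no ion pair
to attack and τ is invariant). Inside the compartment model a
pair-compartment rate k produces a lifetime slope K/(1+K)·k instead; which
microscopic convention is right is genuinely unresolved, so the generator
reproduces the *observable* law and the discrepancy is stated here rather
than papered over.

## Inference

* **Reconvolution fits** use the exact Gaussian⊗exponential kernel
  (erfcx-stabilized). Lifetimes start log-spaced across the data window
  with three deterministic perturbed restarts; amplitudes are solved
  linearly at each trial (variable projection); lifetimes return sorted
  ascending. For counting data the least-squares solution is refined by
  Poisson maximum likelihood (deviance residuals) — weighting by observed
  counts is measurably biased (~−1% on τ at 1e6 counts) on low-count tails.
* **Stern–Volmer** regression is done in the rate domain (1/τ vs c), which
  is linear in k_q; weighted when lifetime uncertainties are supplied.
* **Spectral decomposition** uses non-negative least squares, because
  populations are physically non-negative; coefficients are per-photon
  fractions given the Beer–Lambert scaling, hence invariant under
  rescaling of L·c_exc at fixed product. Masked cells are excluded.
* **Global target analysis** nests NNLS inside a nonlinear search over
  log-rates (xtol 1e−12, max 500 iterations). Two projection modes:
  `free` solves one unconstrained non-negative spectrum per species and
  wavelength (classic species-associated spectra) — appropriate when each
  species has a kinetically distinct profile; `library` fits one amplitude
  per known band shape — far fewer linear degrees of freedom, which is
  what pins weakly identifiable rates on a 750 ps window (a fully free
  spectral model can absorb most of a k_diss change there, a genuine
  identifiability limit of the short-window experiment, not of the code).
  Near-singular projections or normal matrices (condition > 1e10/1e12)
  return the fit with `covariance_available=False`.
* **Quantum yields**: Φ_fl = k_rad·∫[¹La]dt; Φ_e⁻ = surviving `e_sep` at
  the horizon; Φ_T = triplet formed by the horizon with its own decay
  deconvolved (T(h) + k_T·∫T dt); the non-radiative ground recovery closes
  the balance to 1 ± 1e−4 for closed schemes.

## Problem sizes

The shipped test-suite and reproduction scenarios use 40-wavelength ×
80-delay synthetic matrices for fitting studies, 120 × 155 for noise
statistics, 3000–4000-point propagation grids for kinetic traces, 4096 ×
12.2 ps TCSPC histograms at 1e6 counts, and 100 random rate triples for
the ODE-vs-oracle check; the full suite runs in well under a minute of
ODE time on one core.

## Known limitations

* Homogeneous second-order recombination stands in for spur/geminate
  kinetics everywhere except the explicit 200 nm escape model. Consequences:
  the nanosecond-regime c_exc is an effective (calibrated) parameter, and
  the H-atom/cation adduct — in reality formed between geminately close
  partners — accumulates only ~1e−5 per photon by 750 ps, so its 367/400 nm
  bands are present but much weaker than in the measured acid surfaces.
* The contact-pair electron spectrum is a stand-in (no measurement exists);
  its 60 nm blue offset affects where the early-time "blue-shifted 600 nm"
  amplitude appears but no calibrated observable.
* The split of the 0.2 eV endothermicity into dE_pair = 0.03 eV and
  dE_sep = 0.2 eV is a modelling choice; only the composite is constrained
  by the temperature behaviour.
* Passing tests on synthetic data demonstrate internal consistency and
  estimator correctness under the stated noise model — not that the
  parameter values are the true ones for real indole data, whose analysis
  (chirp, bleach, multiphoton solvent ionization, electronic-structure
  calculations) is outside this package's scope.
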