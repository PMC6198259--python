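# Case-study parameterisations (synthetic reconstruction).
#
# blowflies: the classic laboratory sheep-blowfly culture parameterisation
# (Gurney, Blythe & Nisbet's fit to Nicholson's data): total egg-to-adult
# delay 15.6 d split over four juvenile stages, adult per-capita mortality
# 0.27 /d, maximum fecundity 8.5 eggs/adult/d with exponential density
# dependence on the adult population at scale 600 adults.  The original
# supplementary simulation script was not available when this file was
# written; these are the published values of the source model it encodes.
blowflies:
  egg_duration_days: 0.6
  larva_duration_days: 5.0
  pupa_duration_days: 5.9
  immature_duration_days: 4.1
  egg_daily_survival: 1.0
  larva_daily_survival: 1.0
  pupa_daily_survival: 1.0
  immature_daily_survival: 1.0
  adult_daily_mortality: 0.27
  fecundity_per_adult_day: 8.5
  fecundity_scale_adults: 600.0
  initial_adults: 500.0
  alpha: 10
  horizon_days: 400

# Host-parasitoid interaction in discrete generations.  searching_efficiency
# is the parasitoid's area of discovery `a` in the escape term exp(-a P).
nicholson_bailey:
  reproduction: 2.0
  searching_efficiency: 0.02
  juvenile_stage_length: 1
  adult_survival_prob: 0.8
  initial_hosts: 60.0
  initial_parasites: 30.0
  generations: 120

# Plague-outbreak style SIR with a gamma-distributed infectious period.
# transmission is per infectious individual per day (mass action on counts);
# the default infectious period is moderately age-dependent.
eyam_sir:
  transmission_per_day: 5.85e-4
  infectious_mean_days: 11.71
  infectious_sd_days: 5.85
  initial_susceptible: 254
  initial_infectious: 7
  horizon_days: 180
  alpha: 1
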