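# Heavy-ion accelerator beam definitions (facility exposure parameters).
# mass_amu/atomic_number feed the Rutherford cross-section ratio; dose rates
# feed irradiation-duration arithmetic.
He:
  name: He
  mass_amu: 4.0
  atomic_number: 2
  energy_mev_per_nucleon: 150.0
  let_kev_per_um: 2.2
  dose_rate_gy_per_min: 4.2
Ar:
  name: Ar
  mass_amu: 40.0
  atomic_number: 18
  energy_mev_per_nucleon: 500.0
  let_kev_per_um: 90.0
  dose_rate_gy_per_min: 6.8
Fe:
  name: Fe
  mass_amu: 55.9
  atomic_number: 26
  energy_mev_per_nucleon: 500.0
  let_kev_per_um: 200.0
  dose_rate_gy_per_min: 12.1
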