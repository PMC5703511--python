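{
  "F18": {
    "qy": 0.97,
    "eps_max": 92300.0,
    "eps_max_wavelength": 500.0,
    "eps_at": {"465": 34645.0, "488": 71371.0},
    "emission_max_nm": 517.0,
    "excited_state_lifetime_ns": 5.0
  },
  "MitoTracker Red": {
    "qy": 0.43,
    "eps_max": 117000.0,
    "eps_max_wavelength": 578.0,
    "eps_at": {"465": 1671.0, "488": 3882.0, "560": 54764.0},
    "emission_max_nm": 598.0,
    "excited_state_lifetime_ns": 1.8
  },
  "ATTO647N": {
    "qy": 0.65,
    "eps_max": 150000.0,
    "eps_max_wavelength": 646.0,
    "eps_at": {"465": 750.0, "488": 900.0, "560": 10650.0, "633": 103500.0},
    "emission_max_nm": 664.0,
    "excited_state_lifetime_ns": 3.5
  },
  "Eu": {
    "qy": 0.052,
    "eps_max": 2.8,
    "eps_max_wavelength": 390.0,
    "eps_at": {"465": 0.37, "488": 0.035},
    "emission_max_nm": 616.0,
    "excited_state_lifetime_ns": 500000.0
  },
  "Tb": {
    "qy": 0.27,
    "eps_max": 320.0,
    "eps_max_wavelength": 220.0,
    "eps_at": {"488": 0.071},
    "emission_max_nm": 544.0,
    "excited_state_lifetime_ns": 1500000.0
  }
}
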