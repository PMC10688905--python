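{
  "_note": "Default model inputs: 90-day outcome distributions and acute-event proportions from the BAOCHE trial, long-term transition probabilities from published anterior-circulation stroke cohorts, Chinese life-table background mortality, and Chinese healthcare-system costs/utilities in 2021 USD. Entries without an uncertainty range (low == high) are held fixed in sensitivity analyses.",
  "efficacy": {
    "dist_sr": {
      "nondisabling": {"point": 0.39091, "low": 0.29972, "high": 0.4821},
      "disabling": {"point": 0.3, "low": 0.261, "high": 0.351},
      "dead": {"point": 0.30909, "low": 0.22273, "high": 0.39545}
    },
    "dist_bmm": {
      "nondisabling": {"point": 0.14019, "low": 0.0744, "high": 0.20597},
      "disabling": {"point": 0.43925, "low": 0.34521, "high": 0.53329},
      "dead": {"point": 0.42056, "low": 0.32702, "high": 0.5141}
    },
    "rr_mrs02": {"point": 2.79, "low": 1.65, "high": 4.71},
    "rr_mrs35": {"point": 0.68, "low": 0.48, "high": 0.98},
    "rr_mrs6": {"point": 0.73, "low": 0.51, "high": 1.05}
  },
  "acute": {
    "p_ivt_sr": {"point": 0.13636, "low": 0.07223, "high": 0.2005},
    "p_ivt_bmm": {"point": 0.21495, "low": 0.13712, "high": 0.29279},
    "p_sich_sr": {"point": 0.05882, "low": 0.01316, "high": 0.10449},
    "p_sich_bmm": {"point": 0.01136, "low": 0.0, "high": 0.03351}
  },
  "transitions": {
    "first_year": {
      "nondisabling": {"nondisabling": 0.955, "disabling": 0.024, "recurrent": 0.013, "dead": 0.008},
      "disabling": {"nondisabling": 0.029, "disabling": 0.919, "recurrent": 0.013, "dead": 0.039}
    },
    "after_first_year": {
      "nondisabling": {"nondisabling": 0.979, "disabling": 0.0, "recurrent": 0.013, "dead": 0.008},
      "disabling": {"nondisabling": 0.0, "disabling": 0.948, "recurrent": 0.013, "dead": 0.039}
    },
    "recurrent_from_nondisabling": {"nondisabling": 0.834, "disabling": 0.137, "dead": 0.029},
    "recurrent_from_disabling": {"disabling": 0.971, "dead": 0.029}
  },
  "mortality": {
    "annual": {"60": 0.00734, "65": 0.01218, "70": 0.02081, "75": 0.03604, "80": 0.06503, "85": 0.14828},
    "rr_nonstroke_disabled": {"point": 1.68, "low": 1.49, "high": 1.92}
  },
  "costs": {
    "sr_additional": {"point": 11695, "low": 10059, "high": 13520},
    "ivt_additional": {"point": 1720, "low": 848, "high": 2529},
    "annual_nondisabling": {"point": 1420, "low": 1376, "high": 1465},
    "annual_disabling": {"point": 2182, "low": 1965, "high": 2323},
    "acute_bmm_nondisabling": {"point": 1933, "low": 1905, "high": 1962},
    "acute_bmm_disabling": {"point": 2640, "low": 2582, "high": 2699},
    "acute_bmm_death": {"point": 2138, "low": 1965, "high": 2323},
    "recurrent_event": {"point": 1599, "low": 800, "high": 2399},
    "sich_event": {"point": 3507, "low": 3323, "high": 3700}
  },
  "utilities": {
    "u_nondisabling": {"point": 0.76, "low": 0.69, "high": 0.82},
    "u_disabling": {"point": 0.21, "low": 0.17, "high": 0.26},
    "u_recurrent": {"point": 0.42, "low": 0.11, "high": 0.71},
    "u_dead": {"point": 0.0, "low": 0.0, "high": 0.0}
  },
  "settings": {
    "discount_rate_cost": {"point": 0.05, "low": 0.0, "high": 0.08},
    "discount_rate_utility": {"point": 0.05, "low": 0.0, "high": 0.08},
    "horizon_years": 20,
    "cycle_years": 0.25,
    "start_age": 64,
    "wtp_low": 12551,
    "wtp_high": 37654
  }
}
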