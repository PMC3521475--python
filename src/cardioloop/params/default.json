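{
  "network": {
    "compartments": [
      {
        "name": "systemic_arteries",
        "compliance": 1.88,
        "unstressed_volume": 600.0,
        "initial_volume": 778.6,
        "external_pressure_source": "ambient"
      },
      {
        "name": "systemic_veins",
        "compliance": 45.0,
        "unstressed_volume": 3264.0,
        "initial_volume": 3280.0,
        "external_pressure_source": "ambient"
      },
      {
        "name": "right_atrium",
        "compliance": 10.0,
        "unstressed_volume": 20.0,
        "initial_volume": 90.0,
        "external_pressure_source": "intrathoracic"
      },
      {
        "name": "pulmonary_arteries",
        "compliance": 8.0,
        "unstressed_volume": 60.0,
        "initial_volume": 215.0,
        "external_pressure_source": "intrathoracic"
      },
      {
        "name": "left_atrium",
        "compliance": 28.0,
        "unstressed_volume": 40.0,
        "initial_volume": 350.0,
        "external_pressure_source": "intrathoracic"
      }
    ],
    "resistors": [
      {
        "name": "aortic_valve",
        "upstream": "lv",
        "downstream": "systemic_arteries",
        "resistance": 0.013,
        "one_way": true
      },
      {
        "name": "systemic_peripheral",
        "upstream": "systemic_arteries",
        "downstream": "systemic_veins",
        "resistance": 0.88,
        "one_way": false
      },
      {
        "name": "venous_return",
        "upstream": "systemic_veins",
        "downstream": "right_atrium",
        "resistance": 0.05,
        "one_way": false
      },
      {
        "name": "tricuspid_valve",
        "upstream": "right_atrium",
        "downstream": "rv",
        "resistance": 0.01,
        "one_way": true
      },
      {
        "name": "pulmonary_valve",
        "upstream": "rv",
        "downstream": "pulmonary_arteries",
        "resistance": 0.01,
        "one_way": true
      },
      {
        "name": "pulmonary_peripheral",
        "upstream": "pulmonary_arteries",
        "downstream": "left_atrium",
        "resistance": 0.06,
        "one_way": false
      },
      {
        "name": "mitral_valve",
        "upstream": "left_atrium",
        "downstream": "lv",
        "resistance": 0.01,
        "one_way": true
      }
    ],
    "ventricles": {
      "lv": {
        "nominal_gain": 100.0,
        "e_max_ref": 1.75,
        "systole_duration": 0.2,
        "activation_shape": "skewed_half_sine",
        "passive_compliance": 32.0,
        "diastolic_relaxation_tau": 0.05,
        "limiter_max": 8.0,
        "inotropic_slope": 1.0,
        "unstressed_volume": 15.0,
        "initial_volume": 130.0,
        "output_series_resistance": 0.0,
        "external_pressure_source": "intrathoracic",
        "activation_skew": 1.58
      },
      "rv": {
        "nominal_gain": 100.0,
        "e_max_ref": 0.7,
        "systole_duration": 0.2,
        "activation_shape": "skewed_half_sine",
        "passive_compliance": 15.0,
        "diastolic_relaxation_tau": 0.05,
        "limiter_max": 8.0,
        "inotropic_slope": 1.0,
        "unstressed_volume": 10.0,
        "initial_volume": 130.0,
        "output_series_resistance": 0.0,
        "external_pressure_source": "intrathoracic",
        "activation_skew": 1.58
      }
    },
    "respiration": {
      "mean_itp": -4.0,
      "amplitude": 1.0,
      "period": 4.0,
      "waveform": "sinusoid"
    }
  },
  "control": {
    "maop_setpoint": 102.11,
    "maop_filter_tau": 2.5,
    "feedback_gain": 0.13,
    "sy_baseline": 1.0,
    "sy_range": [
      0.0,
      8.0
    ],
    "sy_tau": 7.5,
    "hr_base": 75.0,
    "hr_per_fgu": 25.0,
    "hr_bounds": [
      40.0,
      124.0
    ],
    "venous_ml_per_fgu": 330.0,
    "co_filter_tau": 3.0,
    "switches": {
      "hr": true,
      "lv_inotropy": true,
      "rv_inotropy": true,
      "venous_tone": true
    },
    "clamps": {},
    "venous_max_delta": 520.0
  }
}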