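{
  "rules": {
    "kurtosis_sqi": {
      "boundaries": [
        {"op": ">", "value": 2.6, "decision": "reject"}
      ],
      "na_decision": "reject"
    },
    "dtw_sqi_mean": {
      "boundaries": [
        {"op": ">", "value": 0.04, "decision": "reject"}
      ],
      "na_decision": "reject"
    },
    "acf_prom_1": {
      "boundaries": [
        {"op": "<", "value": 0.9, "decision": "reject"}
      ],
      "na_decision": "reject"
    },
    "msq_sqi": {
      "boundaries": [
        {"op": "<", "value": 0.7, "decision": "reject"}
      ],
      "na_decision": "reject"
    },
    "ectopic_sqi": {
      "boundaries": [
        {"op": ">", "value": 0.1, "decision": "reject"}
      ],
      "na_decision": "reject"
    }
  },
  "order": ["kurtosis_sqi", "dtw_sqi_mean", "acf_prom_1", "msq_sqi", "ectopic_sqi"],
  "combination": "all_accept"
}
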