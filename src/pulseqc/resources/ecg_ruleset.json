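{
  "rules": {
    "msq_sqi": {
      "boundaries": [
        {"op": "<", "value": 0.7, "decision": "reject"}
      ],
      "na_decision": "reject"
    },
    "acf_prom_1": {
      "boundaries": [
        {"op": "<", "value": 0.5, "decision": "reject"}
      ],
      "na_decision": "reject"
    },
    "ectopic_sqi": {
      "boundaries": [
        {"op": ">", "value": 0.2, "decision": "reject"}
      ],
      "na_decision": "reject"
    }
  },
  "order": ["msq_sqi", "acf_prom_1", "ectopic_sqi"],
  "combination": "all_accept"
}
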