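{
  "directions": {
    "TMT_A": 1,
    "TMT_B": 1,
    "FACTCOG_PCI": -1,
    "FACTCOG_QOL": -1,
    "FACTCOG_OTH": -1,
    "FACTCOG_PCA": -1,
    "RAVLT_IMMEDIATE": -1,
    "RAVLT_LEARNING": -1,
    "RAVLT_DELAYED": -1,
    "RAVLT_PERCENT_FORGETTING": 1,
    "RAVLT_TRUE_RECOGNITION": -1,
    "RAVLT_LOT": -1,
    "IPQR_IDENTITY": 1,
    "IPQR_CONSEQUENCES": 1,
    "IPQR_TIMELINE_ACUTE_CHRONIC": 1,
    "IPQR_TIMELINE_CYCLICAL": 1,
    "IPQR_PERSONAL_CONTROL": -1,
    "IPQR_TREATMENT_CONTROL": -1,
    "IPQR_COHERENCE": -1,
    "HAD_ANXIETY": 1,
    "HAD_DEPRESSION": 1,
    "CLCS_CONTROL_COURSE": -1,
    "CLCS_RELIGIOUS_CONTROL": -1,
    "CLCS_CONTROL_CAUSE": 1,
    "EORTC_GLOBAL_QOL": -1,
    "EORTC_PHYSICAL_FUNCTIONING": -1,
    "EORTC_ROLE_FUNCTIONING": -1,
    "EORTC_EMOTIONAL_FUNCTIONING": -1,
    "EORTC_COGNITIVE_FUNCTIONING": -1,
    "EORTC_SOCIAL_FUNCTIONING": -1,
    "EORTC_FATIGUE": 1,
    "EORTC_NAUSEA_VOMITING": 1,
    "EORTC_PAIN": 1,
    "EORTC_DYSPNOEA": 1,
    "EORTC_INSOMNIA": 1,
    "EORTC_APPETITE_LOSS": 1,
    "EORTC_CONSTIPATION": 1,
    "EORTC_DIARRHOEA": 1,
    "EORTC_FINANCIAL_DIFFICULTIES": 1,
    "PSQI_GLOBAL": 1,
    "EPICES": 1
  },
  "instruments": {
    "DN4": {
      "score_range": [0, 10],
      "direction": 1,
      "cutpoints": [{"threshold": 4, "new_category_includes_threshold": true}],
      "categories": ["no neuropathic pain", "neuropathic pain"]
    },
    "HAD": {
      "score_range": [0, 21],
      "direction": 1,
      "cutpoints": [
        {"threshold": 8, "new_category_includes_threshold": true},
        {"threshold": 11, "new_category_includes_threshold": true}
      ],
      "categories": ["normal", "moderate", "severe"]
    },
    "PSQI": {
      "score_range": [0, 21],
      "direction": 1,
      "cutpoints": [{"threshold": 5, "new_category_includes_threshold": false}],
      "categories": ["no sleep disorder", "sleep disorder"]
    },
    "EPICES": {
      "score_range": [0, 100],
      "direction": 1,
      "cutpoints": [{"threshold": 30.2, "new_category_includes_threshold": true}],
      "categories": ["not precarious", "precarious"]
    }
  }
}
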