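{
  "version": "1.0",
  "description": "Default allowed-code sets and date layouts for the seven core death-certificate topics, mirroring the Mortality Information System (SIM/MIS) codification conventions. Editable: pass a file with the same structure to override.",
  "categorical": {
    "place_of_occurrence": {
      "allowed": ["1", "2", "3", "4", "5", "9"],
      "labels": {
        "1": "hospital",
        "2": "other health facility",
        "3": "home",
        "4": "public road",
        "5": "other",
        "9": "ignored"
      }
    },
    "certifier": {
      "allowed": ["1", "2", "3", "4", "5", "9"],
      "labels": {
        "1": "attending physician",
        "2": "substitute physician",
        "3": "forensic institute (IML)",
        "4": "death verification service (SVO)",
        "5": "other",
        "9": "ignored"
      }
    },
    "sex": {
      "allowed": ["1", "2", "0"],
      "labels": {
        "1": "male",
        "2": "female",
        "0": "ignored"
      }
    },
    "marital_status": {
      "allowed": ["1", "2", "3", "4", "5", "9"],
      "labels": {
        "1": "single",
        "2": "married",
        "3": "widowed",
        "4": "legally separated",
        "5": "consensual union",
        "9": "ignored"
      }
    }
  },
  "dates": {
    "date_of_occurrence": {"layout": "DDMMYYYY"},
    "date_of_registration": {"layout": "DDMMYYYY"},
    "date_of_birth": {"layout": "DDMMYYYY"}
  }
}
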