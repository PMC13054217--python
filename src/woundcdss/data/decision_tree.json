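{
  "version": "1.0",
  "root": "phase",
  "nodes": {
    "phase": {
      "question": "phase",
      "branches": {
        "acute": "acute_infection",
        "chronic": "chronic_infection"
      }
    },
    "acute_infection": {
      "question": "infection",
      "branches": {
        "absent": "leaf_acute",
        "present": "leaf_acute_infected"
      }
    },
    "leaf_acute": {
      "payload": {"ointment": 5, "dressing": 4}
    },
    "leaf_acute_infected": {
      "payload": {"ointment": 2, "dressing": 6},
      "extension": true
    },
    "chronic_infection": {
      "question": "infection",
      "branches": {
        "present": "leaf_infected",
        "absent": "pocket"
      }
    },
    "leaf_infected": {
      "payload": {"ointment": 2, "dressing": 6}
    },
    "pocket": {
      "question": "pocket",
      "branches": {
        "present_with_necrosis": "leaf_pocket",
        "absent": "necrosis"
      }
    },
    "leaf_pocket": {
      "payload": {"ointment": 4, "dressing": 6}
    },
    "necrosis": {
      "question": "necrosis",
      "branches": {
        "black_dry": "black_exudate",
        "yellow_moist": "yellow_exudate",
        "none": "depth"
      }
    },
    "black_exudate": {
      "question": "exudate",
      "branches": {
        "minimal": "leaf_black_dry",
        "high": "leaf_black_wet"
      }
    },
    "leaf_black_dry": {
      "payload": {"ointment": 1, "dressing": 5}
    },
    "leaf_black_wet": {
      "payload": {"ointment": 2, "dressing": 6},
      "extension": true
    },
    "yellow_exudate": {
      "question": "exudate",
      "branches": {
        "minimal": "leaf_yellow_dry",
        "high": "leaf_yellow_wet"
      }
    },
    "leaf_yellow_dry": {
      "payload": {"ointment": 2, "dressing": 5},
      "extension": true
    },
    "leaf_yellow_wet": {
      "payload": {"ointment": 2, "dressing": 6},
      "extension": true
    },
    "depth": {
      "question": "depth",
      "branches": {
        "shallow": "surface",
        "deep": "deep_exudate"
      }
    },
    "surface": {
      "question": "surface",
      "branches": {
        "intact_blister": "leaf_blister",
        "erosion_shallow_ulcer": "leaf_shallow",
        "open_deep_ulcer": "leaf_shallow"
      }
    },
    "leaf_blister": {
      "payload": {"ointment": 5, "dressing": 4}
    },
    "leaf_shallow": {
      "payload": {"ointment": 5, "dressing": 3}
    },
    "deep_exudate": {
      "question": "exudate",
      "branches": {
        "minimal": "leaf_deep_dry",
        "high": "leaf_deep_wet"
      }
    },
    "leaf_deep_dry": {
      "payload": {"ointment": 6, "dressing": 3}
    },
    "leaf_deep_wet": {
      "payload": {"ointment": 3, "dressing": 1}
    }
  }
}
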