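{
  "version": "1.0",
  "entries": {
    "1": {"ointment": 5, "dressing": 3},
    "2": {"ointment": 3, "dressing": 1},
    "3": {"ointment": 1, "dressing": 5},
    "4": {"ointment": 4, "dressing": 6},
    "5": {"ointment": 3, "dressing": 1},
    "6": {"ointment": 5, "dressing": 4},
    "7": {"ointment": 6, "dressing": 3},
    "8": {"ointment": 5, "dressing": 4},
    "9": {"ointment": 2, "dressing": 6},
    "10": {"ointment": 6, "dressing": 3}
  }
}
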