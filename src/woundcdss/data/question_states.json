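{
  "version": "1.0",
  "states": {
    "1": {
      "description": "erosion or shallow ulcer with damage limited to the dermis",
      "state": {"phase": "chronic", "depth": "shallow", "surface": "erosion_shallow_ulcer", "necrosis": "none", "infection": "absent", "pocket": "absent", "granulation": "not_applicable", "exudate": "minimal"}
    },
    "2": {
      "description": "deep ulcer with insufficient healthy granulation tissue and a high amount of exudate",
      "state": {"phase": "chronic", "depth": "deep", "surface": "open_deep_ulcer", "necrosis": "none", "infection": "absent", "pocket": "absent", "granulation": "insufficient", "exudate": "high"}
    },
    "3": {
      "description": "ulcer covered with dry black necrotic tissue, minimal exudate, no signs of infection",
      "state": {"phase": "chronic", "depth": "deep", "surface": "open_deep_ulcer", "necrosis": "black_dry", "infection": "absent", "pocket": "absent", "granulation": "not_applicable", "exudate": "minimal"}
    },
    "4": {
      "description": "ulcer with necrotic tissue in pockets but without signs of infection",
      "state": {"phase": "chronic", "depth": "deep", "surface": "open_deep_ulcer", "necrosis": "none", "infection": "absent", "pocket": "present_with_necrosis", "granulation": "not_applicable", "exudate": "minimal"}
    },
    "5": {
      "description": "deep ulcer with well-developed healthy granulation tissue and abundant exudate",
      "state": {"phase": "chronic", "depth": "deep", "surface": "open_deep_ulcer", "necrosis": "none", "infection": "absent", "pocket": "absent", "granulation": "healthy_sufficient", "exudate": "high"}
    },
    "6": {
      "description": "acute-stage pressure ulcer",
      "state": {"phase": "acute", "depth": "shallow", "surface": "erosion_shallow_ulcer", "necrosis": "none", "infection": "absent", "pocket": "absent", "granulation": "not_applicable", "exudate": "minimal"}
    },
    "7": {
      "description": "deep ulcer with insufficient granulation tissue and minimal exudate",
      "state": {"phase": "chronic", "depth": "deep", "surface": "open_deep_ulcer", "necrosis": "none", "infection": "absent", "pocket": "absent", "granulation": "insufficient", "exudate": "minimal"}
    },
    "8": {
      "description": "ulcer presenting with blisters",
      "state": {"phase": "acute", "depth": "shallow", "surface": "intact_blister", "necrosis": "none", "infection": "absent", "pocket": "absent", "granulation": "not_applicable", "exudate": "minimal"}
    },
    "9": {
      "description": "ulcer covered with yellow necrotic tissue, abundant exudate, clear signs of infection",
      "state": {"phase": "chronic", "depth": "deep", "surface": "open_deep_ulcer", "necrosis": "yellow_moist", "infection": "present", "pocket": "absent", "granulation": "not_applicable", "exudate": "high"}
    },
    "10": {
      "description": "deep ulcer with well-formed granulation tissue and minimal exudate",
      "state": {"phase": "chronic", "depth": "deep", "surface": "open_deep_ulcer", "necrosis": "none", "infection": "absent", "pocket": "absent", "granulation": "healthy_sufficient", "exudate": "minimal"}
    }
  }
}
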