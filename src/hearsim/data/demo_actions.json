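[
 {
  "action": "select_mode",
  "params": {
   "mode": "otoscopy"
  }
 },
 {
  "action": "oto_exam",
  "params": {
   "ear": "left"
  }
 },
 {
  "action": "oto_exam",
  "params": {
   "ear": "right"
  }
 },
 {
  "action": "select_mode",
  "params": {
   "mode": "tympanometry"
  }
 },
 {
  "action": "tymp_exam",
  "params": {
   "ear": "left"
  }
 },
 {
  "action": "tymp_exam",
  "params": {
   "ear": "right"
  }
 },
 {
  "action": "select_mode",
  "params": {
   "mode": "audiometry"
  }
 },
 {
  "action": "present_tone",
  "params": {
   "ear": "left",
   "frequency": 1000,
   "level": 20
  }
 },
 {
  "action": "present_tone",
  "params": {
   "ear": "left",
   "frequency": 2000,
   "level": 20
  }
 },
 {
  "action": "present_tone",
  "params": {
   "ear": "left",
   "frequency": 4000,
   "level": 20
  }
 },
 {
  "action": "present_tone",
  "params": {
   "ear": "right",
   "frequency": 1000,
   "level": 20
  }
 },
 {
  "action": "present_tone",
  "params": {
   "ear": "right",
   "frequency": 2000,
   "level": 20
  }
 },
 {
  "action": "present_tone",
  "params": {
   "ear": "right",
   "frequency": 4000,
   "level": 20
  }
 },
 {
  "action": "save_notes",
  "params": {
   "notes": {
    "otoscopy_left": {
     "result": "normal"
    },
    "otoscopy_right": {
     "result": "normal"
    },
    "tympanometry_left": {
     "result": "normal"
    },
    "tympanometry_right": {
     "result": "normal"
    },
    "audiometry_left": {
     "result": "pass"
    },
    "audiometry_right": {
     "result": "pass"
    },
    "final_recommendation": "pass",
    "final_comment": "Routine screen, subject attentive and responsive."
   }
  }
 }
]
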