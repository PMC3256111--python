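{
  "items": ["P1", "P2", "P3", "P4", "P5", "P6", "P7",
            "N1", "N2", "N3", "N4", "N5", "N6", "N7",
            "G1", "G2", "G3", "G4", "G5", "G6", "G7", "G8",
            "G9", "G10", "G11", "G12", "G13", "G14", "G15", "G16"],
  "subscales": {
    "Positive": ["P1", "P2", "P3", "P4", "P5", "P6", "P7"],
    "Negative": ["N1", "N2", "N3", "N4", "N5", "N6", "N7"],
    "General": ["G1", "G2", "G3", "G4", "G5", "G6", "G7", "G8",
                "G9", "G10", "G11", "G12", "G13", "G14", "G15", "G16"]
  },
  "option_min": 1,
  "option_max": 7,
  "labels": {
    "P1": "Delusions",
    "P2": "Conceptual Disorganization",
    "P3": "Hallucinatory Behaviour",
    "P4": "Excitement",
    "P5": "Grandiosity",
    "P6": "Suspiciousness/Persecution",
    "P7": "Hostility",
    "N1": "Blunted Affect",
    "N2": "Emotional Withdrawal",
    "N3": "Poor Rapport",
    "N4": "Passive Apathetic Social Withdrawal",
    "N5": "Difficulty in Abstract Thinking",
    "N6": "Lack of Spontaneity and Flow of Conversation",
    "N7": "Stereotyped Thinking",
    "G1": "Somatic Concern",
    "G2": "Anxiety",
    "G3": "Guilt Feelings",
    "G4": "Tension",
    "G5": "Mannerisms and Posturing",
    "G6": "Depression",
    "G7": "Motor Retardation",
    "G8": "Uncooperative",
    "G9": "Unusual Thought Content",
    "G10": "Disorientation",
    "G11": "Poor Attention",
    "G12": "Lack of Judgment/Insight",
    "G13": "Disturbance of Volition",
    "G14": "Poor Impulse Control",
    "G15": "Preoccupation",
    "G16": "Active Social Avoidance"
  }
}
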