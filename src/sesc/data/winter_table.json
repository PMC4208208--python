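{
  "name": "winter",
  "version": 1,
  "citation": "Winter, D.A., Biomechanics and Motor Control of Human Movement. Segment mass fractions of body mass, lengths as fractions of stature, CoM location as fraction of segment length from the proximal joint.",
  "notes": [
    "Merged-segment table for the 9-segment model: hands merged into forearms, feet into shanks, head+neck into the torso.",
    "forearm_hand: Winter's forearm+hand entry (mass 0.022, CoM 0.682 of forearm length).",
    "shank_foot: shank (mass 0.0465, CoM 0.433) plus the foot (mass 0.0145) treated as a point mass at the ankle; merged CoM fraction = (0.0465*0.433 + 0.0145)/0.061 = 0.5677786885245902 of shank length.",
    "torso: remainder mass (trunk 0.497 + head&neck 0.081 = 0.578); CoM at 0.66 of the hip->shoulder distance above the mid-hip, pulled up by the merged head.",
    "Length fractions follow the Drillis-Contini stature proportions."
  ],
  "segments": {
    "torso": {"mass_fraction": 0.578, "length_fraction": 0.288, "com_fraction": 0.66},
    "upper_arm": {"mass_fraction": 0.028, "length_fraction": 0.186, "com_fraction": 0.436},
    "forearm_hand": {"mass_fraction": 0.022, "length_fraction": 0.146, "com_fraction": 0.682},
    "thigh": {"mass_fraction": 0.1, "length_fraction": 0.245, "com_fraction": 0.433},
    "shank_foot": {"mass_fraction": 0.061, "length_fraction": 0.246, "com_fraction": 0.5677786885245902}
  },
  "shoulder_halfwidth_fraction": 0.129,
  "hip_halfwidth_fraction": 0.0955
}
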