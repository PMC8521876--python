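# Demonstrative assessment rule set.
# Thresholds here are ILLUSTRATIVE, invented for demonstration and testing;
# they do not reproduce any clinically elicited rule content.
rules:
  - id: sway_safety
    metric: sway_radius_deg_s
    op: ">"
    threshold: 40.0
    severity: safety_alert
    message: "High trunk sway ({value:.1f} deg/s): stop the exercise and hold on to support."
  - id: cross_plane_pitch
    metric: head_range_pitch_deg
    op: ">"
    threshold: 15.0
    severity: correction_advice
    message: "Head is moving in the pitch plane ({value:.1f} deg); keep the movement horizontal."
  - id: head_range_low
    metric: head_range_yaw_deg
    op: "<"
    threshold: 0.8
    severity: correction_advice
    category: baseline_dependent
    baseline_key: head_range_yaw_deg
    baseline_mode: ratio
    message: "Head turns smaller than your usual range ({value:.1f} deg); turn a little further."
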