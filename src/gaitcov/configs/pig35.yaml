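# Default whole-body kinematic chain: 16 segments, 15 joints, 35 rotational DOF.
# Generic full-body gait model (Plug-in-Gait-style marker set, documented chain —
# not a clone of the proprietary Vicon conventions).
#
# Conventions:
#   lab frame: X fore-aft (+ walking direction), Y lateral (+ left), Z up
#   segment local frames coincide with the lab frame at the reference posture
#   (theta = 0: upright standing, arms hanging, feet pointing forward)
#   axis: unit vector from proximal to distal end of the segment, local frame
#   rotation_order: Cardan axes per DOF; a leading '-' flips the sign of the
#   angle about that axis ('-y' makes positive sagittal angles move the distal
#   segment forward for downward-pointing segments)
#   lengths/offsets in metres; mass fractions sum to 1 (Winter's anthropometric
#   table, trunk split into pelvis/abdomen/thorax)
schema_version: 1
name: pig35
root_segment: pelvis
task_markers:
  left: {heel: LHEE, toe: LMTP}
  right: {heel: RHEE, toe: RMTP}
segments:
  - id: pelvis
    length: 0.10
    axis: [0.0, 0.0, 1.0]
    mass_fraction: 0.142
    com_offset: 0.5
    markers:
      LASI: [0.10, 0.13, 0.00]
      RASI: [0.10, -0.13, 0.00]
      LPSI: [-0.12, 0.05, 0.03]
      RPSI: [-0.12, -0.05, 0.03]
  - id: lower_trunk
    length: 0.25
    axis: [0.0, 0.0, 1.0]
    mass_fraction: 0.139
    com_offset: 0.5
    markers:
      STRL: [0.10, 0.06, 0.12]
      STRR: [0.10, -0.06, 0.12]
      L5S1: [-0.11, 0.00, 0.04]
      T12L: [-0.10, 0.00, 0.21]
  - id: upper_trunk
    length: 0.30
    axis: [0.0, 0.0, 1.0]
    mass_fraction: 0.216
    com_offset: 0.5
    markers:
      CLAV: [0.10, 0.00, 0.25]
      STRN: [0.11, 0.00, 0.12]
      C7:   [-0.10, 0.00, 0.28]
      T10:  [-0.11, 0.00, 0.05]
  - id: head
    length: 0.25
    axis: [0.0, 0.0, 1.0]
    mass_fraction: 0.081
    com_offset: 0.5
    markers:
      LFHD: [0.09, 0.06, 0.12]
      RFHD: [0.09, -0.06, 0.12]
      LBHD: [-0.09, 0.06, 0.12]
      RBHD: [-0.09, -0.06, 0.12]
  - id: upperarm_l
    length: 0.30
    axis: [0.0, 0.0, -1.0]
    mass_fraction: 0.028
    com_offset: 0.436
    markers:
      LSHO: [0.00, 0.04, -0.02]
      LUPA: [0.035, 0.00, -0.15]
      LELB: [0.00, 0.04, -0.28]
  - id: upperarm_r
    length: 0.30
    axis: [0.0, 0.0, -1.0]
    mass_fraction: 0.028
    com_offset: 0.436
    markers:
      RSHO: [0.00, -0.04, -0.02]
      RUPA: [0.035, 0.00, -0.15]
      RELB: [0.00, -0.04, -0.28]
  - id: forearm_l
    length: 0.26
    axis: [0.0, 0.0, -1.0]
    mass_fraction: 0.016
    com_offset: 0.430
    markers:
      LFRM: [0.03, 0.00, -0.10]
      LFRA: [-0.025, 0.02, -0.13]
      LWRA: [0.00, 0.03, -0.25]
      LWRB: [0.00, -0.03, -0.25]
  - id: forearm_r
    length: 0.26
    axis: [0.0, 0.0, -1.0]
    mass_fraction: 0.016
    com_offset: 0.430
    markers:
      RFRM: [0.03, 0.00, -0.10]
      RFRA: [-0.025, -0.02, -0.13]
      RWRA: [0.00, -0.03, -0.25]
      RWRB: [0.00, 0.03, -0.25]
  - id: hand_l
    length: 0.18
    axis: [0.0, 0.0, -1.0]
    mass_fraction: 0.006
    com_offset: 0.506
    markers:
      LFIN: [0.00, 0.00, -0.16]
      LHNA: [0.03, 0.02, -0.06]
      LHNB: [-0.03, 0.02, -0.06]
      LHNC: [0.00, -0.03, -0.08]
  - id: hand_r
    length: 0.18
    axis: [0.0, 0.0, -1.0]
    mass_fraction: 0.006
    com_offset: 0.506
    markers:
      RFIN: [0.00, 0.00, -0.16]
      RHNA: [0.03, -0.02, -0.06]
      RHNB: [-0.03, -0.02, -0.06]
      RHNC: [0.00, 0.03, -0.08]
  - id: thigh_l
    length: 0.42
    axis: [0.0, 0.0, -1.0]
    mass_fraction: 0.100
    com_offset: 0.433
    markers:
      LTHI: [0.04, 0.03, -0.18]
      LTHA: [-0.04, 0.03, -0.25]
      LKNE: [0.00, 0.05, -0.40]
      LKNM: [0.00, -0.05, -0.40]
  - id: thigh_r
    length: 0.42
    axis: [0.0, 0.0, -1.0]
    mass_fraction: 0.100
    com_offset: 0.433
    markers:
      RTHI: [0.04, -0.03, -0.18]
      RTHA: [-0.04, -0.03, -0.25]
      RKNE: [0.00, -0.05, -0.40]
      RKNM: [0.00, 0.05, -0.40]
  - id: shank_l
    length: 0.43
    axis: [0.0, 0.0, -1.0]
    mass_fraction: 0.0465
    com_offset: 0.433
    markers:
      LTIB: [0.03, 0.03, -0.18]
      LTIA: [-0.03, 0.04, -0.26]
      LANK: [0.00, 0.05, -0.41]
      LANM: [0.00, -0.05, -0.41]
  - id: shank_r
    length: 0.43
    axis: [0.0, 0.0, -1.0]
    mass_fraction: 0.0465
    com_offset: 0.433
    markers:
      RTIB: [0.03, -0.03, -0.18]
      RTIA: [-0.03, -0.04, -0.26]
      RANK: [0.00, -0.05, -0.41]
      RANM: [0.00, 0.05, -0.41]
  - id: foot_l
    length: 0.18
    axis: [1.0, 0.0, 0.0]
    mass_fraction: 0.0145
    com_offset: 0.5
    markers:
      LHEE: [-0.06, 0.00, -0.03]
      LMTP: [0.18, -0.02, -0.05]
      LTOE: [0.22, 0.01, -0.05]
      LFOO: [0.06, 0.03, 0.01]
  - id: foot_r
    length: 0.18
    axis: [1.0, 0.0, 0.0]
    mass_fraction: 0.0145
    com_offset: 0.5
    markers:
      RHEE: [-0.06, 0.00, -0.03]
      RMTP: [0.18, 0.02, -0.05]
      RTOE: [0.22, -0.01, -0.05]
      RFOO: [0.06, -0.03, 0.01]
joints:
  - id: spine
    parent: pelvis
    child: lower_trunk
    offset: [0.0, 0.0, 0.10]
    rotation_order: ["-y", "x", "z"]
  - id: thorax
    parent: lower_trunk
    child: upper_trunk
    offset: [0.0, 0.0, 0.25]
    rotation_order: ["-y", "x", "z"]
  - id: neck
    parent: upper_trunk
    child: head
    offset: [0.0, 0.0, 0.30]
    rotation_order: ["-y", "x", "z"]
  - id: shoulder_l
    parent: upper_trunk
    child: upperarm_l
    offset: [0.0, 0.20, 0.28]
    rotation_order: ["-y", "x", "z"]
  - id: shoulder_r
    parent: upper_trunk
    child: upperarm_r
    offset: [0.0, -0.20, 0.28]
    rotation_order: ["-y", "x", "z"]
  - id: elbow_l
    parent: upperarm_l
    child: forearm_l
    offset: [0.0, 0.0, -0.30]
    rotation_order: ["-y"]
  - id: elbow_r
    parent: upperarm_r
    child: forearm_r
    offset: [0.0, 0.0, -0.30]
    rotation_order: ["-y"]
  - id: wrist_l
    parent: forearm_l
    child: hand_l
    offset: [0.0, 0.0, -0.26]
    rotation_order: ["-y", "x"]
  - id: wrist_r
    parent: forearm_r
    child: hand_r
    offset: [0.0, 0.0, -0.26]
    rotation_order: ["-y", "x"]
  - id: hip_l
    parent: pelvis
    child: thigh_l
    offset: [0.0, 0.09, -0.05]
    rotation_order: ["-y", "x", "z"]
  - id: hip_r
    parent: pelvis
    child: thigh_r
    offset: [0.0, -0.09, -0.05]
    rotation_order: ["-y", "x", "z"]
  - id: knee_l
    parent: thigh_l
    child: shank_l
    offset: [0.0, 0.0, -0.42]
    rotation_order: ["y", "z"]
  - id: knee_r
    parent: thigh_r
    child: shank_r
    offset: [0.0, 0.0, -0.42]
    rotation_order: ["y", "z"]
  - id: ankle_l
    parent: shank_l
    child: foot_l
    offset: [0.0, 0.0, -0.43]
    rotation_order: ["-y", "x"]
  - id: ankle_r
    parent: shank_r
    child: foot_r
    offset: [0.0, 0.0, -0.43]
    rotation_order: ["-y", "x"]
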