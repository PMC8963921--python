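# Default anthropometric scaling table for the four-link sagittal model.
#
# Segment properties are expressed as fractions of subject height (lengths)
# and subject mass (masses); moments of inertia come from a radius-of-gyration
# fraction of segment length about the segment centre of mass.  Values are
# literature-order defaults for a standing adult with both legs lumped into
# single shank/thigh segments; every number here is a configuration choice
# and may be overridden per subject.
#
# com_fraction is the centre-of-mass distance from the PROXIMAL joint of the
# chain (ankle, knee, hip, lumbar) as a fraction of segment length.
segments:
  shank:  {mass_fraction: 0.12, length_fraction: 0.25, com_fraction: 0.55, gyration_fraction: 0.30}
  thigh:  {mass_fraction: 0.20, length_fraction: 0.24, com_fraction: 0.45, gyration_fraction: 0.30}
  pelvis: {mass_fraction: 0.14, length_fraction: 0.10, com_fraction: 0.50, gyration_fraction: 0.35}
  hat:    {mass_fraction: 0.50, length_fraction: 0.35, com_fraction: 0.45, gyration_fraction: 0.35}

# Joint viscous coefficients.  Ankle/knee/hip resist angular velocity
# (N*m*s/rad); the lumbar joint resists angular displacement outside a
# +/-0.0314 rad dead zone (N*m/rad).  Values are small published-order
# defaults; 0 is a legitimate setting for testing.
viscous:
  ankle: 0.5
  knee: 0.5
  hip: 0.5
  lumbar_extension: 10.0
  lumbar_flexion: 10.0

# Seat reaction force application point: fraction along the pelvis segment
# measured from the hip joint.
hip_contact_fraction: 0.5
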