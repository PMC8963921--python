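# Default Hill-model parameter table for the 11-muscle sit-to-stand model.
#
# fmax  : isometric maximum force [N]
# l_opt : optimal length of the lumped muscle-tendon unit [m]
# v_max : maximum shortening velocity [m/s]
# moment_arms : signed, constant moment arm per joint [m].  Sign convention:
#   a positive moment arm produces torque in the direction of increasing
#   joint angle (dorsiflexion at the ankle, extension at the knee, flexion
#   at the hip and lumbar under the chain-relative angle convention -- see
#   the dynamics module docstring).
#
# Values are literature-order defaults.  l_opt is chosen so that the
# normalized length stays within a physiological band (~0.7-1.4) over the
# sit-to-stand joint range under the constant-moment-arm linearization;
# v_max is scaled as ~5 optimal lengths per second.  All values are
# configuration, overridable per subject.
#
# theta_ref is the reference posture (rad, ankle/knee/hip/lumbar) at which
# the muscle-tendon length equals l_ref (default l_opt); the default is the
# midpoint of the sit-to-stand range.
theta_ref: [0.12, -0.85, 0.80, 0.12]

muscles:
  TA:   {fmax: 1000.0, l_opt: 0.10, v_max: 0.50, moment_arms: {ankle: 0.040}}
  SOL:  {fmax: 3500.0, l_opt: 0.12, v_max: 0.60, moment_arms: {ankle: -0.050}}
  GAS:  {fmax: 1500.0, l_opt: 0.15, v_max: 0.75, moment_arms: {ankle: -0.050, knee: -0.020}}
  RF:   {fmax: 1200.0, l_opt: 0.20, v_max: 1.00, moment_arms: {knee: 0.045, hip: 0.035}}
  VAS:  {fmax: 3000.0, l_opt: 0.15, v_max: 0.75, moment_arms: {knee: 0.045}}
  BFL:  {fmax: 900.0,  l_opt: 0.18, v_max: 0.90, moment_arms: {knee: -0.025, hip: -0.055}}
  BFS:  {fmax: 450.0,  l_opt: 0.12, v_max: 0.60, moment_arms: {knee: -0.025}}
  GMAX: {fmax: 1500.0, l_opt: 0.145, v_max: 0.72, moment_arms: {hip: -0.060}}
  RA:   {fmax: 900.0,  l_opt: 0.30, v_max: 1.50, moment_arms: {lumbar: 0.060}}
  ES:   {fmax: 2000.0, l_opt: 0.20, v_max: 1.00, moment_arms: {lumbar: -0.055}}
  IL:   {fmax: 1200.0, l_opt: 0.15, v_max: 0.75, moment_arms: {hip: 0.040}}
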