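activity,channel,offset,amplitude,freq_hz,harmonic_ratio,noise_sd
sitting,waist_accel_x,0.1,0.0,0.0,0.0,0.08
sitting,waist_accel_y,9.55,0.0,0.0,0.0,0.08
sitting,waist_gyro_x,0.0,0.0,0.0,0.0,0.5
sitting,thigh_L_accel_x,9.3,0.0,0.0,0.0,0.1
sitting,thigh_L_accel_z,1.0,0.0,0.0,0.0,0.1
sitting,thigh_L_gyro_y,0.0,0.0,0.0,0.0,0.6
sitting,thigh_R_accel_x,9.3,0.0,0.0,0.0,0.1
sitting,thigh_R_accel_z,1.0,0.0,0.0,0.0,0.1
sitting,thigh_R_gyro_y,0.0,0.0,0.0,0.0,0.6
sitting,shank_L_accel_x,0.4,0.0,0.0,0.0,0.1
sitting,shank_L_accel_z,9.7,0.0,0.0,0.0,0.1
sitting,shank_L_gyro_y,0.0,0.0,0.0,0.0,0.6
sitting,shank_R_accel_x,0.4,0.0,0.0,0.0,0.1
sitting,shank_R_accel_z,9.7,0.0,0.0,0.0,0.1
sitting,shank_R_gyro_y,0.0,0.0,0.0,0.0,0.6
sitting,knee_L_gonio_angle,86.0,0.0,0.0,0.0,1.0
sitting,knee_R_gonio_angle,86.0,0.0,0.0,0.0,1.0
sitting,ankle_L_gonio_angle,3.0,0.0,0.0,0.0,0.8
sitting,ankle_R_gonio_angle,3.0,0.0,0.0,0.0,0.8
standing,waist_accel_x,0.25,0.05,0.0,0.0,0.08
standing,waist_accel_y,9.81,0.05,0.0,0.0,0.08
standing,waist_gyro_x,0.0,1.0,0.0,0.0,0.5
standing,thigh_L_accel_x,0.5,0.06,0.0,0.0,0.1
standing,thigh_L_accel_z,9.78,0.06,0.0,0.0,0.1
standing,thigh_L_gyro_y,0.0,1.2,0.0,0.0,0.6
standing,thigh_R_accel_x,0.5,0.06,0.0,0.0,0.1
standing,thigh_R_accel_z,9.78,0.06,0.0,0.0,0.1
standing,thigh_R_gyro_y,0.0,1.2,0.0,0.0,0.6
standing,shank_L_accel_x,0.3,0.06,0.0,0.0,0.1
standing,shank_L_accel_z,9.8,0.06,0.0,0.0,0.1
standing,shank_L_gyro_y,0.0,1.5,0.0,0.0,0.6
standing,shank_R_accel_x,0.3,0.06,0.0,0.0,0.1
standing,shank_R_accel_z,9.8,0.06,0.0,0.0,0.1
standing,shank_R_gyro_y,0.0,1.5,0.0,0.0,0.6
standing,knee_L_gonio_angle,7.0,0.8,0.0,0.0,1.0
standing,knee_R_gonio_angle,7.0,0.8,0.0,0.0,1.0
standing,ankle_L_gonio_angle,1.5,0.5,0.0,0.0,0.8
standing,ankle_R_gonio_angle,1.5,0.5,0.0,0.0,0.8
walking,waist_accel_x,1.0,0.5,0.95,0.4,0.25
walking,waist_accel_y,9.75,0.7,0.95,0.4,0.25
walking,waist_gyro_x,0.0,22.0,0.95,0.35,3.0
walking,thigh_L_accel_x,1.5,0.6,0.95,0.4,0.3
walking,thigh_L_accel_z,9.3,0.5,0.95,0.4,0.3
walking,thigh_L_gyro_y,0.0,85.0,0.95,0.45,6.0
walking,thigh_R_accel_x,1.5,0.6,0.95,0.4,0.3
walking,thigh_R_accel_z,9.3,0.5,0.95,0.4,0.3
walking,thigh_R_gyro_y,0.0,85.0,0.95,0.45,6.0
walking,shank_L_accel_x,1.8,0.7,0.95,0.4,0.35
walking,shank_L_accel_z,9.2,0.6,0.95,0.4,0.35
walking,shank_L_gyro_y,0.0,150.0,0.95,0.5,8.0
walking,shank_R_accel_x,1.8,0.7,0.95,0.4,0.35
walking,shank_R_accel_z,9.2,0.6,0.95,0.4,0.35
walking,shank_R_gyro_y,0.0,150.0,0.95,0.5,8.0
walking,knee_L_gonio_angle,22.0,16.0,0.95,0.4,3.5
walking,knee_R_gonio_angle,22.0,16.0,0.95,0.4,3.5
walking,ankle_L_gonio_angle,5.0,7.0,0.95,0.35,3.0
walking,ankle_R_gonio_angle,5.0,7.0,0.95,0.35,3.0
ramp_ascent,waist_accel_x,2.4,0.55,0.8,0.4,0.25
ramp_ascent,waist_accel_y,9.55,0.75,0.8,0.4,0.25
ramp_ascent,waist_gyro_x,0.0,28.0,0.8,0.35,3.0
ramp_ascent,thigh_L_accel_x,3.8,0.65,0.8,0.4,0.3
ramp_ascent,thigh_L_accel_z,8.3,0.55,0.8,0.4,0.3
ramp_ascent,thigh_L_gyro_y,0.0,100.0,0.8,0.45,6.0
ramp_ascent,thigh_R_accel_x,3.8,0.65,0.8,0.4,0.3
ramp_ascent,thigh_R_accel_z,8.3,0.55,0.8,0.4,0.3
ramp_ascent,thigh_R_gyro_y,0.0,100.0,0.8,0.45,6.0
ramp_ascent,shank_L_accel_x,3.6,0.75,0.8,0.4,0.35
ramp_ascent,shank_L_accel_z,8.0,0.65,0.8,0.4,0.35
ramp_ascent,shank_L_gyro_y,0.0,165.0,0.8,0.5,8.0
ramp_ascent,shank_R_accel_x,3.6,0.75,0.8,0.4,0.35
ramp_ascent,shank_R_accel_z,8.0,0.65,0.8,0.4,0.35
ramp_ascent,shank_R_gyro_y,0.0,165.0,0.8,0.5,8.0
ramp_ascent,knee_L_gonio_angle,30.0,18.0,0.8,0.4,3.5
ramp_ascent,knee_R_gonio_angle,30.0,18.0,0.8,0.4,3.5
ramp_ascent,ankle_L_gonio_angle,9.0,8.0,0.8,0.35,3.0
ramp_ascent,ankle_R_gonio_angle,9.0,8.0,0.8,0.35,3.0
ramp_descent,waist_accel_x,-0.6,0.5,0.85,0.4,0.25
ramp_descent,waist_accel_y,9.95,0.7,0.85,0.4,0.25
ramp_descent,waist_gyro_x,0.0,16.0,0.85,0.35,3.0
ramp_descent,thigh_L_accel_x,-0.8,0.6,0.85,0.4,0.3
ramp_descent,thigh_L_accel_z,10.3,0.5,0.85,0.4,0.3
ramp_descent,thigh_L_gyro_y,0.0,65.0,0.85,0.45,6.0
ramp_descent,thigh_R_accel_x,-0.8,0.6,0.85,0.4,0.3
ramp_descent,thigh_R_accel_z,10.3,0.5,0.85,0.4,0.3
ramp_descent,thigh_R_gyro_y,0.0,65.0,0.85,0.45,6.0
ramp_descent,shank_L_accel_x,-0.3,0.7,0.85,0.4,0.35
ramp_descent,shank_L_accel_z,10.6,0.6,0.85,0.4,0.35
ramp_descent,shank_L_gyro_y,0.0,115.0,0.85,0.5,8.0
ramp_descent,shank_R_accel_x,-0.3,0.7,0.85,0.4,0.35
ramp_descent,shank_R_accel_z,10.6,0.6,0.85,0.4,0.35
ramp_descent,shank_R_gyro_y,0.0,115.0,0.85,0.5,8.0
ramp_descent,knee_L_gonio_angle,16.0,17.0,0.85,0.4,3.5
ramp_descent,knee_R_gonio_angle,16.0,17.0,0.85,0.4,3.5
ramp_descent,ankle_L_gonio_angle,0.5,7.5,0.85,0.35,3.0
ramp_descent,ankle_R_gonio_angle,0.5,7.5,0.85,0.35,3.0
stair_ascent,waist_accel_x,3.6,0.6,0.55,0.4,0.25
stair_ascent,waist_accel_y,9.35,0.85,0.55,0.4,0.25
stair_ascent,waist_gyro_x,0.0,33.0,0.55,0.35,3.0
stair_ascent,thigh_L_accel_x,6.0,0.7,0.55,0.4,0.3
stair_ascent,thigh_L_accel_z,7.2,0.65,0.55,0.4,0.3
stair_ascent,thigh_L_gyro_y,0.0,125.0,0.55,0.45,6.0
stair_ascent,thigh_R_accel_x,6.0,0.7,0.55,0.4,0.3
stair_ascent,thigh_R_accel_z,7.2,0.65,0.55,0.4,0.3
stair_ascent,thigh_R_gyro_y,0.0,125.0,0.55,0.45,6.0
stair_ascent,shank_L_accel_x,5.2,0.85,0.55,0.4,0.35
stair_ascent,shank_L_accel_z,6.7,0.75,0.55,0.4,0.35
stair_ascent,shank_L_gyro_y,0.0,185.0,0.55,0.5,8.0
stair_ascent,shank_R_accel_x,5.2,0.85,0.55,0.4,0.35
stair_ascent,shank_R_accel_z,6.7,0.75,0.55,0.4,0.35
stair_ascent,shank_R_gyro_y,0.0,185.0,0.55,0.5,8.0
stair_ascent,knee_L_gonio_angle,50.0,24.0,0.55,0.4,3.5
stair_ascent,knee_R_gonio_angle,50.0,24.0,0.55,0.4,3.5
stair_ascent,ankle_L_gonio_angle,12.0,10.0,0.55,0.35,3.0
stair_ascent,ankle_R_gonio_angle,12.0,10.0,0.55,0.35,3.0
stair_descent,waist_accel_x,-1.8,0.6,0.65,0.4,0.25
stair_descent,waist_accel_y,10.15,0.9,0.65,0.4,0.25
stair_descent,waist_gyro_x,0.0,38.0,0.65,0.35,3.0
stair_descent,thigh_L_accel_x,-3.0,0.7,0.65,0.4,0.3
stair_descent,thigh_L_accel_z,11.2,0.6,0.65,0.4,0.3
stair_descent,thigh_L_gyro_y,0.0,140.0,0.65,0.45,6.0
stair_descent,thigh_R_accel_x,-3.0,0.7,0.65,0.4,0.3
stair_descent,thigh_R_accel_z,11.2,0.6,0.65,0.4,0.3
stair_descent,thigh_R_gyro_y,0.0,140.0,0.65,0.45,6.0
stair_descent,shank_L_accel_x,-1.9,0.9,0.65,0.4,0.35
stair_descent,shank_L_accel_z,11.6,0.7,0.65,0.4,0.35
stair_descent,shank_L_gyro_y,0.0,205.0,0.65,0.5,8.0
stair_descent,shank_R_accel_x,-1.9,0.9,0.65,0.4,0.35
stair_descent,shank_R_accel_z,11.6,0.7,0.65,0.4,0.35
stair_descent,shank_R_gyro_y,0.0,205.0,0.65,0.5,8.0
stair_descent,knee_L_gonio_angle,40.0,26.0,0.65,0.4,3.5
stair_descent,knee_R_gonio_angle,40.0,26.0,0.65,0.4,3.5
stair_descent,ankle_L_gonio_angle,-3.0,11.0,0.65,0.35,3.0
stair_descent,ankle_R_gonio_angle,-3.0,11.0,0.65,0.35,3.0
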