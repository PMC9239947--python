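# MDME acquisition protocol presets: 3 families (ETL, Matrix, Phase) x 4 members.
# One YAML document per protocol. All times in ms, angles in degrees,
# bandwidth in kHz, FOV/geometry in mm. scan_time_s is carried as metadata
# only and never computed. Delay times follow the package default
# (0.07, 0.26, 0.52, 0.87) x TR; see docs/methods.md.
family: ETL
name: ETL1
te1_ms: 18.9
te2_ms: 94.4
tr_ms: 4000.0
delay_times_ms: [280.0, 1040.0, 2080.0, 3480.0]
etl: 16
matrix_freq: 288
matrix_phase: 224
bandwidth_khz: 25.0
accel_factor: 3.0
fov_mm: 240.0
slice_thickness_mm: 4.0
gap_mm: 1.0
flip_excitation_deg: 90.0
flip_saturation_deg: 120.0
scan_time_s: 144
---
family: ETL
name: ETL2
te1_ms: 18.9
te2_ms: 94.4
tr_ms: 4000.0
delay_times_ms: [280.0, 1040.0, 2080.0, 3480.0]
etl: 14
matrix_freq: 288
matrix_phase: 224
bandwidth_khz: 25.0
accel_factor: 3.0
fov_mm: 240.0
slice_thickness_mm: 4.0
gap_mm: 1.0
flip_excitation_deg: 90.0
flip_saturation_deg: 120.0
scan_time_s: 176
---
family: ETL
name: ETL3
te1_ms: 18.9
te2_ms: 94.4
tr_ms: 4000.0
delay_times_ms: [280.0, 1040.0, 2080.0, 3480.0]
etl: 12
matrix_freq: 288
matrix_phase: 224
bandwidth_khz: 25.0
accel_factor: 3.0
fov_mm: 240.0
slice_thickness_mm: 4.0
gap_mm: 1.0
flip_excitation_deg: 90.0
flip_saturation_deg: 120.0
scan_time_s: 176
---
family: ETL
name: ETL4
te1_ms: 18.9
te2_ms: 94.4
tr_ms: 4000.0
delay_times_ms: [280.0, 1040.0, 2080.0, 3480.0]
etl: 10
matrix_freq: 288
matrix_phase: 224
bandwidth_khz: 25.0
accel_factor: 3.0
fov_mm: 240.0
slice_thickness_mm: 4.0
gap_mm: 1.0
flip_excitation_deg: 90.0
flip_saturation_deg: 120.0
scan_time_s: 208
---
family: Matrix
name: Matrix1
te1_ms: 14.6
te2_ms: 87.5
tr_ms: 4000.0
delay_times_ms: [280.0, 1040.0, 2080.0, 3480.0]
etl: 16
matrix_freq: 192
matrix_phase: 128
bandwidth_khz: 25.0
accel_factor: 3.0
fov_mm: 240.0
slice_thickness_mm: 4.0
gap_mm: 1.0
flip_excitation_deg: 90.0
flip_saturation_deg: 120.0
scan_time_s: 112
---
family: Matrix
name: Matrix2
te1_ms: 18.9
te2_ms: 94.4
tr_ms: 4000.0
delay_times_ms: [280.0, 1040.0, 2080.0, 3480.0]
etl: 16
matrix_freq: 288
matrix_phase: 224
bandwidth_khz: 25.0
accel_factor: 3.0
fov_mm: 240.0
slice_thickness_mm: 4.0
gap_mm: 1.0
flip_excitation_deg: 90.0
flip_saturation_deg: 120.0
scan_time_s: 144
---
family: Matrix
name: Matrix3
te1_ms: 20.3
te2_ms: 101.7
tr_ms: 4013.0
delay_times_ms: [280.91, 1043.38, 2086.76, 3491.31]
etl: 16
matrix_freq: 320
matrix_phase: 256
bandwidth_khz: 25.0
accel_factor: 3.0
fov_mm: 240.0
slice_thickness_mm: 4.0
gap_mm: 1.0
flip_excitation_deg: 90.0
flip_saturation_deg: 120.0
scan_time_s: 177
---
family: Matrix
name: Matrix4
te1_ms: 23.0
te2_ms: 115.0
tr_ms: 4450.0
delay_times_ms: [311.5, 1157.0, 2314.0, 3871.5]
etl: 16
matrix_freq: 384
matrix_phase: 288
bandwidth_khz: 25.0
accel_factor: 3.0
fov_mm: 240.0
slice_thickness_mm: 4.0
gap_mm: 1.0
flip_excitation_deg: 90.0
flip_saturation_deg: 120.0
scan_time_s: 196
---
family: Phase
name: Phase1
te1_ms: 18.9
te2_ms: 94.4
tr_ms: 4000.0
delay_times_ms: [280.0, 1040.0, 2080.0, 3480.0]
etl: 16
matrix_freq: 288
matrix_phase: 224
bandwidth_khz: 25.0
accel_factor: 3.0
fov_mm: 240.0
slice_thickness_mm: 4.0
gap_mm: 1.0
flip_excitation_deg: 90.0
flip_saturation_deg: 120.0
scan_time_s: 144
---
family: Phase
name: Phase2
te1_ms: 18.9
te2_ms: 94.4
tr_ms: 4000.0
delay_times_ms: [280.0, 1040.0, 2080.0, 3480.0]
etl: 16
matrix_freq: 288
matrix_phase: 224
bandwidth_khz: 25.0
accel_factor: 2.5
fov_mm: 240.0
slice_thickness_mm: 4.0
gap_mm: 1.0
flip_excitation_deg: 90.0
flip_saturation_deg: 120.0
scan_time_s: 176
---
family: Phase
name: Phase3
te1_ms: 18.9
te2_ms: 94.4
tr_ms: 4000.0
delay_times_ms: [280.0, 1040.0, 2080.0, 3480.0]
etl: 16
matrix_freq: 288
matrix_phase: 224
bandwidth_khz: 25.0
accel_factor: 2.0
fov_mm: 240.0
slice_thickness_mm: 4.0
gap_mm: 1.0
flip_excitation_deg: 90.0
flip_saturation_deg: 120.0
scan_time_s: 208
---
family: Phase
name: Phase4
te1_ms: 18.9
te2_ms: 94.4
tr_ms: 4000.0
delay_times_ms: [280.0, 1040.0, 2080.0, 3480.0]
etl: 16
matrix_freq: 288
matrix_phase: 224
bandwidth_khz: 25.0
accel_factor: 1.0
fov_mm: 240.0
slice_thickness_mm: 4.0
gap_mm: 1.0
flip_excitation_deg: 90.0
flip_saturation_deg: 120.0
scan_time_s: 400
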