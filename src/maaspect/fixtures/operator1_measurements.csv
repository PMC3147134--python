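operator,config,object,sb_ratio,method,isocontour_pct,true_mL,true_mL_alt,measured_mL,error_pct
1,18.5 MBq/sphere,Cylinder 1,,spect,2,6716,,6521,-2.90
1,18.5 MBq/sphere,Cylinder 1,,spect_ct,2,6716,,6521,-2.90
1,18.5 MBq/sphere,Sphere 1,2.8,spect,42,55,,75.45,37.18
1,18.5 MBq/sphere,Sphere 1,2.8,spect_ct,48,55,,57.22,4.04
1,18.5 MBq/sphere,Sphere 2,7.6,spect,31,20.5,21.0,22.35,6.43
1,18.5 MBq/sphere,Sphere 2,7.6,spect_ct,27,20.5,21.0,27.08,28.95
1,18.5 MBq/sphere,Sphere 3,9.6,spect,27,16,,18,12.50
1,18.5 MBq/sphere,Sphere 3,9.6,spect_ct,29,16,,16.94,5.88
1,18.5 MBq/sphere,Sphere 4,19.6,spect,15,8,,14.72,84.00
1,18.5 MBq/sphere,Sphere 4,19.6,spect_ct,19,8,,10.91,36.38
1,37 MBq/sphere,Cylinder 1,,spect,2,6716,,6180,-7.98
1,37 MBq/sphere,Cylinder 1,,spect_ct,1,6716,,6735,0.28
1,37 MBq/sphere,Sphere 1,6,spect,46,55,,44.86,-18.44
1,37 MBq/sphere,Sphere 1,6,spect_ct,42,55,,49.06,-10.80
1,37 MBq/sphere,Sphere 2,17,spect,25,20.5,21.0,22.58,7.52
1,37 MBq/sphere,Sphere 2,17,spect_ct,29,20.5,21.0,20.52,-2.29
1,37 MBq/sphere,Sphere 3,23.4,spect,23,16,,17.55,9.69
1,37 MBq/sphere,Sphere 3,23.4,spect_ct,27,16,,14.95,-6.56
1,37 MBq/sphere,Sphere 4,43.8,spect,31,8,,10.45,30.63
1,37 MBq/sphere,Sphere 4,43.8,spect_ct,35,8,,9.08,13.50
1,55.5 MBq/sphere,Cylinder 1,,spect,1,6716,,6737,0.31
1,55.5 MBq/sphere,Cylinder 1,,spect_ct,1,6716,,6737,0.31
1,55.5 MBq/sphere,Sphere 1,9.9,spect,44,55,,45.32,-17.60
1,55.5 MBq/sphere,Sphere 1,9.9,spect_ct,31,55,,59.28,7.78
1,55.5 MBq/sphere,Sphere 2,29.6,spect,33,20.5,21.0,18.62,-11.33
1,55.5 MBq/sphere,Sphere 2,29.6,spect_ct,31,20.5,21.0,19.3,-8.10
1,55.5 MBq/sphere,Sphere 3,38.6,spect,33,16,,17.32,8.25
1,55.5 MBq/sphere,Sphere 3,38.6,spect_ct,35,16,,16.17,1.06
1,55.5 MBq/sphere,Sphere 4,73.1,spect,31,8,,14.37,79.63
1,55.5 MBq/sphere,Sphere 4,73.1,spect_ct,40,8,,10.53,31.63
1,74 MBq/sphere,Cylinder 1,,spect,,6716,,,
1,74 MBq/sphere,Cylinder 1,,spect_ct,,6716,,,
1,74 MBq/sphere,Sphere 1,16,spect,52,55,,33.72,-38.69
1,74 MBq/sphere,Sphere 1,16,spect_ct,31,55,,54.86,-0.25
1,74 MBq/sphere,Sphere 2,45,spect,21,20.5,21.0,23.5,11.90
1,74 MBq/sphere,Sphere 2,45,spect_ct,27,20.5,21.0,19.81,-5.67
1,74 MBq/sphere,Sphere 3,57,spect,21,16,,18.05,12.81
1,74 MBq/sphere,Sphere 3,57,spect_ct,27,16,,15.49,-3.19
1,74 MBq/sphere,Sphere 4,114,spect,31,8,,5.95,-25.63
1,74 MBq/sphere,Sphere 4,114,spect_ct,21,8,,8.32,4.00
1,55 MBq,Cylinder 2,,spect,46,774,,709,-8.40
1,55 MBq,Cylinder 2,,spect_ct,25,774,,795,2.71
1,116 MBq,Cylinder 2,,spect,46,774,,667,-13.82
1,116 MBq,Cylinder 2,,spect_ct,35,774,,770,-0.52
1,72 MBq,Cylinder 3,,spect,33,473,,455,-3.81
1,72 MBq,Cylinder 3,,spect_ct,23,473,,515,8.88
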