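operator,config,object,sb_ratio,method,isocontour_pct,true_mL,true_mL_alt,measured_mL,error_pct
2,18.5 MBq/sphere,Cylinder 1,,spect,1,6716,,7087,5.52
2,18.5 MBq/sphere,Cylinder 1,,spect_ct,2,6716,,6521,-2.90
2,18.5 MBq/sphere,Sphere 1,2.8,spect,31,55,,207,276.36
2,18.5 MBq/sphere,Sphere 1,2.8,spect_ct,48,55,,57.2,4.00
2,18.5 MBq/sphere,Sphere 2,7.6,spect,13,20.5,21.0,104.5,397.62
2,18.5 MBq/sphere,Sphere 2,7.6,spect_ct,28,20.5,21.0,24.4,16.19
2,18.5 MBq/sphere,Sphere 3,9.6,spect,19,16,,27.4,71.25
2,18.5 MBq/sphere,Sphere 3,9.6,spect_ct,29,16,,16.9,5.62
2,18.5 MBq/sphere,Sphere 4,19.6,spect,8,8,,29.2,265.00
2,18.5 MBq/sphere,Sphere 4,19.6,spect_ct,19,8,,10.9,36.25
2,37 MBq/sphere,Cylinder 1,,spect,2,6716,,6180,-7.98
2,37 MBq/sphere,Cylinder 1,,spect_ct,1,6716,,6700,-0.24
2,37 MBq/sphere,Sphere 1,6,spect,7,55,,169.7,208.55
2,37 MBq/sphere,Sphere 1,6,spect_ct,34,55,,53.56,-2.62
2,37 MBq/sphere,Sphere 2,17,spect,3,20.5,21.0,113.7,441.43
2,37 MBq/sphere,Sphere 2,17,spect_ct,23,20.5,21.0,24.34,15.90
2,37 MBq/sphere,Sphere 3,23.4,spect,3,16,,119.78,648.63
2,37 MBq/sphere,Sphere 3,23.4,spect_ct,27,16,,14.9,-6.88
2,37 MBq/sphere,Sphere 4,43.8,spect,4,8,,53.48,568.50
2,37 MBq/sphere,Sphere 4,43.8,spect_ct,33,8,,9.8,22.50
2,55.5 MBq/sphere,Cylinder 1,,spect,1,6716,,6737,0.31
2,55.5 MBq/sphere,Cylinder 1,,spect_ct,1,6716,,6737,0.31
2,55.5 MBq/sphere,Sphere 1,9.9,spect,10,55,,159.3,189.64
2,55.5 MBq/sphere,Sphere 1,9.9,spect_ct,35,55,,55.7,1.27
2,55.5 MBq/sphere,Sphere 2,29.6,spect,4,20.5,21.0,85,304.76
2,55.5 MBq/sphere,Sphere 2,29.6,spect_ct,25,20.5,21.0,22.7,8.10
2,55.5 MBq/sphere,Sphere 3,38.6,spect,7,16,,51.5,221.88
2,55.5 MBq/sphere,Sphere 3,38.6,spect_ct,36,16,,15.5,-3.13
2,55.5 MBq/sphere,Sphere 4,73.1,spect,6,8,,44.1,451.25
2,55.5 MBq/sphere,Sphere 4,73.1,spect_ct,36,8,,12,50.00
2,74 MBq/sphere,Cylinder 1,,spect,1,6716,,6565,-2.10
2,74 MBq/sphere,Cylinder 1,,spect_ct,1,6716,,6565,-2.10
2,74 MBq/sphere,Sphere 1,16,spect,15,55,,99.5,80.91
2,74 MBq/sphere,Sphere 1,16,spect_ct,32,55,,56,1.82
2,74 MBq/sphere,Sphere 2,45,spect,6,20.5,21.0,54.1,157.62
2,74 MBq/sphere,Sphere 2,45,spect_ct,23,20.5,21.0,23.7,12.86
2,74 MBq/sphere,Sphere 3,57,spect,5,16,,42.8,167.50
2,74 MBq/sphere,Sphere 3,57,spect_ct,25,16,,17.4,8.75
2,74 MBq/sphere,Sphere 4,114,spect,2,8,,35.8,347.50
2,74 MBq/sphere,Sphere 4,114,spect_ct,20,8,,8.7,8.75
2,55 MBq,Cylinder 2,,spect,17,774,,887,14.60
2,55 MBq,Cylinder 2,,spect_ct,27,774,,801,3.49
2,116 MBq,Cylinder 2,,spect,19,774,,855,10.47
2,116 MBq,Cylinder 2,,spect_ct,29,774,,775,0.13
2,72 MBq,Cylinder 3,,spect,21,473,,520,9.94
2,72 MBq,Cylinder 3,,spect_ct,27,473,,481,1.69
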