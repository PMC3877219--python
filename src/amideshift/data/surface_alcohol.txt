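# amideshift coefficient file v1
# kind: ALCOHOL
# interpolation: bilinear
# Chemical shift perturbation (ppm) on an (r_HO, angle_HOC) grid;
# rows follow r_HO, columns follow angle_HOC.
r_HO 1.50 1.60 1.70 1.80 1.90 2.00 2.10 2.20 2.30 2.40 2.50 2.60 2.70 2.80 2.90 3.00
angle_HOC 90.0 100.0 110.0 120.0 130.0 140.0 150.0 160.0 170.0 180.0
0.00000000 0.12712702 0.49317469 1.05399225 1.74193683 2.47403216 3.16197674 3.72279430 4.08884196 4.21596898
0.00000000 0.10941924 0.42447939 0.90717953 1.49929892 2.12941921 2.72153860 3.20423875 3.51929889 3.62871813
0.00000000 0.09417801 0.36535279 0.78081666 1.29045854 1.83280810 2.34244998 2.75791385 3.02908863 3.12326664
0.00000000 0.08105977 0.31446206 0.67205513 1.11070796 1.57751255 2.01616538 2.37375845 2.60716074 2.68822051
0.00000000 0.06976879 0.27066001 0.57844321 0.95599520 1.35777764 1.73532963 2.04311283 2.24400405 2.31377283
0.00000000 0.06005055 0.23295923 0.49787068 0.82283269 1.16865004 1.49361205 1.75852351 1.93143218 1.99148273
0.00000000 0.05168599 0.20050986 0.42852127 0.70821866 1.00586641 1.28556381 1.51357521 1.66239909 1.71408507
0.00000000 0.04448654 0.17258044 0.36883167 0.60956945 0.86575724 1.10649502 1.30274626 1.43084015 1.47532670
0.00000000 0.03828992 0.14854136 0.31745636 0.52466129 0.74516417 0.95236909 1.12128409 1.23153553 1.26982546
0.00000000 0.03295644 0.12785073 0.27323722 0.45158016 0.64136874 0.81971167 0.96509816 1.05999246 1.09294890
0.00000000 0.02836587 0.11004215 0.23517746 0.38867864 0.55203119 0.70553238 0.83066769 0.91234396 0.94070983
0.00000000 0.02441473 0.09471415 0.20241911 0.33453881 0.47513765 0.60725734 0.71496230 0.78526173 0.80967646
0.00000000 0.02101396 0.08152123 0.17422375 0.28794022 0.40895476 0.52267124 0.61537376 0.67588103 0.69689499
0.00000000 0.01808688 0.07016597 0.14995577 0.24783244 0.35199063 0.44986730 0.52965710 0.58173619 0.59982307
0.00000000 0.01556752 0.06039241 0.12906813 0.21331136 0.30296114 0.38720438 0.45588009 0.50070498 0.51627250
0.00000000 0.01339909 0.05198023 0.11108997 0.18359879 0.26076107 0.33326990 0.39237963 0.43096077 0.44435986
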