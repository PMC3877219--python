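# amideshift coefficient file v1
# kind: CARBOXYLATE
# interpolation: bilinear
# Chemical shift perturbation (ppm) on an (r_HO, angle_HOC) grid;
# rows follow r_HO, columns follow angle_HOC.
r_HO 1.50 1.60 1.70 1.80 1.90 2.00 2.10 2.20 2.30 2.40 2.50 2.60 2.70 2.80 2.90 3.00
angle_HOC 90.0 100.0 110.0 120.0 130.0 140.0 150.0 160.0 170.0 180.0
0.00000000 0.21611593 0.83839697 1.79178682 2.96129260 4.20585467 5.37536045 6.32875030 6.95103134 7.16714727
0.00000000 0.18601271 0.72161496 1.54220521 2.54880816 3.62001266 4.62661562 5.44720587 5.98280812 6.16882082
0.00000000 0.16010262 0.62109975 1.32738832 2.19377952 3.11577377 3.98216497 4.68845354 5.14945067 5.30955329
0.00000000 0.13780160 0.53458551 1.14249372 1.88820353 2.68177134 3.42748115 4.03538936 4.43217326 4.56997487
0.00000000 0.11860694 0.46012201 0.98335345 1.62519184 2.30822198 2.95006036 3.47329181 3.81480688 3.93341382
0.00000000 0.10208594 0.39603068 0.84638016 1.39881558 1.98670507 2.53914049 2.98948996 3.28343471 3.38552065
0.00000000 0.08786618 0.34086677 0.72848616 1.20397173 1.70997290 2.18545847 2.57307786 2.82607845 2.91394463
0.00000000 0.07562712 0.29338675 0.62701385 1.03626807 1.47178732 1.88104154 2.21466864 2.43242826 2.50805538
0.00000000 0.06509287 0.25252031 0.53967582 0.89192419 1.26677908 1.61902746 1.90618296 2.09361041 2.15870327
0.00000000 0.05602595 0.21734625 0.46450328 0.76768627 1.09032686 1.39350984 1.64066688 1.80198718 1.85801313
0.00000000 0.04822198 0.18707165 0.39980168 0.66075369 0.93845303 1.19940504 1.41213507 1.55098474 1.59920672
0.00000000 0.04150505 0.16101406 0.34411249 0.56871597 0.80773400 1.03233748 1.21543592 1.33494493 1.37644998
0.00000000 0.03572372 0.13858609 0.29618037 0.48949838 0.69522310 0.88854111 1.04613539 1.14899775 1.18472148
0.00000000 0.03074769 0.11928215 0.25492481 0.42131516 0.59838407 0.76477442 0.90041707 0.98895153 1.01969922
0.00000000 0.02646479 0.10266710 0.21941581 0.36262932 0.51503394 0.65824744 0.77499616 0.85119847 0.87766326
0.00000000 0.02277845 0.08836639 0.18885294 0.31211794 0.44329382 0.56655882 0.66704537 0.73263331 0.75541176
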