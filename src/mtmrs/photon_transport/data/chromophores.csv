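# Default chromophore absorption table for the layered head model.
# Approximate literature-derived values (NOT a measured dataset):
#   hb_oxy/hb_deoxy: absorption of whole blood (150 g Hb/L) per cm, from
#     coarse Prahl-style molar extinction anchors, PCHIP-interpolated
#   water: pure-water absorption per cm (Hale & Querry style anchors)
#   melanin: interior-melanosome power law 519*(lambda/500)^-3.48 per cm
#   cco_oxidised/cco_reduced: synthetic smooth approximations of the
#     cytochrome c / cytochrome c oxidase bands (~695 nm haem iron-Met80,
#     broad ~830 nm copper-centre band; reduced alpha band ~605 nm), in
#     per-cm units at unit relative concentration
# Columns multiply the per-layer volume/concentration fractions to give mu_a.
wavelength_nm,melanin,hb_oxy,hb_deoxy,water,cco_oxidised,cco_reduced
450,748.865,336.431,553.213,9.2e-05,2.25,2.8
460,693.722,254.562,404.033,0.000120319,2.21899,2.75969
470,643.698,191.613,281.637,0.000150397,2.12883,2.64247
480,598.223,147.165,189.684,0.000182115,1.98763,2.45892
490,556.802,120.803,131.83,0.000215355,1.8076,2.22488
500,519,112.108,111.733,0.00025,1.60327,1.95925
510,484.439,128.485,123.369,0.000281845,1.38957,1.68144
520,452.784,160.653,149.958,0.000311168,1.18009,1.40911
530,423.743,186.094,187.02,0.000344567,0.985759,1.15649
540,397.057,207.682,250.535,0.000388644,0.814126,0.933368
550,372.495,230.386,286.065,0.00045,0.669223,0.74515
560,349.855,262.759,264.885,0.000649856,0.551955,0.596019
570,328.957,292.433,220.367,0.00103693,0.460798,0.515091
580,309.638,269.197,175.232,0.00150908,0.392633,0.646966
590,291.755,119.81,121.668,0.00196415,0.343541,1.22047
600,275.18,17.1386,78.6073,0.0023,0.30946,1.94371
610,259.798,8.86364,51.6247,0.00250501,0.28666,1.91411
620,245.505,5.04518,34.8663,0.0026604,0.272233,1.12757
630,232.208,3.28943,27.7645,0.0028033,0.265861,0.478561
640,219.825,2.36727,23.271,0.00297079,0.277258,0.251342
650,208.279,1.94149,19.9233,0.0032,0.343563,0.210393
660,197.501,1.71386,17.2832,0.00350947,0.534154,0.206085
670,187.432,1.60128,14.9236,0.00391348,0.878117,0.206849
680,178.013,1.55319,12.8914,0.00444276,1.23572,0.209588
690,169.195,1.55319,11.0207,0.00512803,1.34494,0.214352
700,160.932,1.55319,9.60833,0.006,1.11242,0.221544
710,153.181,1.63267,8.83581,0.00757437,0.737646,0.231687
720,145.904,1.78884,8.24795,0.0104,0.463411,0.245323
730,139.066,1.9727,7.57495,0.0193337,0.356463,0.262896
740,132.635,2.22802,7.19821,0.027,0.363147,0.284624
750,126.581,2.66133,8.06853,0.0277358,0.432215,0.310366
760,120.879,3.13851,8.93885,0.028,0.547033,0.339514
770,115.504,3.49005,8.29412,0.0259688,0.706304,0.370935
780,110.432,3.80263,7.07503,0.023,0.906403,0.40299
790,105.643,4.09411,5.37314,0.0210312,1.13386,0.43364
800,101.118,4.37034,4.08113,0.02,1.36399,0.460645
810,96.8401,4.63813,3.81412,0.0225714,1.56421,0.481824
820,92.792,4.90593,3.71158,0.028,1.70122,0.495349
830,88.9593,5.20223,3.71158,0.0382747,1.75,0.5
840,85.3279,5.47364,3.71158,0.048,1.70122,0.495349
850,81.8851,5.67352,3.77721,0.0517788,1.56421,0.481824
860,78.6192,5.84855,3.88832,0.054,1.36399,0.460645
870,75.519,6.02414,4.00479,0.0549464,1.13386,0.43364
880,72.5744,6.18061,4.07577,0.056,0.906402,0.40299
890,69.7759,6.3294,4.07577,0.06,0.706294,0.370935
900,67.1149,6.41627,4.07577,0.068,0.546897,0.339513
910,64.5831,6.42855,4.05572,0.0864462,0.430823,0.310364
920,62.1729,6.43764,4.00791,0.119,0.353083,0.284619
930,59.8773,6.4438,3.95083,0.185689,0.305006,0.262883
940,57.6897,6.44729,3.90302,0.267,0.277473,0.245293
950,55.6038,6.4484,3.88297,0.337747,0.262844,0.23162
960,53.6141,6.39139,3.94035,0.39,0.255621,0.221395
970,51.7151,6.24611,4.0819,0.417546,0.252302,0.214031
980,49.9018,6.05113,4.2617,0.43,0.250883,0.208919
990,48.1695,5.84504,4.43385,0.404749,0.250317,0.205495
1000,46.5139,5.66645,4.55244,0.36,0.250106,0.203281
1010,44.9308,5.50823,4.61783,0.311122,0.250033,0.201899
1020,43.4165,5.34462,4.66752,0.250962,0.25001,0.201065
1030,41.9671,5.1862,4.71128,0.192242,0.250003,0.200579
1040,40.5795,5.04357,4.75892,0.147681,0.250001,0.200305
1050,39.2504,4.92735,4.82023,0.13,0.25,0.200156
1060,37.9768,4.83085,4.90021,0.13032,0.25,0.200077
1070,36.7559,4.74226,4.9959,0.13256,0.25,0.200037
1080,35.5851,4.66442,5.10516,0.13864,0.25,0.200017
1090,34.4619,4.60019,5.22585,0.15048,0.25,0.200008
1100,33.3839,4.55244,5.35581,0.17,0.25,0.200003
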