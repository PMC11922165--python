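wavelength_nm,power
380,5.7447
381,5.9517
382,6.1677
383,6.3935
384,6.6300
385,6.8780
386,7.1385
387,7.4126
388,7.7014
389,8.0063
390,8.3286
391,8.6699
392,9.0318
393,9.4162
394,9.8248
395,10.2598
396,10.7233
397,11.2177
398,11.7452
399,12.3085
400,12.9102
401,13.5530
402,14.2396
403,14.9730
404,15.7560
405,16.5915
406,17.4823
407,18.4313
408,19.4411
409,20.5144
410,21.6536
411,22.8609
412,24.1383
413,25.4874
414,26.9094
415,28.4054
416,29.9758
417,31.6205
418,33.3390
419,35.1301
420,36.9922
421,38.9229
422,40.9190
423,42.9770
424,45.0923
425,47.2599
426,49.4739
427,51.7279
428,54.0147
429,56.3267
430,58.6553
431,60.9919
432,63.3270
433,65.6511
434,67.9540
435,70.2256
436,72.4555
437,74.6335
438,76.7491
439,78.7924
440,80.7535
441,82.6231
442,84.3924
443,86.0529
444,87.5973
445,89.0187
446,90.3114
447,91.4703
448,92.4915
449,93.3723
450,94.1108
451,94.7064
452,95.1595
453,95.4717
454,95.6457
455,95.6851
456,95.5947
457,95.3802
458,95.0481
459,94.6057
460,94.0610
461,93.4229
462,92.7003
463,91.9030
464,91.0407
465,90.1235
466,89.1617
467,88.1652
468,87.1441
469,86.1083
470,85.0671
471,84.0296
472,83.0046
473,82.0001
474,81.0237
475,80.0822
476,79.1820
477,78.3285
478,77.5268
479,76.7810
480,76.0946
481,75.4703
482,74.9105
483,74.4164
484,73.9892
485,73.6290
486,73.3356
487,73.1085
488,72.9463
489,72.8477
490,72.8106
491,72.8330
492,72.9123
493,73.0458
494,73.2308
495,73.4643
496,73.7433
497,74.0645
498,74.4250
499,74.8216
500,75.2511
501,75.7106
502,76.1971
503,76.7078
504,77.2398
505,77.7905
506,78.3573
507,78.9380
508,79.5301
509,80.1315
510,80.7403
511,81.3545
512,81.9723
513,82.5923
514,83.2127
515,83.8322
516,84.4495
517,85.0634
518,85.6728
519,86.2767
520,86.8741
521,87.4642
522,88.0461
523,88.6192
524,89.1827
525,89.7360
526,90.2787
527,90.8100
528,91.3296
529,91.8370
530,92.3318
531,92.8135
532,93.2818
533,93.7364
534,94.1769
535,94.6031
536,95.0147
537,95.4113
538,95.7928
539,96.1588
540,96.5093
541,96.8440
542,97.1626
543,97.4650
544,97.7511
545,98.0206
546,98.2735
547,98.5095
548,98.7285
549,98.9305
550,99.1153
551,99.2828
552,99.4329
553,99.5655
554,99.6806
555,99.7781
556,99.8579
557,99.9201
558,99.9645
559,99.9911
560,100.0000
561,99.9911
562,99.9645
563,99.9200
564,99.8579
565,99.7780
566,99.6805
567,99.5654
568,99.4327
569,99.2826
570,99.1151
571,98.9302
572,98.7282
573,98.5090
574,98.2729
575,98.0199
576,97.7501
577,97.4638
578,97.1611
579,96.8420
580,96.5069
581,96.1558
582,95.7890
583,95.4066
584,95.0089
585,94.5959
586,94.1681
587,93.7255
588,93.2684
589,92.7970
590,92.3116
591,91.8125
592,91.2997
593,90.7738
594,90.2348
595,89.6830
596,89.1188
597,88.5424
598,87.9541
599,87.3541
600,86.7428
601,86.1205
602,85.4875
603,84.8440
604,84.1904
605,83.5270
606,82.8541
607,82.1720
608,81.4810
609,80.7815
610,80.0737
611,79.3581
612,78.6348
613,77.9043
614,77.1669
615,76.4228
616,75.6725
617,74.9162
618,74.1543
619,73.3871
620,72.6149
621,71.8381
622,71.0569
623,70.2718
624,69.4829
625,68.6908
626,67.8955
627,67.0976
628,66.2972
629,65.4948
630,64.6905
631,63.8848
632,63.0779
633,62.2701
634,61.4617
635,60.6531
636,59.8444
637,59.0360
638,58.2282
639,57.4213
640,56.6154
641,55.8110
642,55.0081
643,54.2072
644,53.4085
645,52.6122
646,51.8185
647,51.0278
648,50.2402
649,49.4559
650,48.6752
651,47.8984
652,47.1255
653,46.3569
654,45.5927
655,44.8332
656,44.0784
657,43.3287
658,42.5841
659,41.8449
660,41.1112
661,40.3832
662,39.6611
663,38.9449
664,38.2349
665,37.5311
666,36.8338
667,36.1429
668,35.4588
669,34.7813
670,34.1108
671,33.4473
672,32.7908
673,32.1415
674,31.4995
675,30.8647
676,30.2375
677,29.6176
678,29.0054
679,28.4007
680,27.8037
681,27.2144
682,26.6329
683,26.0592
684,25.4933
685,24.9352
686,24.3850
687,23.8428
688,23.3084
689,22.7820
690,22.2635
691,21.7529
692,21.2503
693,20.7556
694,20.2688
695,19.7899
696,19.3188
697,18.8557
698,18.4004
699,17.9528
700,17.5131
701,17.0811
702,16.6567
703,16.2401
704,15.8310
705,15.4295
706,15.0355
707,14.6490
708,14.2698
709,13.8980
710,13.5335
711,13.1762
712,12.8261
713,12.4830
714,12.1470
715,11.8179
716,11.4957
717,11.1802
718,10.8715
719,10.5695
720,10.2740
721,9.9850
722,9.7024
723,9.4261
724,9.1560
725,8.8922
726,8.6343
727,8.3825
728,8.1366
729,7.8965
730,7.6621
731,7.4333
732,7.2101
733,6.9923
734,6.7800
735,6.5729
736,6.3709
737,6.1741
738,5.9824
739,5.7955
740,5.6135
741,5.4362
742,5.2636
743,5.0956
744,4.9320
745,4.7729
746,4.6180
747,4.4674
748,4.3210
749,4.1786
750,4.0401
751,3.9056
752,3.7749
753,3.6479
754,3.5245
755,3.4047
756,3.2884
757,3.1756
758,3.0660
759,2.9597
760,2.8566
761,2.7565
762,2.6595
763,2.5655
764,2.4743
765,2.3860
766,2.3004
767,2.2175
768,2.1372
769,2.0594
770,1.9841
771,1.9112
772,1.8407
773,1.7725
774,1.7064
775,1.6426
776,1.5809
777,1.5212
778,1.4635
779,1.4077
780,1.3538
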