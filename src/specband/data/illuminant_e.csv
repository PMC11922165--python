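wavelength_nm,power
380,100.0000
381,100.0000
382,100.0000
383,100.0000
384,100.0000
385,100.0000
386,100.0000
387,100.0000
388,100.0000
389,100.0000
390,100.0000
391,100.0000
392,100.0000
393,100.0000
394,100.0000
395,100.0000
396,100.0000
397,100.0000
398,100.0000
399,100.0000
400,100.0000
401,100.0000
402,100.0000
403,100.0000
404,100.0000
405,100.0000
406,100.0000
407,100.0000
408,100.0000
409,100.0000
410,100.0000
411,100.0000
412,100.0000
413,100.0000
414,100.0000
415,100.0000
416,100.0000
417,100.0000
418,100.0000
419,100.0000
420,100.0000
421,100.0000
422,100.0000
423,100.0000
424,100.0000
425,100.0000
426,100.0000
427,100.0000
428,100.0000
429,100.0000
430,100.0000
431,100.0000
432,100.0000
433,100.0000
434,100.0000
435,100.0000
436,100.0000
437,100.0000
438,100.0000
439,100.0000
440,100.0000
441,100.0000
442,100.0000
443,100.0000
444,100.0000
445,100.0000
446,100.0000
447,100.0000
448,100.0000
449,100.0000
450,100.0000
451,100.0000
452,100.0000
453,100.0000
454,100.0000
455,100.0000
456,100.0000
457,100.0000
458,100.0000
459,100.0000
460,100.0000
461,100.0000
462,100.0000
463,100.0000
464,100.0000
465,100.0000
466,100.0000
467,100.0000
468,100.0000
469,100.0000
470,100.0000
471,100.0000
472,100.0000
473,100.0000
474,100.0000
475,100.0000
476,100.0000
477,100.0000
478,100.0000
479,100.0000
480,100.0000
481,100.0000
482,100.0000
483,100.0000
484,100.0000
485,100.0000
486,100.0000
487,100.0000
488,100.0000
489,100.0000
490,100.0000
491,100.0000
492,100.0000
493,100.0000
494,100.0000
495,100.0000
496,100.0000
497,100.0000
498,100.0000
499,100.0000
500,100.0000
501,100.0000
502,100.0000
503,100.0000
504,100.0000
505,100.0000
506,100.0000
507,100.0000
508,100.0000
509,100.0000
510,100.0000
511,100.0000
512,100.0000
513,100.0000
514,100.0000
515,100.0000
516,100.0000
517,100.0000
518,100.0000
519,100.0000
520,100.0000
521,100.0000
522,100.0000
523,100.0000
524,100.0000
525,100.0000
526,100.0000
527,100.0000
528,100.0000
529,100.0000
530,100.0000
531,100.0000
532,100.0000
533,100.0000
534,100.0000
535,100.0000
536,100.0000
537,100.0000
538,100.0000
539,100.0000
540,100.0000
541,100.0000
542,100.0000
543,100.0000
544,100.0000
545,100.0000
546,100.0000
547,100.0000
548,100.0000
549,100.0000
550,100.0000
551,100.0000
552,100.0000
553,100.0000
554,100.0000
555,100.0000
556,100.0000
557,100.0000
558,100.0000
559,100.0000
560,100.0000
561,100.0000
562,100.0000
563,100.0000
564,100.0000
565,100.0000
566,100.0000
567,100.0000
568,100.0000
569,100.0000
570,100.0000
571,100.0000
572,100.0000
573,100.0000
574,100.0000
575,100.0000
576,100.0000
577,100.0000
578,100.0000
579,100.0000
580,100.0000
581,100.0000
582,100.0000
583,100.0000
584,100.0000
585,100.0000
586,100.0000
587,100.0000
588,100.0000
589,100.0000
590,100.0000
591,100.0000
592,100.0000
593,100.0000
594,100.0000
595,100.0000
596,100.0000
597,100.0000
598,100.0000
599,100.0000
600,100.0000
601,100.0000
602,100.0000
603,100.0000
604,100.0000
605,100.0000
606,100.0000
607,100.0000
608,100.0000
609,100.0000
610,100.0000
611,100.0000
612,100.0000
613,100.0000
614,100.0000
615,100.0000
616,100.0000
617,100.0000
618,100.0000
619,100.0000
620,100.0000
621,100.0000
622,100.0000
623,100.0000
624,100.0000
625,100.0000
626,100.0000
627,100.0000
628,100.0000
629,100.0000
630,100.0000
631,100.0000
632,100.0000
633,100.0000
634,100.0000
635,100.0000
636,100.0000
637,100.0000
638,100.0000
639,100.0000
640,100.0000
641,100.0000
642,100.0000
643,100.0000
644,100.0000
645,100.0000
646,100.0000
647,100.0000
648,100.0000
649,100.0000
650,100.0000
651,100.0000
652,100.0000
653,100.0000
654,100.0000
655,100.0000
656,100.0000
657,100.0000
658,100.0000
659,100.0000
660,100.0000
661,100.0000
662,100.0000
663,100.0000
664,100.0000
665,100.0000
666,100.0000
667,100.0000
668,100.0000
669,100.0000
670,100.0000
671,100.0000
672,100.0000
673,100.0000
674,100.0000
675,100.0000
676,100.0000
677,100.0000
678,100.0000
679,100.0000
680,100.0000
681,100.0000
682,100.0000
683,100.0000
684,100.0000
685,100.0000
686,100.0000
687,100.0000
688,100.0000
689,100.0000
690,100.0000
691,100.0000
692,100.0000
693,100.0000
694,100.0000
695,100.0000
696,100.0000
697,100.0000
698,100.0000
699,100.0000
700,100.0000
701,100.0000
702,100.0000
703,100.0000
704,100.0000
705,100.0000
706,100.0000
707,100.0000
708,100.0000
709,100.0000
710,100.0000
711,100.0000
712,100.0000
713,100.0000
714,100.0000
715,100.0000
716,100.0000
717,100.0000
718,100.0000
719,100.0000
720,100.0000
721,100.0000
722,100.0000
723,100.0000
724,100.0000
725,100.0000
726,100.0000
727,100.0000
728,100.0000
729,100.0000
730,100.0000
731,100.0000
732,100.0000
733,100.0000
734,100.0000
735,100.0000
736,100.0000
737,100.0000
738,100.0000
739,100.0000
740,100.0000
741,100.0000
742,100.0000
743,100.0000
744,100.0000
745,100.0000
746,100.0000
747,100.0000
748,100.0000
749,100.0000
750,100.0000
751,100.0000
752,100.0000
753,100.0000
754,100.0000
755,100.0000
756,100.0000
757,100.0000
758,100.0000
759,100.0000
760,100.0000
761,100.0000
762,100.0000
763,100.0000
764,100.0000
765,100.0000
766,100.0000
767,100.0000
768,100.0000
769,100.0000
770,100.0000
771,100.0000
772,100.0000
773,100.0000
774,100.0000
775,100.0000
776,100.0000
777,100.0000
778,100.0000
779,100.0000
780,100.0000
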