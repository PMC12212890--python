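# NVSS 2021 leading causes of mortality in the United States, counts by gender.
# Transcribed from the published leading-causes report (12 named causes + other).
# ICD-10 ranges: heart I00-I09,I11,I13,I20-I51; cancer C00-C97; covid19 U07.1;
# accidents V01-X59,Y85-Y86; cerebrovascular I60-I69; chronic_lower_respiratory
# J40-J47; alzheimer G30; diabetes E10-E14; chronic_liver K70,K73-K74;
# nephritis N00-N07,N17-N19,N25-N27; suicide U03,X60-X84,Y87.0; hypertension I10,I12,I15.
# Known transcription notes: the diabetes row is stored as printed even though
# women + men (44,666 + 56,628 = 101,294) does not equal the printed total
# (103,294); the loader flags it rather than correcting it.
cause,total,women,men
heart,695547,310661,384886
cancer,605213,286543,318670
covid19,416893,180283,236610
accidents,224935,75333,149602
cerebrovascular,162890,92038,70852
chronic_lower_respiratory,142342,74814,67528
alzheimer,119399,82424,36975
diabetes,103294,44666,56628
chronic_liver,56585,20878,35707
nephritis,54358,25769,28589
suicide,48183,9825,38358
hypertension,42816,22730,20086
other,791776,400159,391617
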