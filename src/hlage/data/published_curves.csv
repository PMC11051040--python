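bone,group,family,a,b,c,aic,aicc,rss,selected,n_source,note
femur,male,linear,0.217859,-6.43422,,25.82,27.82,3.234,False,16,
femur,male,quadratic,0.00106893,0.077086,-2.28129,-18.35,-14.71,0.1804,True,16,
femur,male,exponential,11.5213,0.00979342,-14.5196,-15.94,-12.3,0.2098,False,16,
femur,female,linear,0.191588,-5.93988,,24.19,26.59,3.007,False,14,
femur,female,quadratic,0.00114036,0.0387797,-1.33028,-12.01,-7.56,0.1963,False,14,
femur,female,exponential,6.84604,0.0121551,-9.07047,-14.22,-9.77,0.1676,True,14,
tibia,male,linear,0.216145,-6.14786,,20.56,22.56,2.328,False,16,
tibia,male,quadratic,0.000860092,0.103426,-2.84765,-13.35,-9.71,0.2467,True,16,
tibia,male,exponential,16.227,0.00787971,-19.5643,-11.19,-7.55,0.2823,False,16,
tibia,female,linear,0.19219,-5.90254,,22.61,25.01,2.685,False,14,
tibia,female,quadratic,0.00105703,0.0508895,-1.64875,-4.59,-0.15,0.3333,False,14,
tibia,female,exponential,7.78153,0.011363,-10.1631,-6.38,-1.94,0.2933,True,14,sign corrected from printed 6.38
tibia,unisex,linear,0.211442,-6.50326,,33.78,35.78,5.318,False,16,
tibia,unisex,quadratic,0.00128889,0.0374516,-1.24991,4.29,7.93,0.7431,False,16,
tibia,unisex,exponential,6.79694,0.0128072,-9.00042,1.11,4.75,0.6093,True,16,
femur,unisex,linear,0.211759,-6.65994,,36.57,38.57,6.331,False,16,
femur,unisex,quadratic,0.00142038,0.0191624,-0.812149,6.1,9.74,0.8323,False,16,
femur,unisex,exponential,5.61797,0.0140969,-7.60929,2.58,6.21,0.6677,True,16,
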