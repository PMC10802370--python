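# Synthetic LMS reference table (stand-in for WHO growth standards;
# smooth plausible curves, for offline tests and examples only).
measure,sex,key,L,M,S
weight-for-length,F,45,-0.35,2.5387,0.090
weight-for-length,F,50,-0.35,3.2010,0.090
weight-for-length,F,55,-0.35,3.9477,0.090
weight-for-length,F,60,-0.35,4.7806,0.090
weight-for-length,F,65,-0.35,5.7011,0.090
weight-for-length,F,70,-0.35,6.7107,0.090
weight-for-length,F,75,-0.35,7.8106,0.090
weight-for-length,F,80,-0.35,9.0022,0.090
weight-for-length,F,85,-0.35,10.2866,0.090
weight-for-length,F,90,-0.35,11.6650,0.090
weight-for-length,F,95,-0.35,13.1384,0.090
weight-for-length,F,100,-0.35,14.7079,0.090
weight-for-length,F,105,-0.35,16.3745,0.090
weight-for-length,F,110,-0.35,18.1391,0.090
weight-for-length,M,45,-0.35,2.6173,0.090
weight-for-length,M,50,-0.35,3.3000,0.090
weight-for-length,M,55,-0.35,4.0698,0.090
weight-for-length,M,60,-0.35,4.9285,0.090
weight-for-length,M,65,-0.35,5.8775,0.090
weight-for-length,M,70,-0.35,6.9182,0.090
weight-for-length,M,75,-0.35,8.0522,0.090
weight-for-length,M,80,-0.35,9.2806,0.090
weight-for-length,M,85,-0.35,10.6048,0.090
weight-for-length,M,90,-0.35,12.0258,0.090
weight-for-length,M,95,-0.35,13.5448,0.090
weight-for-length,M,100,-0.35,15.1628,0.090
weight-for-length,M,105,-0.35,16.8809,0.090
weight-for-length,M,110,-0.35,18.7001,0.090
head-circumference-for-age,F,0,1.0,34.6000,0.030
head-circumference-for-age,F,40,1.0,36.9912,0.030
head-circumference-for-age,F,80,1.0,38.9058,0.030
head-circumference-for-age,F,120,1.0,40.4390,0.030
head-circumference-for-age,F,160,1.0,41.6667,0.030
head-circumference-for-age,F,200,1.0,42.6497,0.030
head-circumference-for-age,F,240,1.0,43.4368,0.030
head-circumference-for-age,F,280,1.0,44.0671,0.030
head-circumference-for-age,F,320,1.0,44.5718,0.030
head-circumference-for-age,F,360,1.0,44.9760,0.030
head-circumference-for-age,F,400,1.0,45.2996,0.030
head-circumference-for-age,F,440,1.0,45.5587,0.030
head-circumference-for-age,F,480,1.0,45.7662,0.030
head-circumference-for-age,F,520,1.0,45.9323,0.030
head-circumference-for-age,F,560,1.0,46.0654,0.030
head-circumference-for-age,F,600,1.0,46.1719,0.030
head-circumference-for-age,F,640,1.0,46.2572,0.030
head-circumference-for-age,F,680,1.0,46.3255,0.030
head-circumference-for-age,F,720,1.0,46.3802,0.030
head-circumference-for-age,F,760,1.0,46.4240,0.030
head-circumference-for-age,M,0,1.0,35.0000,0.030
head-circumference-for-age,M,40,1.0,37.3912,0.030
head-circumference-for-age,M,80,1.0,39.3058,0.030
head-circumference-for-age,M,120,1.0,40.8390,0.030
head-circumference-for-age,M,160,1.0,42.0667,0.030
head-circumference-for-age,M,200,1.0,43.0497,0.030
head-circumference-for-age,M,240,1.0,43.8368,0.030
head-circumference-for-age,M,280,1.0,44.4671,0.030
head-circumference-for-age,M,320,1.0,44.9718,0.030
head-circumference-for-age,M,360,1.0,45.3760,0.030
head-circumference-for-age,M,400,1.0,45.6996,0.030
head-circumference-for-age,M,440,1.0,45.9587,0.030
head-circumference-for-age,M,480,1.0,46.1662,0.030
head-circumference-for-age,M,520,1.0,46.3323,0.030
head-circumference-for-age,M,560,1.0,46.4654,0.030
head-circumference-for-age,M,600,1.0,46.5719,0.030
head-circumference-for-age,M,640,1.0,46.6572,0.030
head-circumference-for-age,M,680,1.0,46.7255,0.030
head-circumference-for-age,M,720,1.0,46.7802,0.030
head-circumference-for-age,M,760,1.0,46.8240,0.030
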