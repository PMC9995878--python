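0.0000000000 0.4459866637 -0.4511141836 0.8595996622 0.0612831107 -0.0652383097 -0.5226848084 0.5910697537 0.9051173954 -0.5401702473 0.1884506168 -0.4696801849 0.9874269038 0.7439053909 -0.0191351372 -0.2485580440 0.5069197098 0.7670290803 0.8249859502 0.1045204990
0.0000000000 0.7295671416 0.6769607069 -0.3903658154 0.9146604300 -0.5460231248 0.3931749432 0.6547233906 0.0728976122 -0.1826779038 0.9760092830 0.8821657334 0.1056180986 0.2637579717 0.0005741488 0.8319106125 -0.1646018260 0.6400831134 -0.5032630865 0.4943175267
0.0000000000 0.5184859513 -0.5815670165 0.3297013057 -0.3995505952 0.8352261431 0.7564483162 -0.4711409854 -0.4188656570 0.8214894323 0.1090515682 -0.0344113737 0.1176134640 0.6140329810 0.9998167416 0.4961286442 0.8461315776 0.0442718643 -0.2571467435 0.8629748826
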