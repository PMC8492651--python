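# miniature disease-to-phenotype annotation fixture (disease_id <TAB> hpo_id)
disease_id	hpo_id
OMIM:109400	HP:0010603
OMIM:109400	HP:0010610
OMIM:109400	HP:0002671
OMIM:109400	HP:0005462
OMIM:109400	HP:0002885
OMIM:109400	HP:0000256
OMIM:109400	HP:0000772
OMIM:109400	HP:0000925
OMIM:109400	HP:0000518
OMIM:109400	HP:0000175
OMIM:100050	HP:0002885
OMIM:100050	HP:0002119
OMIM:100050	HP:0000256
OMIM:100050	HP:0000365
OMIM:100100	HP:0000772
OMIM:100100	HP:0000925
OMIM:100100	HP:0000175
OMIM:100100	HP:0010442
OMIM:100150	HP:0000518
OMIM:100150	HP:0000589
OMIM:100150	HP:0000486
OMIM:100150	HP:0000568
OMIM:100200	HP:0000107
OMIM:100200	HP:0000104
OMIM:100200	HP:0000365
OMIM:100200	HP:0000098
OMIM:100250	HP:0002671
OMIM:100250	HP:0010603
OMIM:100250	HP:0010618
OMIM:100300	HP:0000098
OMIM:100300	HP:0000365
OMIM:100300	HP:0000695
OMIM:100350	HP:0004482
OMIM:100350	HP:0000892
OMIM:100350	HP:0100702
OMIM:100400	HP:0002308
OMIM:100400	HP:0002126
OMIM:100400	HP:0000589
OMIM:100450	HP:0410030
OMIM:100450	HP:0000175
OMIM:100450	HP:0000925
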