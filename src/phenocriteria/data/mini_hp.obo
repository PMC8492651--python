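format-version: 1.2
ontology: mini_hp
remark: Miniature phenotype ontology fixture. Contains every term referenced by the shipped diagnostic criteria definitions, with plausible is_a placements, plus a pair of descendant terms, one alt_id and one obsolete stanza for parser exercises. Not a redistribution of the real ontology.

[Term]
id: HP:0000001
name: All

[Term]
id: HP:0000118
name: Phenotypic abnormality
is_a: HP:0000001 ! All

[Term]
id: HP:0002664
name: Neoplasm
is_a: HP:0000118 ! Phenotypic abnormality

[Term]
id: HP:0000924
name: Abnormality of the skeletal system
is_a: HP:0000118 ! Phenotypic abnormality

[Term]
id: HP:0000478
name: Abnormality of the eye
is_a: HP:0000118 ! Phenotypic abnormality

[Term]
id: HP:0000152
name: Abnormality of head or neck
is_a: HP:0000118 ! Phenotypic abnormality

[Term]
id: HP:0000707
name: Abnormality of the nervous system
is_a: HP:0000118 ! Phenotypic abnormality

[Term]
id: HP:0000119
name: Abnormality of the genitourinary system
is_a: HP:0000118 ! Phenotypic abnormality

[Term]
id: HP:0000598
name: Abnormality of the ear
is_a: HP:0000118 ! Phenotypic abnormality

[Term]
id: HP:0001574
name: Abnormality of the integument
is_a: HP:0000118 ! Phenotypic abnormality

[Term]
id: HP:0001507
name: Growth abnormality
is_a: HP:0000118 ! Phenotypic abnormality

[Term]
id: HP:0010603
name: Odontogenic keratocysts of the jaw
is_a: HP:0002664 ! Neoplasm
is_a: HP:0000152 ! Abnormality of head or neck

[Term]
id: HP:0002671
name: Basal cell carcinoma
is_a: HP:0002664 ! Neoplasm
is_a: HP:0001574 ! Abnormality of the integument

[Term]
id: HP:0002885
name: Medulloblastoma
is_a: HP:0002664 ! Neoplasm
is_a: HP:0000707 ! Abnormality of the nervous system

[Term]
id: HP:0010618
name: Ovarian fibroma
is_a: HP:0002664 ! Neoplasm

[Term]
id: HP:0010610
name: Palmar pits
is_a: HP:0001574 ! Abnormality of the integument

[Term]
id: HP:0005462
name: Calcification of the falx cerebri
is_a: HP:0000707 ! Abnormality of the nervous system

[Term]
id: HP:0002119
name: Ventriculomegaly
is_a: HP:0000707 ! Abnormality of the nervous system

[Term]
id: HP:0002126
name: Polymicrogyria
is_a: HP:0000707 ! Abnormality of the nervous system

[Term]
id: HP:0002308
name: Chiari malformation
is_a: HP:0000707 ! Abnormality of the nervous system

[Term]
id: HP:0100702
name: Arachnoid cyst
is_a: HP:0000707 ! Abnormality of the nervous system

[Term]
id: HP:0000256
name: Macrocephaly
alt_id: HP:0001355
is_a: HP:0000152 ! Abnormality of head or neck

[Term]
id: HP:0004482
name: Relative macrocephaly
is_a: HP:0000256 ! Macrocephaly

[Term]
id: HP:0000175
name: Cleft palate
is_a: HP:0000152 ! Abnormality of head or neck

[Term]
id: HP:0410030
name: Cleft lip
is_a: HP:0000152 ! Abnormality of head or neck

[Term]
id: HP:0000695
name: Natal tooth
is_a: HP:0000152 ! Abnormality of head or neck

[Term]
id: HP:0000925
name: Abnormality of the vertebral column
is_a: HP:0000924 ! Abnormality of the skeletal system

[Term]
id: HP:0000772
name: Abnormality of the ribs
is_a: HP:0000924 ! Abnormality of the skeletal system

[Term]
id: HP:0000892
name: Bifid ribs
is_a: HP:0000772 ! Abnormality of the ribs

[Term]
id: HP:0010442
name: Polydactyly
is_a: HP:0000924 ! Abnormality of the skeletal system

[Term]
id: HP:0000098
name: Tall stature
is_a: HP:0001507 ! Growth abnormality

[Term]
id: HP:0000518
name: Cataract
is_a: HP:0000478 ! Abnormality of the eye

[Term]
id: HP:0000589
name: Coloboma
is_a: HP:0000478 ! Abnormality of the eye

[Term]
id: HP:0000568
name: Microphthalmia
is_a: HP:0000478 ! Abnormality of the eye

[Term]
id: HP:0008058
name: Aplasia/Hypoplasia of the lens
is_a: HP:0000478 ! Abnormality of the eye

[Term]
id: HP:0000486
name: Strabismus
is_a: HP:0000478 ! Abnormality of the eye

[Term]
id: HP:0000107
name: Renal cyst
is_a: HP:0000119 ! Abnormality of the genitourinary system

[Term]
id: HP:0000104
name: Renal agenesis
is_a: HP:0000119 ! Abnormality of the genitourinary system

[Term]
id: HP:0000365
name: Hearing impairment
is_a: HP:0000598 ! Abnormality of the ear

[Term]
id: HP:0009999
name: Retired fixture term
is_obsolete: true
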