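sample_id,locality,culture_period,estimated_date,haplogroup
Bau-11,Baucina,Sicanian,600–400 BCE,H
Bau-13,Baucina,Sicanian,600–400 BCE,T2c1d+152
Bau-14,Baucina,Sicanian,600–400 BCE,J1c
Bau-16,Baucina,Sicanian,600–400 BCE,T2b3+151
Bau-17,Baucina,Sicanian,600–400 BCE,H1e8
Bau-19,Baucina,Sicanian,600–400 BCE,T2e7
Bau-1A,Baucina,Sicanian,600–400 BCE,I4a
Bau-1,Baucina,Sicanian,600–400 BCE,H1
Bau-20,Baucina,Sicanian,600–400 BCE,T2e7
Bau-22,Baucina,Sicanian,600–400 BCE,U5a1a1
Bau-23,Baucina,Sicanian,600–400 BCE,U5b1d1a
Bau-25,Baucina,Sicanian,600–400 BCE,H1e8
Bau-26,Baucina,Sicanian,600–400 BCE,T2b3+151
Bau-4,Baucina,Sicanian,600–400 BCE,H
Bau-6,Baucina,Sicanian,600–400 BCE,T2b3+151
Bau-12G,Baucina,Sicanian,600–400 BCE,V+72at
Bau-15G,Baucina,Sicanian,600–400 BCE,T2b3+151
Bau-EST6,Baucina,Greek,600–400 BCE,U3a1
Bau-EST7,Baucina,Greek,600–400 BCE,"H+16,311"
Bau-EST9,Baucina,Greek,600–400 BCE,V+72at
MO-101,Motya,Phoenician,730–690 cal. BCE,HV0a
MO-103,Motya,Bronze Age,"1,690–1,495 cal. BCE",H4a1
MO-104a,Motya,Bronze Age,2030–1740 cal. BCE,H1j
MO-104b,Motya,Phoenician,805–535 cal. BCE,HV0+195
MO-106b,Motya,Phoenician,755–400 cal. BCE,V
M0-107b,Motya,Bronze Age,"1,640–1,420 cal. BCE",L3b1a5
MO-108,Motya,Bronze Age,"1890–1,620 cal. BCE",I1
MO-109a,Motya,Bronze Age,"1890–1,530 cal. BCE",K2b1
MO-114b,Motya,Bronze Age,"1,640–1,430 cal. BCE",H4a1
MO-115,Motya,Bronze Age,"1,610–1,410 cal. BCE",T2h
MO-121a,Motya,Bronze Age,"1775–1,505 cal. BCE",U5b1d1a
MA90,Lilibeo,Phoenician,3rd cen. BCE,V25
MOK1,Mokarta,Late Bronze Age,"1,250–1050 BCE",H1
MOK114C,Mokarta,Late Bronze Age,"1,250–1050 BCE",H5a
T73-7,Ispica,Bronze Age,"1,500–1200 BCE",K1a
T73-M73-1,Ispica,Bronze Age,"1,500–1200 BCE",X2b+226
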