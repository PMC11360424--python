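pesticide,ld50,lc50,test_species,acute_rq,chronic_rq
bifenthrin,1800,75,Colinus virginianus,0.0083,0.13
carbaryl,2290,300,Coturnix japonica,0.34,0.041
chlorantraniliprole,>2250,120,Colinus virginianus,<0.011,0.0031
chlorpyrifos,8.41,25,Phasianus colchicus,30,4.5
cyfluthrin,>2000,250,Colinus virginianus,0.011,0.39
dimethoate,5.4,4.0,Agelaius phoeniceus,12,12
esfenvalerate,381,608,Colinus virginianus,0.072,0.028
indoxacarb,98,144,Colinus virginianus,0.34,0.15
lambda-cyhalothrin,3950,5,Anas platyrhynchos,0.0057,2.1
malathion,167,110,Phasianus colchicus,1.8,0.039
methomyl,15,150,Phasianus colchicus,18,1.1
methoxyfenozide,>2250,819,Colinus virginianus,<0.057,0.014
permethrin,>9869,125,Anas platyrhynchos,<0.022,0.0099
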