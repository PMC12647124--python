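segment_label,lobe,generation,parent
RUL.A,RUL,1,
RUL.Aa,RUL,2,RUL.A
RUL.AaI,RUL,3,RUL.Aa
RUL.AaIA,RUL,4,RUL.AaI
RUL.AaIAa,RUL,5,RUL.AaIA
RUL.AaIAaI,RUL,6,RUL.AaIAa
RUL.AaIAaIA,RUL,7,RUL.AaIAaI
RUL.AaIAaIAa,RUL,8,RUL.AaIAaIA
RUL.AaIAaIAaI,RUL,9,RUL.AaIAaIAa
RUL.AaIAaIAaIA,RUL,10,RUL.AaIAaIAaI
RUL.AaIAaIAaIAa,RUL,11,RUL.AaIAaIAaIA
RUL.Ab,RUL,2,RUL.A
RUL.AbI,RUL,3,RUL.Ab
RUL.AaII,RUL,3,RUL.Aa
RUL.AaIIA,RUL,4,RUL.AaII
RUL.AaIB,RUL,4,RUL.AaI
RUL.AaIBa,RUL,5,RUL.AaIB
RUL.AaIAb,RUL,5,RUL.AaIA
RUL.AaIAbI,RUL,6,RUL.AaIAb
RUL.AaIAaII,RUL,6,RUL.AaIAa
RUL.AaIAaIIA,RUL,7,RUL.AaIAaII
RUL.AaIAaIB,RUL,7,RUL.AaIAaI
RUL.AaIAaIBa,RUL,8,RUL.AaIAaIB
RUL.AaIAaIAb,RUL,8,RUL.AaIAaIA
RUL.AaIAaIAbI,RUL,9,RUL.AaIAaIAb
RUL.AaIAaIAaII,RUL,9,RUL.AaIAaIAa
RUL.AaIAaIAaIIA,RUL,10,RUL.AaIAaIAaII
RUL.AaIAaIAaIB,RUL,10,RUL.AaIAaIAaI
RUL.AaIAaIAaIBa,RUL,11,RUL.AaIAaIAaIB
RUL.AaIAaIAaIAb,RUL,11,RUL.AaIAaIAaIA
RML.A,RML,1,
RML.Aa,RML,2,RML.A
RML.AaI,RML,3,RML.Aa
RML.AaIA,RML,4,RML.AaI
RML.AaIAa,RML,5,RML.AaIA
RML.AaIAaI,RML,6,RML.AaIAa
RML.AaIAaIA,RML,7,RML.AaIAaI
RML.AaIAaIAa,RML,8,RML.AaIAaIA
RML.AaIAaIAaI,RML,9,RML.AaIAaIAa
RML.AaIAaIAaIA,RML,10,RML.AaIAaIAaI
RML.AaIAaIAaIAa,RML,11,RML.AaIAaIAaIA
RML.Ab,RML,2,RML.A
RML.AbI,RML,3,RML.Ab
RML.AaII,RML,3,RML.Aa
RML.AaIIA,RML,4,RML.AaII
RML.AaIB,RML,4,RML.AaI
RML.AaIBa,RML,5,RML.AaIB
RML.AaIAb,RML,5,RML.AaIA
RML.AaIAbI,RML,6,RML.AaIAb
RML.AaIAaII,RML,6,RML.AaIAa
RML.AaIAaIIA,RML,7,RML.AaIAaII
RML.AaIAaIB,RML,7,RML.AaIAaI
RML.AaIAaIBa,RML,8,RML.AaIAaIB
RML.AaIAaIAb,RML,8,RML.AaIAaIA
RML.AaIAaIAbI,RML,9,RML.AaIAaIAb
RML.AaIAaIAaII,RML,9,RML.AaIAaIAa
RML.AaIAaIAaIIA,RML,10,RML.AaIAaIAaII
RML.AaIAaIAaIB,RML,10,RML.AaIAaIAaI
RML.AaIAaIAaIBa,RML,11,RML.AaIAaIAaIB
RML.AaIAaIAaIAb,RML,11,RML.AaIAaIAaIA
RLL.A,RLL,1,
RLL.Aa,RLL,2,RLL.A
RLL.AaI,RLL,3,RLL.Aa
RLL.AaIA,RLL,4,RLL.AaI
RLL.AaIAa,RLL,5,RLL.AaIA
RLL.AaIAaI,RLL,6,RLL.AaIAa
RLL.AaIAaIA,RLL,7,RLL.AaIAaI
RLL.AaIAaIAa,RLL,8,RLL.AaIAaIA
RLL.AaIAaIAaI,RLL,9,RLL.AaIAaIAa
RLL.AaIAaIAaIA,RLL,10,RLL.AaIAaIAaI
RLL.AaIAaIAaIAa,RLL,11,RLL.AaIAaIAaIA
RLL.Ab,RLL,2,RLL.A
RLL.AbI,RLL,3,RLL.Ab
RLL.AaII,RLL,3,RLL.Aa
RLL.AaIIA,RLL,4,RLL.AaII
RLL.AaIB,RLL,4,RLL.AaI
RLL.AaIBa,RLL,5,RLL.AaIB
RLL.AaIAb,RLL,5,RLL.AaIA
RLL.AaIAbI,RLL,6,RLL.AaIAb
RLL.AaIAaII,RLL,6,RLL.AaIAa
RLL.AaIAaIIA,RLL,7,RLL.AaIAaII
RLL.AaIAaIB,RLL,7,RLL.AaIAaI
RLL.AaIAaIBa,RLL,8,RLL.AaIAaIB
RLL.AaIAaIAb,RLL,8,RLL.AaIAaIA
RLL.AaIAaIAbI,RLL,9,RLL.AaIAaIAb
RLL.AaIAaIAaII,RLL,9,RLL.AaIAaIAa
RLL.AaIAaIAaIIA,RLL,10,RLL.AaIAaIAaII
RLL.AaIAaIAaIB,RLL,10,RLL.AaIAaIAaI
RLL.AaIAaIAaIBa,RLL,11,RLL.AaIAaIAaIB
RLL.AaIAaIAaIAb,RLL,11,RLL.AaIAaIAaIA
RCL.A,RCL,1,
RCL.Aa,RCL,2,RCL.A
RCL.AaI,RCL,3,RCL.Aa
RCL.AaIA,RCL,4,RCL.AaI
RCL.AaIAa,RCL,5,RCL.AaIA
RCL.AaIAaI,RCL,6,RCL.AaIAa
RCL.AaIAaIA,RCL,7,RCL.AaIAaI
RCL.AaIAaIAa,RCL,8,RCL.AaIAaIA
RCL.AaIAaIAaI,RCL,9,RCL.AaIAaIAa
RCL.AaIAaIAaIA,RCL,10,RCL.AaIAaIAaI
RCL.AaIAaIAaIAa,RCL,11,RCL.AaIAaIAaIA
RCL.Ab,RCL,2,RCL.A
RCL.AbI,RCL,3,RCL.Ab
RCL.AaII,RCL,3,RCL.Aa
RCL.AaIIA,RCL,4,RCL.AaII
RCL.AaIB,RCL,4,RCL.AaI
RCL.AaIBa,RCL,5,RCL.AaIB
RCL.AaIAb,RCL,5,RCL.AaIA
RCL.AaIAbI,RCL,6,RCL.AaIAb
RCL.AaIAaII,RCL,6,RCL.AaIAa
RCL.AaIAaIIA,RCL,7,RCL.AaIAaII
RCL.AaIAaIB,RCL,7,RCL.AaIAaI
RCL.AaIAaIBa,RCL,8,RCL.AaIAaIB
RCL.AaIAaIAb,RCL,8,RCL.AaIAaIA
RCL.AaIAaIAbI,RCL,9,RCL.AaIAaIAb
RCL.AaIAaIAaII,RCL,9,RCL.AaIAaIAa
RCL.AaIAaIAaIIA,RCL,10,RCL.AaIAaIAaII
RCL.AaIAaIAaIB,RCL,10,RCL.AaIAaIAaI
RCL.AaIAaIAaIBa,RCL,11,RCL.AaIAaIAaIB
RCL.AaIAaIAaIAb,RCL,11,RCL.AaIAaIAaIA
LL.A,LL,1,
LL.Aa,LL,2,LL.A
LL.AaI,LL,3,LL.Aa
LL.AaIA,LL,4,LL.AaI
LL.AaIAa,LL,5,LL.AaIA
LL.AaIAaI,LL,6,LL.AaIAa
LL.AaIAaIA,LL,7,LL.AaIAaI
LL.AaIAaIAa,LL,8,LL.AaIAaIA
LL.AaIAaIAaI,LL,9,LL.AaIAaIAa
LL.AaIAaIAaIA,LL,10,LL.AaIAaIAaI
LL.AaIAaIAaIAa,LL,11,LL.AaIAaIAaIA
LL.Ab,LL,2,LL.A
LL.AbI,LL,3,LL.Ab
LL.AaII,LL,3,LL.Aa
LL.AaIIA,LL,4,LL.AaII
LL.AaIB,LL,4,LL.AaI
LL.AaIBa,LL,5,LL.AaIB
LL.AaIAb,LL,5,LL.AaIA
LL.AaIAbI,LL,6,LL.AaIAb
LL.AaIAaII,LL,6,LL.AaIAa
LL.AaIAaIIA,LL,7,LL.AaIAaII
LL.AaIAaIB,LL,7,LL.AaIAaI
LL.AaIAaIBa,LL,8,LL.AaIAaIB
LL.AaIAaIAb,LL,8,LL.AaIAaIA
LL.AaIAaIAbI,LL,9,LL.AaIAaIAb
LL.AaIAaIAaII,LL,9,LL.AaIAaIAa
LL.AaIAaIAaIIA,LL,10,LL.AaIAaIAaII
LL.AaIAaIAaIB,LL,10,LL.AaIAaIAaI
LL.AaIAaIAaIBa,LL,11,LL.AaIAaIAaIB
LL.AaIAaIAaIAb,LL,11,LL.AaIAaIAaIA
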