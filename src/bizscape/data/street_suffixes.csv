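abbrev,expansion
ST,STREET
AVE,AVENUE
AV,AVENUE
RD,ROAD
BLVD,BOULEVARD
DR,DRIVE
LN,LANE
CT,COURT
PL,PLACE
PKWY,PARKWAY
HWY,HIGHWAY
SQ,SQUARE
TER,TERRACE
TERR,TERRACE
CIR,CIRCLE
EXPY,EXPRESSWAY
PLZ,PLAZA
ALY,ALLEY
BND,BEND
CRES,CRESCENT
XING,CROSSING
GDNS,GARDENS
HTS,HEIGHTS
TPKE,TURNPIKE
BRG,BRIDGE
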