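country	region
US	America
CA	America
MX	America
BR	America
AR	America
CL	America
CO	America
PE	America
GB	Europe
DE	Europe
FR	Europe
IT	Europe
ES	Europe
NL	Europe
BE	Europe
SE	Europe
NO	Europe
DK	Europe
FI	Europe
CH	Europe
AT	Europe
PL	Europe
PT	Europe
IE	Europe
GR	Europe
CZ	Europe
HU	Europe
RO	Europe
JP	Asia
CN	Asia
KR	Asia
IN	Asia
TH	Asia
SG	Asia
MY	Asia
PH	Asia
ID	Asia
VN	Asia
IL	Asia
TR	Asia
SA	Asia
AE	Asia
AU	Oceania
NZ	Oceania
ZA	Africa
EG	Africa
NG	Africa
KE	Africa
MA	Africa
TN	Africa
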