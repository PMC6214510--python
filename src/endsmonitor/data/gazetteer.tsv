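# Gazetteer: columns surface_form<TAB>iso3 (ISO 3166 alpha-3).
# Countries, selected capitals/major cities, and a few country-linked
# organizations. Homonymous place names: first entry wins.
surface_form	iso3
Afghanistan	AFG
Albania	ALB
Algeria	DZA
Argentina	ARG
Armenia	ARM
Australia	AUS
Austria	AUT
Azerbaijan	AZE
Bahrain	BHR
Bangladesh	BGD
Belarus	BLR
Belgium	BEL
Bolivia	BOL
Bosnia and Herzegovina	BIH
Botswana	BWA
Brazil	BRA
Bulgaria	BGR
Cambodia	KHM
Cameroon	CMR
Canada	CAN
Chile	CHL
China	CHN
Colombia	COL
Costa Rica	CRI
Croatia	HRV
Cuba	CUB
Cyprus	CYP
Czech Republic	CZE
Denmark	DNK
Dominican Republic	DOM
Ecuador	ECU
Egypt	EGY
El Salvador	SLV
Estonia	EST
Ethiopia	ETH
Finland	FIN
France	FRA
Georgia	GEO
Germany	DEU
Ghana	GHA
Greece	GRC
Guatemala	GTM
Honduras	HND
Hong Kong	HKG
Hungary	HUN
Iceland	ISL
India	IND
Indonesia	IDN
Iran	IRN
Iraq	IRQ
Ireland	IRL
Israel	ISR
Italy	ITA
Jamaica	JAM
Japan	JPN
Jordan	JOR
Kazakhstan	KAZ
Kenya	KEN
Kuwait	KWT
Laos	LAO
Latvia	LVA
Lebanon	LBN
Lithuania	LTU
Luxembourg	LUX
Malaysia	MYS
Mexico	MEX
Mongolia	MNG
Morocco	MAR
Myanmar	MMR
Nepal	NPL
Netherlands	NLD
New Zealand	NZL
Nicaragua	NIC
Nigeria	NGA
North Korea	PRK
Norway	NOR
Oman	OMN
Pakistan	PAK
Panama	PAN
Paraguay	PRY
Peru	PER
Philippines	PHL
Poland	POL
Portugal	PRT
Qatar	QAT
Romania	ROU
Russia	RUS
Russian Federation	RUS
Rwanda	RWA
Saudi Arabia	SAU
Senegal	SEN
Serbia	SRB
Singapore	SGP
Slovakia	SVK
Slovenia	SVN
South Africa	ZAF
South Korea	KOR
Spain	ESP
Sri Lanka	LKA
Sudan	SDN
Sweden	SWE
Switzerland	CHE
Syria	SYR
Taiwan	TWN
Tanzania	TZA
Thailand	THA
Tunisia	TUN
Turkey	TUR
Uganda	UGA
Ukraine	UKR
United Arab Emirates	ARE
United Kingdom	GBR
Great Britain	GBR
Britain	GBR
England	GBR
Scotland	GBR
Wales	GBR
United States	USA
United States of America	USA
America	USA
Uruguay	URY
Uzbekistan	UZB
Venezuela	VEN
Vietnam	VNM
Yemen	YEM
Zambia	ZMB
Zimbabwe	ZWE
Kabul	AFG
Buenos Aires	ARG
Canberra	AUS
Sydney	AUS
Melbourne	AUS
Vienna	AUT
Dhaka	BGD
Brussels	BEL
Brasilia	BRA
Sao Paulo	BRA
Rio de Janeiro	BRA
Ottawa	CAN
Toronto	CAN
Vancouver	CAN
Santiago	CHL
Beijing	CHN
Shanghai	CHN
Bogota	COL
Cairo	EGY
Paris	FRA
Berlin	DEU
Munich	DEU
Athens	GRC
New Delhi	IND
Mumbai	IND
Jakarta	IDN
Tehran	IRN
Dublin	IRL
Jerusalem	ISR
Rome	ITA
Tokyo	JPN
Nairobi	KEN
Kuala Lumpur	MYS
Mexico City	MEX
Amsterdam	NLD
Wellington	NZL
Auckland	NZL
Abuja	NGA
Lagos	NGA
Oslo	NOR
Islamabad	PAK
Asuncion	PRY
Lima	PER
Manila	PHL
Warsaw	POL
Lisbon	PRT
Bucharest	ROU
Moscow	RUS
Saint Petersburg	RUS
Riyadh	SAU
Seoul	KOR
Madrid	ESP
Barcelona	ESP
Stockholm	SWE
Geneva	CHE
Zurich	CHE
Bangkok	THA
Ankara	TUR
Istanbul	TUR
Kyiv	UKR
Kiev	UKR
London	GBR
Manchester	GBR
Edinburgh	GBR
Washington	USA
New York	USA
New York City	USA
Los Angeles	USA
Chicago	USA
San Francisco	USA
Boston	USA
Hanoi	VNM
Centers for Disease Control and Prevention	USA
Food and Drug Administration	USA
National Institutes of Health	USA
Surgeon General	USA
Congress	USA
White House	USA
National Health Service	GBR
Public Health England	GBR
Health Canada	CAN
European Commission	BEL
Kremlin	RUS
Duma	RUS
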