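alias	code	canonical
United States	US	United States
United States of America	US	United States
USA	US	United States
U.S.A.	US	United States
US	US	United States
United Kingdom	GB	United Kingdom
UK	GB	United Kingdom
Great Britain	GB	United Kingdom
England	GB	United Kingdom
Scotland	GB	United Kingdom
Wales	GB	United Kingdom
Northern Ireland	GB	United Kingdom
New Zealand	NZ	New Zealand
Aotearoa New Zealand	NZ	New Zealand
China	CN	China
People's Republic of China	CN	China
PRC	CN	China
Japan	JP	Japan
Taiwan	TW	Taiwan
Uruguay	UY	Uruguay
France	FR	France
Switzerland	CH	Switzerland
Germany	DE	Germany
Australia	AU	Australia
Canada	CA	Canada
Brazil	BR	Brazil
Brasil	BR	Brazil
Argentina	AR	Argentina
Chile	CL	Chile
South Korea	KR	South Korea
Republic of Korea	KR	South Korea
Korea	KR	South Korea
India	IN	India
Italy	IT	Italy
Spain	ES	Spain
Netherlands	NL	Netherlands
The Netherlands	NL	Netherlands
Belgium	BE	Belgium
Sweden	SE	Sweden
Norway	NO	Norway
Denmark	DK	Denmark
Finland	FI	Finland
Portugal	PT	Portugal
Mexico	MX	Mexico
South Africa	ZA	South Africa
Kenya	KE	Kenya
Nigeria	NG	Nigeria
Thailand	TH	Thailand
Vietnam	VN	Vietnam
Viet Nam	VN	Vietnam
Indonesia	ID	Indonesia
Malaysia	MY	Malaysia
Philippines	PH	Philippines
Russia	RU	Russia
Russian Federation	RU	Russia
Poland	PL	Poland
Austria	AT	Austria
Ireland	IE	Ireland
Israel	IL	Israel
Turkey	TR	Turkey
Türkiye	TR	Turkey
Egypt	EG	Egypt
Morocco	MA	Morocco
Colombia	CO	Colombia
Peru	PE	Peru
Ecuador	EC	Ecuador
Panama	PA	Panama
Costa Rica	CR	Costa Rica
Fiji	FJ	Fiji
Papua New Guinea	PG	Papua New Guinea
Hungary	HU	Hungary
Czechia	CZ	Czechia
Czech Republic	CZ	Czechia
Greece	GR	Greece
Singapore	SG	Singapore
Hong Kong	HK	Hong Kong
Pakistan	PK	Pakistan
Iran	IR	Iran
Saudi Arabia	SA	Saudi Arabia
United Arab Emirates	AE	United Arab Emirates
Ukraine	UA	Ukraine
Romania	RO	Romania
Bulgaria	BG	Bulgaria
Croatia	HR	Croatia
Slovenia	SI	Slovenia
Slovakia	SK	Slovakia
Estonia	EE	Estonia
Latvia	LV	Latvia
Lithuania	LT	Lithuania
Iceland	IS	Iceland
Luxembourg	LU	Luxembourg
Ghana	GH	Ghana
Ethiopia	ET	Ethiopia
Tanzania	TZ	Tanzania
Uganda	UG	Uganda
Madagascar	MG	Madagascar
Bolivia	BO	Bolivia
Paraguay	PY	Paraguay
Venezuela	VE	Venezuela
Cuba	CU	Cuba
Guatemala	GT	Guatemala
Honduras	HN	Honduras
Nicaragua	NI	Nicaragua
Dominican Republic	DO	Dominican Republic
Jamaica	JM	Jamaica
Sri Lanka	LK	Sri Lanka
Bangladesh	BD	Bangladesh
Nepal	NP	Nepal
Myanmar	MM	Myanmar
Cambodia	KH	Cambodia
Laos	LA	Laos
Mongolia	MN	Mongolia
Kazakhstan	KZ	Kazakhstan
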