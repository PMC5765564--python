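country	continent	aliases
United States	North America	USA|United States of America|U.S.A.|U.S.
United Kingdom	Europe	UK|U.K.|England|Scotland|Wales|Northern Ireland|Great Britain
France	Europe
Germany	Europe
Italy	Europe
Spain	Europe
Netherlands	Europe	The Netherlands|Holland
Belgium	Europe
Switzerland	Europe
Austria	Europe
Sweden	Europe
Norway	Europe
Denmark	Europe
Finland	Europe
Iceland	Europe
Ireland	Europe
Portugal	Europe
Greece	Europe
Poland	Europe
Czech Republic	Europe	Czechia|Czechoslovakia
Slovakia	Europe
Hungary	Europe
Romania	Europe
Bulgaria	Europe
Serbia	Europe	Yugoslavia
Croatia	Europe
Slovenia	Europe
Russia	Europe	Russian Federation|USSR|Soviet Union
Ukraine	Europe
Estonia	Europe
Latvia	Europe
Lithuania	Europe
Canada	North America
Mexico	North America
Cuba	North America
Costa Rica	North America
Panama	North America
Guatemala	North America
Jamaica	North America
Brazil	South America	Brasil
Argentina	South America
Chile	South America
Peru	South America
Colombia	South America
Venezuela	South America
Ecuador	South America
Uruguay	South America
Bolivia	South America
China	Asia	People's Republic of China|P.R. China|PR China
Japan	Asia
South Korea	Asia	Korea|Republic of Korea
India	Asia
Taiwan	Asia
Thailand	Asia
Vietnam	Asia	Viet Nam
Singapore	Asia
Malaysia	Asia
Indonesia	Asia
Philippines	Asia
Pakistan	Asia
Bangladesh	Asia
Sri Lanka	Asia
Nepal	Asia
Iran	Asia	Islamic Republic of Iran
Iraq	Asia
Israel	Asia
Turkey	Asia	Türkiye
Saudi Arabia	Asia
United Arab Emirates	Asia	UAE
Jordan	Asia
Lebanon	Asia
Qatar	Asia
Kuwait	Asia
Egypt	Africa
South Africa	Africa
Nigeria	Africa
Kenya	Africa
Ethiopia	Africa
Ghana	Africa
Tanzania	Africa	United Republic of Tanzania
Uganda	Africa
Morocco	Africa
Tunisia	Africa
Algeria	Africa
Senegal	Africa
Cameroon	Africa
Zimbabwe	Africa
Zambia	Africa
Malawi	Africa
Australia	Oceania
New Zealand	Oceania
Fiji	Oceania
Papua New Guinea	Oceania
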