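region_name,adm0_code,kind
Anguilla,9,no_data
Aruba,14,no_data
Ashmore_and_Cartier_Islands,16,no_data
Azores_Islands,74578,no_data
Baker_Island,22,no_data
Bassas_da_India,25,no_data
Bird_Island,32,no_data
Bouvet_Island,36,no_data
British_Indian_Ocean_Territory,38,no_data
Christmas_Island,54,no_data
Clipperton_Island,55,no_data
Cocos_(Keeling)_Islands,56,no_data
Europa_Island,80,no_data
French_Southern_and_Antarctic_Territories,88,no_data
Glorioso_Island,96,no_data
Greenland,98,no_data
Guernsey,104,no_data
Heard_Island_and_McDonald_Islands,109,no_data
Howland_Island,112,no_data
Isle_of_Man,120,no_data
Jarvis_Island,127,no_data
Jersey,128,no_data
Johnston_Atoll,129,no_data
Juan_de_Nova_Island,131,no_data
Kingman_Reef,134,no_data
Kuril_islands,136,no_data
Madeira_Islands,151,no_data
Mayotte,161,no_data
Midway_Island,164,no_data
Navassa_Island,174,no_data
Netherlands_Antilles,176,no_data
Norfolk_Island,184,no_data
Northern_Mariana_Islands,185,no_data
Palmyra_Atoll,190,no_data
Paracel_Islands,193,no_data
Pitcairn,197,no_data
Saint_Helena,207,no_data
Scarborough_Reef,216,no_data
Senkaku_Islands,218,no_data
South_Georgia_and_the_South_Sandwich_Islands,228,no_data
Spratly_Islands,230,no_data
Svalbard_and_Jan_Mayen_Islands,234,no_data
Tromelin_Island,247,no_data
Turks_and_Caicos_Islands,251,no_data
United_States_Virgin_Islands,258,no_data
Wake_Island,265,no_data
Gibraltar,95,no_data
Holy_See,110,no_data
Liechtenstein,146,no_data
Abyei,102,disputed
Aksai_Chin,2,disputed
Arunachal_Pradesh,15,disputed
China/India,52,disputed
Halaib_Triangle,40760,disputed
Ilemi_Triangle,61013,disputed
Jammu_and_Kashmir,40781,disputed
Matan_al-Sarra,40762,disputed
Falkland_Islands_(Malvinas),81,disputed
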