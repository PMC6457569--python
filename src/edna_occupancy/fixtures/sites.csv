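site_id,pair_id,island_type,area_m2
C01,P01,colony,1100.0
T01,P01,control,1150.0
C02,P02,colony,1200.0
T02,P02,control,1250.0
C03,P03,colony,1300.0
T03,P03,control,1350.0
C04,P04,colony,1400.0
T04,P04,control,1450.0
C05,P05,colony,1500.0
T05,P05,control,1550.0
C06,P06,colony,1600.0
T06,P06,control,1650.0
C07,P07,colony,1700.0
T07,P07,control,1750.0
C08,P08,colony,1800.0
T08,P08,control,1850.0
C09,P09,colony,1900.0
T09,P09,control,1950.0
C10,P10,colony,2000.0
T10,P10,control,2050.0
C11,P11,colony,2100.0
T11,P11,control,2150.0
C12,P12,colony,2200.0
T12,P12,control,2250.0
C13,P13,colony,2300.0
T13,P13,control,2350.0
C14,P14,colony,2400.0
T14,P14,control,2450.0
C15,P15,colony,2500.0
T15,P15,control,2550.0
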