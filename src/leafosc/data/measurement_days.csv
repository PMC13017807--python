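order,date,time,measure,weather,soil_moisture
1,2021-04-29,9:00-17:00,325,sunny,26.49
2,2021-06-29,9:30-12:00,80,overcast,26.60
3,2021-07-02,10:00-18:00,141,cloudy,24.45
4,2021-07-03,10:00-18:00,115,overcast,22.66
5,2021-07-20,10:00-17:00,67,overcast,21.66
6,2021-07-31,9:00-17:30,113,sunny,26.75
7,2021-08-02,9:30-10:30,37,cloudy,26.06
8,2021-08-06,9:30-10:30,37,sunny,24.09
9,2021-09-15,9:00-12:00,86,cloudy,24.43
10,2022-04-29,9:00-12:00,26,cloudy,23.62
11,2022-06-24,9:00-12:00,28,cloudy,26.70
12,2022-07-06,9:00-16:00,302,overcast,
13,2022-07-07,9:00-12:00,226,overcast,
14,2022-07-21,9:00-12:00,86,overcast,26.80
15,2022-07-22,10:00-13:00,76,overcast,26.80
16,2022-08-09,9:00-11:30,26,cloudy,22.58
17,2022-10-01,10:00-10:30,81,cloudy,26.83
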